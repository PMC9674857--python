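# kinstack

Genomic prediction of quantitative traits from **stacked kinship matrices**.

`kinstack` is a toolkit for comparing whole-genome prediction models on
simulated trait architectures. It targets the common situation in animal and
plant breeding where a panel of biallelic SNP genotypes (coded 0/1/2) must
predict a continuous phenotype, and the phenotype may be anything from fully
additive to dominated by dominance and epistatic interactions. The package
provides:

- a **phenotype simulator** spanning nine architectures (S1–S9) that mix
  additive, dominant and epistatic (AA/AD/DD) effects at a controlled
  broad-sense heritability H²;
- the **15-matrix kinship set**: realized additive (VanRaden), dominance
  (heterozygosity coding) and Hadamard-product epistatic relationship
  matrices, each under three MAF filters (>1%, >5%, and the rare 1–5% band);
- a **kinship-image representation**: samples are seriated by hierarchical
  clustering of the reference additive kinship, the 15 matrices are stacked
  into an n×n×15 tensor, and each sample's (n_ref × 15) slice is treated as a
  grayscale image;
- a **convolutional regression network** (numpy engine: conv 3×3 → dropout →
  conv → maxpool → dense stack → linear output, RMSprop + MSE, optional noise
  augmentation) plus a greedy stepwise hyperparameter search;
- **multi-kernel GBLUP** fitted by Gibbs sampling, with per-scenario kernel
  selection (GBLUP-A uses K_A only; GBLUP-optim includes exactly the kernels
  matching the active effects);
- an **evaluation harness**: repeated 80/20 hold-out validation with Pearson
  correlation, RMSE, NDCG and prediction bias.

## The model at the core

GBLUP treats phenotypes as `y = 1μ + Σᵢ uᵢ + e`, with `uᵢ ~ N(0, Kᵢ σᵢ²)` for
each relationship matrix `Kᵢ ∈ {K_A, K_D, K_AA, K_AD, K_DD}` and
`e ~ N(0, I σₑ²)`. K_A is the centered cross-product `Z Z′ / 2Σpⱼqⱼ`
(`Z = calls − 2p`); K_D uses the heterozygosity coding
`W = 1{het} − 2pq`; the epistatic matrices are Hadamard products
(`K_AA = K_A ∘ K_A`, …). The Gibbs sampler works in each kernel's eigenbasis
and predicts held-out samples by treating their phenotypes as missing data.
The CNN replaces the linear mixed model with a learned map from a sample's
kinship image (its relationships to all training samples under all 15
matrices) to its phenotype.

## Worked example

```python
from kinstack.genotypes import simulate_genotypes
from kinstack.harness import ExperimentPlan, run_experiment, task_seed

# synthetic stand-in for a livestock panel: 25 half-sib-like families
panel = simulate_genotypes(500, 1000, (0.01, 0.5), n_families=25,
                           seed=task_seed(1, "panel"))
plan = ExperimentPlan(scenarios=("S1", "S3", "S5"),
                      models=("gblup_a", "gblup_optim"), repeats=10, seed=1)
metrics, bias, provenance = run_experiment(plan, panel)
print(metrics.groupby(["model", "scenario"])["pearson"].mean().round(3))
```

prints (hold-out Pearson correlation, mean of 10 repeats):

```
model        scenario
gblup_a      S1          0.666
             S3          0.605
             S5          0.430
gblup_optim  S1          0.664
             S3          0.628
             S5          0.545
Name: pearson, dtype: float64
```

Read: on the fully additive trait (S1, H² = 0.7) both models approach the
heritability ceiling √0.7 ≈ 0.84 as closely as the panel allows, and the
dominance kernel adds nothing. As the dominant share grows (S3) and becomes
total (S5), additive-only GBLUP degrades sharply while the kernel-matched
model retains much of its accuracy — the motivating phenomenon for
non-additive kernels and for the kinship-image CNN.

The same pipeline is scriptable from a shell via the `kinstack` command
(`simulate-genotypes`, `simulate-phenotypes`, `build-kinships`, `make-stack`,
`train-dnn`, `fit-gblup`, `evaluate`, `benchmark`).

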