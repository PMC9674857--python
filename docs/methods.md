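# Methods

## Phenotype simulation

A simulated trait is built from a genotype panel in seven steps: (1) draw
`qtn` causal markers (QTNs) uniformly without replacement, ignoring
chromosome structure; (2) give each QTN an additive effect from
`N(μ_A, cv·μ_A)` with an independent 50% sign flip (so neither allele is
systematically favoured); (3) likewise dominant effects with mean `μ_D`;
(4) shuffle the QTNs into `⌊qtn/2⌋` disjoint pairs and give each pair AA, AD
and DD interaction effects with means `μ_AA`, `μ_AD`, `μ_DD`; (5) form
noiseless genetic values with Cockerham-style codes — additive code
`x_A = call − 1 ∈ {−1,0,1}`, dominance code `x_D = 1{heterozygote}`, pair
contributions `e·x·x′`; (6) add Gaussian noise with variance
`σ_N² = σ_G²(1−H²)/H²`, where `σ_G²` is the *empirical* variance of the
realized genetic values; (7) standardize to zero mean and unit variance
(population denominator).

Defaults: `qtn = 1000`, `H² = 0.7`, `cv = 0.1`. A zero effect mean disables
that component entirely (its SD `cv·μ` is also zero). The nine shipped
scenarios S1–S9 run from fully additive (μ_A=100) through additive/dominant
mixtures to fully dominant (μ_D=100) and three epistasis flavours; only
their ratios matter because of the final standardization.

Using the empirical `σ_G²` for noise calibration guarantees the realized
broad-sense heritability matches the target on the panel at hand, up to the
sampling noise of the noise draw itself (±0.02 at n = 500). An analytic
HWE-based variance decomposition was considered as the calibration path and
rejected: it would make realized H² drift with the realized QTN frequencies.

Epistatic pairs are formed from the same selected QTNs that carry the
single-locus effects, so in S6–S9 a marker can act through both routes; this
matches the construction in which pairing is a step applied to the already
selected markers.

## Kinship matrices

- Additive: `K_A = Z Z′ / (2 Σ_j p_j q_j)` with `Z = calls − 2p`
  (VanRaden's centered cross-product). PSD by construction; for an outbred
  panel `mean(diag K_A) ≈ 1 +` mean inbreeding.
- Dominance: heterozygosity coding `W = 1{call=1} − 2pq`, scaled by
  `Σ_j 2p_jq_j(1 − 2p_jq_j)`. A "genotypic" carrier coding (het and alt
  homozygote alike) is available as an option but is not the default: the
  heterozygosity form is what the standard kinship software computes.
- Epistatic: Hadamard products `K_AA = K_A∘K_A`, `K_AD = K_A∘K_D`,
  `K_DD = K_D∘K_D`, held to exact elementwise identity in tests.

Each of three MAF filters (>1%, >5%, 1–5% rare band; boundaries chosen as
strict thresholds with a half-open rare interval so the three bands
partition exactly) is applied first, and allele frequencies are recomputed
on the filtered subset before centering. 3 filters × 5 types = 15 matrices
in a fixed channel order. No blending or bending toward the identity is
applied; near-singular kernels are handled downstream by an eigenvalue
floor.

## Kinship-image representation

Samples are reordered for data locality using average-linkage hierarchical
clustering of `d(i,j) = 1 − K_A[i,j]/√(K_A[i,i]·K_A[j,j])` on the MAF>5%
additive matrix; the dendrogram leaf order (as emitted by scipy) is applied
to every channel before stacking into the n×n×15 tensor. The linkage and
dissimilarity are our choices — any seriation that keeps related samples
adjacent serves the purpose.

A sample's network input is its tensor row restricted to a reference set of
columns, a (n_ref × 15) matrix treated as one grayscale image. Training
samples use the training set itself as reference; a held-out sample's slice
is its own kinship row restricted to the *same training columns*, which
keeps the input width fixed and leaks no validation phenotype (kinships are
functions of genotypes only). Slices are fed as raw kinship values; an
optional min-max rescale exists but is off by default. Noise augmentation
appends `reps` copies of the training slices with i.i.d. Gaussian noise
(default SD 0.1); symmetry of the noisy copies is deliberately not
enforced, since slicing is linear in the tensor.

## Convolutional network

Final architecture for (n_ref × 15) single-channel inputs:
conv(32, 3×3, same, ReLU) → dropout(0.25) → conv(64, 3×3, same, ReLU) →
maxpool(2×2) → dropout → flatten → dense(64) → dropout → dense(32) →
dropout → dense(16) → dropout → dense(1, linear). Training: RMSprop
(lr 0.001, ρ 0.9, ε 1e-7), MSE loss, fixed 300 epochs by default (no early
stopping), minibatch 32 (unreported upstream; exposed in the config),
Glorot-uniform initialization, inverted dropout. L1/L2 penalties exist as
config knobs and default to zero. One master seed drives initialization,
shuffling, dropout masks and augmentation noise; reproducibility is
promised per platform, not across BLAS builds.

The engine is a compact numpy implementation (im2col convolution, argmax
max-pool routing, reverse-mode gradients per layer) with per-layer
parameter counts exposed so architectures can be audited by hand
(e.g. the first conv layer trains (3·3·1)·32+32 = 320 parameters; a dense
64 on a 50,000-long flattened input would train 3.2M weights — the
overparameterization the kinship representation avoids).

The greedy stepwise search tunes one hyperparameter at a time in a stated
order (kernel size, padding, layout, penalties, drop rate, augmentation),
scoring each candidate by mean validation Pearson over resampled 80/20
splits and fixing the winner before moving on; ties keep the
earlier-listed candidate, and the step log records the percentage
improvement over the previous step.

## GBLUP by Gibbs sampling

Model: `y = 1μ + Σᵢ uᵢ + e`, `uᵢ ~ N(0, Kᵢσᵢ²)`, `e ~ N(0, Iσₑ²)`; one
record per sample, so incidence matrices are identity and never
materialized. Each kernel is eigendecomposed once with eigenvalues floored
at 1e-8 (kernels with eigenvalues below −1e-6 are rejected as non-PSD);
random effects are updated blockwise in their eigenbasis, where the full
conditional is diagonal. Variance components use scaled-inverse-χ² full
conditionals with prior df 5 and scales whose prior modes split half of
var(y_obs) equally across the genetic components and give the other half
to the residual (the convention of standard Bayesian genomic-prediction
software). Default chain: 10,000 iterations, 500 burn-in, thinning 1;
tests and the desk-scale harness use shorter chains (2,000–5,000) after
checking that estimates are stable from ~2,000 iterations.

Held-out samples enter with missing phenotypes imputed from their full
conditional each sweep; a prediction is the posterior mean of `μ + Σ uᵢ`
at the sample's position. With variances and mean fixed the sampler
reports the exact conditional mean (Rao-Blackwellized), which the test
suite checks against a direct dense mixed-model solve to 1e-6.

Kernel selection (GBLUP-optim) includes exactly the relationship types
whose effect means are active in the scenario (K_A and K_D for an
additive+dominant mixture, all five only when every effect type is
present). GBLUP kernels are taken from the MAF>5% set — the reference
filter used for sample ordering — exposed as an option since the choice of
filter for model fitting is otherwise open.

The sampler was validated against direct 2D numerical integration of the
marginal posterior (random effects integrated analytically in the
eigenbasis): posterior means of the variance components agree to the
Monte-Carlo error. A consequence worth knowing: at a few hundred samples
the marginal posterior of the heritability is broad and the prior-weighted
posterior mean sits noticeably below a boundary ML estimate for strongly
heritable traits; the parameter-recovery tests therefore run at n = 600,
where the posterior concentrates enough for the ±0.1 recovery check, and
the package documents rather than hides the small-n shrinkage.

## Evaluation harness

For each simulation run × scenario × repeat: simulate the phenotype, draw
an 80/20 split (validation size = round(0.2·n); the split is shared across
models within a repeat for paired comparisons), fit each model on training
samples only, predict validation samples, and record Pearson, RMSE and
NDCG. Kinships are computed once per panel from genotypes only and reused
across repeats (a strict mode recomputes them per split for users who
object to test-genotype visibility). All task seeds derive from one master
seed via a CRC-mixed schedule logged in the provenance.

Metrics follow the standard definitions; NDCG ranks by descending true
value (ties broken by original index), normalizes by the ideal DCG, and
flags a near-zero ideal DCG as undefined instead of clipping. Because
standardized phenotypes can be negative, NDCG computed verbatim is not
bounded by 1 for arbitrary predictions; the ≤1 bound is a rearrangement
inequality that holds when the predictions carry the same (non-negative)
gain multiset, and the property suite asserts exactly that form. Bias is
the per-sample mean prediction across replicates minus truth, averaged
over covered samples to one value per model × scenario.

## Synthetic data and what the tests show

The genotype generator draws per-marker allele frequencies from
Uniform(0.01, 0.5) (covering all three MAF bands, including the rare one)
and either independent binomial genotypes or family blocks: families share
four founder haplotypes inherited in blocks of 50 markers, giving realized
kinship the within-family structure of a livestock population. Benchmark-
level checks use a 500-sample, 25-family, 1000-marker panel: an unrelated
panel of independent markers has an effective-segment count equal to the
marker count, which caps hold-out accuracy far below what a related panel
(or a real cattle population with extensive LD) supports; the family panel
reproduces the accuracy regime in which additive GBLUP on a fully additive
H²=0.7 trait reaches Pearson ≈ 0.67 against the √0.7 ≈ 0.84 ceiling.

What the generator does *not* emulate: linkage disequilibrium within
chromosomes beyond founder blocks, genotyping error, population
stratification across breeds, genotype×environment interaction, and minor-
allele/effect-size coupling. Passing tests therefore demonstrate the
correctness and calibration of the pipeline and the qualitative model
ordering (kernel-matched GBLUP ≥ additive GBLUP as dominance grows), not
performance on any real population.

Stochastic trend checks (accuracy decline along the additive→dominant
gradient) are judged at the Monte Carlo level: adjacent scenario means over
10 repeats may not rise by more than two standard errors of their
difference, and the end-to-end S1→S5 decline must be strict. Problem sizes
used by the default suite — n ≤ 600 samples, ≤ 5000 markers, chains ≤ 5000
iterations, CNN replicas with 4–16 filters and ≤ 60 epochs — are the
package's desk-scale choices; every size is a plain argument, so
full-scale runs are a configuration change, not a code change.

## Known limitations

- The CNN engine is single-threaded numpy; full-scale inputs
  (1000+ samples × 300 epochs) are feasible but slow compared to a GPU
  framework. The architecture and training contract are engine-independent.
- NDCG on standardized (signed) phenotypes can exceed 1 or blow up when the
  ideal DCG is near zero; the implementation surfaces this rather than
  redefining the metric.
- The Gibbs sampler assumes one record per sample; repeated records or
  fixed-effect covariates beyond the overall mean are out of scope.
- Loader-side imputation is a deliberate opt-in and rounds to legal calls;
  panels with substantial missingness deserve a real imputation tool.
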