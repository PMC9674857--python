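"""Quantitative-trait simulation with additive, dominant and epistatic effects.

A phenotype is built in seven steps:

1. select ``qtn`` causal markers uniformly at random (no chromosome
   structure);
2. assign each an additive effect drawn from ``N(mu_A, cv * mu_A)`` with an
   independent 50% sign flip;
3. same for dominant effects with ``mu_D``;
4. randomly couple the causal markers into ``floor(qtn / 2)`` disjoint pairs
   and assign each pair AA / AD / DD interaction effects the same way;
5. form noiseless genetic values by multiplying effects and genotype codes
   (Cockerham-style: additive code ``call - 1`` in {-1, 0, 1}, dominance
   code ``1{heterozygote}``; pair contributions are products of the
   per-locus codes);
6. add Gaussian noise with variance ``sigma2_N = sigma2_G * (1 - H2) / H2``
   where ``sigma2_G`` is the realized variance of the genetic values, so the
   broad-sense heritability of the raw phenotype is ``H2``;
7. standardize the phenotype to zero mean and unit variance.

A mean effect of zero switches that component off entirely (its standard
deviation ``cv * mu`` is then also zero). Scenario presets S1–S9 span the
gradient from fully additive to fully dominant plus three epistasis types;
they are shipped in ``data/scenarios.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .genotypes import GenotypeMatrix

__all__ = [
    "ScenarioConfig",
    "SimulatedPhenotype",
    "scenario_preset",
    "scenario_table",
    "sample_effects",
    "pair_qtn",
    "genetic_values",
    "calibrate_noise",
    "simulate_scenario",
]

_EFFECT_KEYS = ("mu_A", "mu_D", "mu_AA", "mu_AD", "mu_DD")


def scenario_table() -> dict[str, dict]:
    """All shipped scenario presets (S1..S9) as a name -> parameters mapping."""
    text = resources.files("kinstack.data").joinpath("scenarios.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class ScenarioConfig:
    """Effect means and shared simulation parameters for one scenario."""

    mu_A: float = 0.0
    mu_D: float = 0.0
    mu_AA: float = 0.0
    mu_AD: float = 0.0
    mu_DD: float = 0.0
    qtn: int = 1000
    h2: float = 0.7
    cv: float = 0.1
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        means = [getattr(self, k) for k in _EFFECT_KEYS]
        if any(m < 0 for m in means):
            raise ValueError("effect means must be non-negative")
        if not any(m > 0 for m in means):
            raise ValueError("at least one effect mean must be positive")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must lie in (0, 1]")
        if self.qtn < 1:
            raise ValueError("qtn must be >= 1")

    def effect_means(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in _EFFECT_KEYS}

    def active_effects(self) -> list[str]:
        """Effect kinds with positive mean, in A, D, AA, AD, DD order."""
        return [k.removeprefix("mu_") for k in _EFFECT_KEYS if getattr(self, k) > 0]


def scenario_preset(name: str, **overrides) -> ScenarioConfig:
    """Build a ScenarioConfig from a shipped preset (``"S1"`` .. ``"S9"``)."""
    table = scenario_table()
    if name not in table:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(table)}")
    params = {k: v for k, v in table[name].items() if k in _EFFECT_KEYS}
    params.update(overrides)
    return ScenarioConfig(name=name, **params)


@dataclass
class SimulatedPhenotype:
    """A simulated trait plus the full provenance of its construction."""

    phenotype: np.ndarray          # standardized (zero mean, unit variance)
    phenotype_raw: np.ndarray      # genetic values + calibrated noise
    genetic_values: np.ndarray     # noiseless
    qtn_indices: np.ndarray
    pairs: np.ndarray              # (n_pairs, 2) marker-index couples
    effects: dict[str, np.ndarray]  # keys: A, D (per QTN); AA, AD, DD (per pair)
    sigma2_G: float
    sigma2_N: float
    config: ScenarioConfig = field(default=None)  # type: ignore[assignment]

    @property
    def realized_h2(self) -> float:
        """var(genetic values) / var(raw phenotype): realized broad-sense H2."""
        return float(np.var(self.genetic_values) / np.var(self.phenotype_raw))


def sample_effects(mu: float, cv: float, n: int, rng) -> np.ndarray:
    """Draw n effects from N(mu, cv*mu) with independent 50% sign swaps.

    A zero mean switches the component off (all-zero vector).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if mu < 0 or cv < 0:
        raise ValueError("mu and cv must be non-negative")
    rng = np.random.default_rng(rng)
    if mu == 0.0:
        return np.zeros(n)
    eff = rng.normal(mu, cv * mu, size=n)
    flip = rng.random(n) < 0.5
    eff[flip] *= -1.0
    return eff


def pair_qtn(qtn_indices, rng) -> np.ndarray:
    """Couple causal markers into floor(n/2) disjoint pairs (random shuffle)."""
    idx = np.asarray(qtn_indices)
    if idx.size < 2:
        raise ValueError("need at least 2 QTN indices to form pairs")
    rng = np.random.default_rng(rng)
    perm = rng.permutation(idx)
    n_pairs = idx.size // 2
    return perm[: 2 * n_pairs].reshape(n_pairs, 2)


def genetic_values(
    g: GenotypeMatrix,
    qtn_indices,
    pairs,
    effects: dict[str, np.ndarray],
) -> np.ndarray:
    """Noiseless genetic values from per-QTN and per-pair effects.

    Per sample: ``sum_j a_j x_A + d_j x_D`` over QTNs plus
    ``e_AA x_A x_A' + e_AD x_A x_D' + e_DD x_D x_D'`` over pairs, with
    ``x_A = call - 1`` and ``x_D = 1{call == 1}``.
    """
    qtn_indices = np.asarray(qtn_indices, dtype=int)
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if qtn_indices.size and qtn_indices.max() >= g.n_markers:
        raise ValueError("QTN index out of range")
    a = np.asarray(effects.get("A", np.zeros(qtn_indices.size)), dtype=float)
    d = np.asarray(effects.get("D", np.zeros(qtn_indices.size)), dtype=float)
    if a.size != qtn_indices.size or d.size != qtn_indices.size:
        raise ValueError("per-QTN effect vectors do not match qtn_indices")
    n_pairs = pairs.shape[0]
    e_aa = np.asarray(effects.get("AA", np.zeros(n_pairs)), dtype=float)
    e_ad = np.asarray(effects.get("AD", np.zeros(n_pairs)), dtype=float)
    e_dd = np.asarray(effects.get("DD", np.zeros(n_pairs)), dtype=float)
    if not (e_aa.size == e_ad.size == e_dd.size == n_pairs):
        raise ValueError("per-pair effect vectors do not match pairs")

    calls = g.calls.astype(float)
    xa = calls[:, qtn_indices] - 1.0
    xd = (calls[:, qtn_indices] == 1.0).astype(float)
    values = xa @ a + xd @ d
    if n_pairs:
        xa1 = calls[:, pairs[:, 0]] - 1.0
        xd1 = (calls[:, pairs[:, 0]] == 1.0).astype(float)
        xa2 = calls[:, pairs[:, 1]] - 1.0
        xd2 = (calls[:, pairs[:, 1]] == 1.0).astype(float)
        values = values + (xa1 * xa2) @ e_aa + (xa1 * xd2) @ e_ad + (xd1 * xd2) @ e_dd
    return values


def calibrate_noise(genetic, h2: float, rng) -> tuple[np.ndarray, float, float]:
    """Add Gaussian noise so the broad-sense heritability of the result is h2.

    ``sigma2_G`` is the empirical (population) variance of the genetic
    values; ``sigma2_N = sigma2_G * (1 - h2) / h2``.
    """
    genetic = np.asarray(genetic, dtype=float)
    sigma2_g = float(np.var(genetic))
    if sigma2_g <= 0.0:
        raise ValueError("zero genetic variance: heritability undefined")
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    sigma2_n = sigma2_g * (1.0 - h2) / h2
    rng = np.random.default_rng(rng)
    noise = rng.normal(0.0, np.sqrt(sigma2_n), size=genetic.shape) if sigma2_n > 0 else 0.0
    return genetic + noise, sigma2_g, sigma2_n


def simulate_scenario(g: GenotypeMatrix, cfg: ScenarioConfig) -> SimulatedPhenotype:
    """Run the full simulation pipeline for one scenario on one panel."""
    if cfg.qtn > g.n_markers:
        raise ValueError(f"qtn={cfg.qtn} exceeds panel markers ({g.n_markers})")
    rng = np.random.default_rng(cfg.seed)
    qtn = rng.choice(g.n_markers, size=cfg.qtn, replace=False)
    eff_a = sample_effects(cfg.mu_A, cfg.cv, cfg.qtn, rng)
    eff_d = sample_effects(cfg.mu_D, cfg.cv, cfg.qtn, rng)
    pairs = pair_qtn(qtn, rng) if cfg.qtn >= 2 else np.empty((0, 2), dtype=int)
    n_pairs = pairs.shape[0]
    effects = {
        "A": eff_a,
        "D": eff_d,
        "AA": sample_effects(cfg.mu_AA, cfg.cv, max(n_pairs, 1), rng)[:n_pairs],
        "AD": sample_effects(cfg.mu_AD, cfg.cv, max(n_pairs, 1), rng)[:n_pairs],
        "DD": sample_effects(cfg.mu_DD, cfg.cv, max(n_pairs, 1), rng)[:n_pairs],
    }
    gv = genetic_values(g, qtn, pairs, effects)
    raw, s2g, s2n = calibrate_noise(gv, cfg.h2, rng)
    std = raw.std()
    if std <= 0:
        raise ValueError("degenerate raw phenotype (zero variance)")
    pheno = (raw - raw.mean()) / std
    return SimulatedPhenotype(
        phenotype=pheno,
        phenotype_raw=raw,
        genetic_values=gv,
        qtn_indices=qtn,
        pairs=pairs,
        effects=effects,
        sigma2_G=s2g,
        sigma2_N=s2n,
        config=cfg,
    )
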