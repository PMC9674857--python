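"""Realized genomic relationship (kinship) matrices.

Five relationship types are computed from a genotype panel:

* ``A``  — additive kinship (VanRaden method 1): centered cross-product
  ``Z Z' / (2 * sum_j p_j q_j)`` with ``Z = calls - 2p``.
* ``D``  — dominance kinship (heterozygosity coding): ``W W' / sum_j 2 p_j
  q_j (1 - 2 p_j q_j)`` with ``W = 1{call==1} - 2 p q``.
* ``AA``, ``AD``, ``DD`` — epistatic kinships, Hadamard products of the
  component matrices (e.g. ``K_AA = K_A ∘ K_A``).

Combined with three MAF filtering strategies these give the 15-matrix set
used by the stacked-kinship representation. The fixed channel order is
``gt1pct`` [A, D, AA, AD, DD], then ``gt5pct`` [...], then
``rare_1to5pct`` [...].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MAF_STRATEGIES, GenotypeMatrix, filter_by_maf

__all__ = [
    "KinshipMatrix",
    "REL_TYPES",
    "CHANNEL_ORDER",
    "additive_kinship",
    "dominance_kinship",
    "epistatic_kinships",
    "build_kinship_set",
    "write_kinship",
    "read_kinship",
]

REL_TYPES = ("A", "D", "AA", "AD", "DD")

#: The documented fixed channel order of the 15-matrix set.
CHANNEL_ORDER = tuple((tag, rel) for tag in MAF_STRATEGIES for rel in REL_TYPES)


@dataclass
class KinshipMatrix:
    """An n x n symmetric realized relationship matrix."""

    values: np.ndarray
    rel_type: str
    samples: list[str]
    maf_tag: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("kinship must be square")
        if len(self.samples) != n:
            raise ValueError("sample labels do not match matrix size")
        if not np.isfinite(self.values).all():
            raise ValueError("kinship contains non-finite entries")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValueError("kinship is not symmetric within 1e-10")
        if self.rel_type not in REL_TYPES:
            raise ValueError(f"rel_type must be one of {REL_TYPES}")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def additive_kinship(g: GenotypeMatrix, maf_tag: str | None = None) -> KinshipMatrix:
    """Centered cross-product additive relationship matrix.

    ``K_A = Z Z' / (2 * sum_j p_j (1 - p_j))`` with columns of ``Z``
    centered by twice the allele frequency. Positive semidefinite by
    construction; under this scaling the mean diagonal is approximately
    ``1 + mean inbreeding`` for an outbred panel.
    """
    p = g.allele_freq
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: additive scaling denominator is zero")
    z = g.calls.astype(float) - 2.0 * p
    k = (z @ z.T) / denom
    k = 0.5 * (k + k.T)
    return KinshipMatrix(k, "A", list(g.samples), maf_tag)


def dominance_kinship(g: GenotypeMatrix, maf_tag: str | None = None, coding: str = "het") -> KinshipMatrix:
    """Dominance relationship matrix.

    Default ``coding="het"`` is the heterozygosity coding
    ``W = 1{call==1} - 2pq`` scaled by ``sum_j 2 p_j q_j (1 - 2 p_j q_j)``.
    ``coding="genotypic"`` instead codes carriers (het or alt homozygote)
    as 1, centered by the carrier frequency and scaled by the summed
    carrier-indicator variance — the verbal "het and dominant homozygote
    act alike" model, kept as an option.
    """
    p = g.allele_freq
    q = 1.0 - p
    if coding == "het":
        h = 2.0 * p * q
        denom = float(np.sum(h * (1.0 - h)))
        if denom <= 0.0:
            raise ValueError("degenerate dominance denominator (no expected heterozygosity)")
        w = (g.calls == 1).astype(float) - h
    elif coding == "genotypic":
        carrier = (g.calls >= 1).astype(float)
        f = 1.0 - q**2  # carrier frequency under HWE
        denom = float(np.sum(f * (1.0 - f)))
        if denom <= 0.0:
            raise ValueError("degenerate dominance denominator (no carrier variance)")
        w = carrier - f
    else:
        raise ValueError(f"unknown dominance coding {coding!r}")
    k = (w @ w.T) / denom
    k = 0.5 * (k + k.T)
    return KinshipMatrix(k, "D", list(g.samples), maf_tag)


def epistatic_kinships(ka: KinshipMatrix, kd: KinshipMatrix) -> tuple[KinshipMatrix, KinshipMatrix, KinshipMatrix]:
    """Hadamard-product epistatic kinships (K_AA, K_AD, K_DD)."""
    if ka.samples != kd.samples:
        raise ValueError("additive and dominance kinships have different sample order")
    tag = ka.maf_tag
    kaa = KinshipMatrix(ka.values * ka.values, "AA", list(ka.samples), tag)
    kad = KinshipMatrix(ka.values * kd.values, "AD", list(ka.samples), tag)
    kdd = KinshipMatrix(kd.values * kd.values, "DD", list(ka.samples), tag)
    return kaa, kad, kdd


def build_kinship_set(g: GenotypeMatrix, coding: str = "het") -> list[KinshipMatrix]:
    """The full 15-matrix set: 3 MAF filters x 5 relationship types.

    Channel order follows :data:`CHANNEL_ORDER`. Allele frequencies are
    recomputed on each filtered marker subset before centering. Raises if
    any MAF band retains no markers.
    """
    out: list[KinshipMatrix] = []
    for tag in MAF_STRATEGIES:
        try:
            sub = filter_by_maf(g, tag)
        except ValueError as exc:
            raise ValueError(f"cannot build kinship set: MAF band {tag!r} is empty") from exc
        ka = additive_kinship(sub, maf_tag=tag)
        kd = dominance_kinship(sub, maf_tag=tag, coding=coding)
        kaa, kad, kdd = epistatic_kinships(ka, kd)
        out.extend([ka, kd, kaa, kad, kdd])
    return out


def write_kinship(k: KinshipMatrix, path, sep: str = "\t") -> None:
    """Serialize to delimited text with sample IDs as header/first column.

    Full float precision is kept so a round trip preserves values to 1e-12.
    """
    df = pd.DataFrame(k.values, index=k.samples, columns=k.samples)
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_kinship(path, rel_type: str = "A", maf_tag: str | None = None, sep: str = "\t") -> KinshipMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return KinshipMatrix(df.to_numpy(dtype=float), rel_type, [str(s) for s in df.index], maf_tag)
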