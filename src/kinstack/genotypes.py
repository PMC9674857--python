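"""Biallelic SNP genotype panels: loading, filtering, summarising, simulating.

Genotypes are coded as the count of the alternative allele (0/1/2). Minor
allele frequency (MAF) is ``min(p, 1 - p)`` where ``p`` is the alternative
allele frequency. Three MAF filtering strategies are supported:

* ``gt1pct``        — keep markers with MAF > 1%
* ``gt5pct``        — keep markers with MAF > 5%
* ``rare_1to5pct``  — keep markers with MAF in (1%, 5%] (rare alleles only)

Boundary semantics: the ``>`` thresholds are strict and the rare band is the
half-open interval (0.01, 0.05], so ``gt1pct`` is the disjoint union of
``gt5pct`` and ``rare_1to5pct``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "MAF_STRATEGIES",
    "read_genotypes",
    "simulate_genotypes",
    "filter_by_maf",
    "panel_summary",
]

MAF_STRATEGIES = ("gt1pct", "gt5pct", "rare_1to5pct")

#: Columns preceding genotype calls in a PLINK .raw export.
_PLINK_RAW_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


class GenotypeFormatError(ValueError):
    """Raised when a genotype file contains unparseable or out-of-range calls."""


@dataclass
class GenotypeMatrix:
    """An n_samples x n_markers panel of 0/1/2 genotype calls.

    ``allele_freq`` holds the per-marker alternative-allele frequency,
    recomputable as ``calls.mean(axis=0) / 2``.
    """

    samples: list[str]
    markers: list[str]
    calls: np.ndarray
    allele_freq: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2D samples x markers matrix")
        n, m = self.calls.shape
        if n < 2 or m < 1:
            raise ValueError(f"need >=2 samples and >=1 marker, got {n}x{m}")
        if len(self.samples) != n or len(self.markers) != m:
            raise ValueError("sample/marker label counts do not match calls shape")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample identifiers")
        bad = (self.calls < 0) | (self.calls > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeFormatError(
                f"call out of range {{0,1,2}} at sample {self.samples[i]!r}, "
                f"marker {self.markers[j]!r}"
            )
        if self.allele_freq is None:
            self.allele_freq = self.calls.mean(axis=0) / 2.0
        else:
            self.allele_freq = np.asarray(self.allele_freq, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency."""
        return np.minimum(self.allele_freq, 1.0 - self.allele_freq)


def _parse_calls(df: pd.DataFrame, missing: str | None, impute_missing: bool) -> np.ndarray:
    raw = df.to_numpy()
    calls = np.empty(raw.shape, dtype=float)
    miss_mask = np.zeros(raw.shape, dtype=bool)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        for i, tok in enumerate(col):
            s = str(tok).strip()
            if missing is not None and (s == missing or s in ("", "nan", "NA")):
                miss_mask[i, j] = True
                calls[i, j] = np.nan
                continue
            try:
                v = float(s)
            except ValueError:
                raise GenotypeFormatError(
                    f"unparseable genotype token {s!r} at row {i}, column {df.columns[j]!r}"
                ) from None
            if v not in (0.0, 1.0, 2.0):
                raise GenotypeFormatError(
                    f"genotype {s!r} not in {{0,1,2}} at row {i}, column {df.columns[j]!r}"
                )
            calls[i, j] = v
    if miss_mask.any():
        if not impute_missing:
            i, j = np.argwhere(miss_mask)[0]
            raise GenotypeFormatError(
                f"missing genotype at row {i}, column {df.columns[j]!r}; "
                "pass impute_missing=True to mean-impute"
            )
        col_mean = np.nanmean(calls, axis=0)
        # Round imputed values to the nearest legal call so downstream coding
        # ({-1,0,1} / heterozygote indicator) stays well defined.
        for i, j in np.argwhere(miss_mask):
            calls[i, j] = np.clip(np.rint(col_mean[j]), 0, 2)
    return calls.astype(np.int8)


def read_genotypes(
    path,
    format: str = "delimited",
    missing: str | None = "NA",
    impute_missing: bool = False,
) -> GenotypeMatrix:
    """Load a genotype panel from a PLINK ``.raw`` export or a delimited matrix.

    ``plink_raw``: whitespace-delimited with a header row; the first six
    columns are FID/IID/PAT/MAT/SEX/PHENOTYPE and the remaining columns are
    0/1/2 calls. ``delimited``: first column sample ID, header row of marker
    IDs, comma or tab separated.

    Missing tokens are rejected unless ``impute_missing`` is set, in which
    case they are filled with the marker mean rounded to a legal call.
    """
    if format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        meta = [c for c in df.columns if c.upper() in _PLINK_RAW_META]
        if len(meta) < 2 or "IID" not in [c.upper() for c in meta]:
            raise GenotypeFormatError("not a PLINK .raw file: missing FID/IID header")
        samples = df["IID"].astype(str).tolist()
        geno = df.drop(columns=meta)
    elif format == "delimited":
        with open(path) as fh:
            first = fh.readline()
        sep = "," if first.count(",") >= first.count("\t") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
        samples = [str(s) for s in df.index]
        geno = df
    else:
        raise ValueError(f"unknown format {format!r}")
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicate sample IDs in {path}")
    calls = _parse_calls(geno, missing, impute_missing)
    return GenotypeMatrix(samples=samples, markers=[str(m) for m in geno.columns], calls=calls)


def write_genotypes(g: GenotypeMatrix, path, sep: str = "\t") -> None:
    """Write a panel as a delimited matrix (sample IDs in the first column)."""
    pd.DataFrame(g.calls, index=g.samples, columns=g.markers).to_csv(path, sep=sep)


def simulate_genotypes(
    n_samples: int,
    n_markers: int,
    maf_law=(0.01, 0.5),
    n_families: int = 0,
    seed: int = 0,
    block_size: int = 50,
) -> GenotypeMatrix:
    """Simulate a diploid biallelic panel with a spread of allele frequencies.

    ``maf_law`` is either a ``(low, high)`` uniform range in (0, 0.5] or a
    callable ``rng -> p`` drawing one frequency. With ``n_families == 0``
    each sample draws two independent allele copies per marker (binomial).
    With ``n_families > 0`` samples are split into families that share four
    founder haplotypes; each sample inherits, per block of ``block_size``
    markers, one haplotype from each founder pair, giving block-structured
    within-family relatedness.
    """
    if n_samples < 2:
        raise ValueError("need n_samples >= 2")
    rng = np.random.default_rng(seed)
    if callable(maf_law):
        p = np.array([maf_law(rng) for _ in range(n_markers)], dtype=float)
    else:
        low, high = maf_law
        if not (0.0 < low <= high <= 0.5):
            raise ValueError(f"maf_law range must lie in (0, 0.5], got ({low}, {high})")
        p = rng.uniform(low, high, size=n_markers) if low < high else np.full(n_markers, low)
    if np.all(p <= 0):
        raise ValueError("degenerate maf_law: all mass at frequency 0")

    samples = [f"s{i:04d}" for i in range(n_samples)]
    markers = [f"m{j:05d}" for j in range(n_markers)]

    if n_families <= 0:
        calls = rng.binomial(2, p, size=(n_samples, n_markers))
        return GenotypeMatrix(samples, markers, calls, allele_freq=None)

    fam_of = np.arange(n_samples) % n_families
    n_blocks = int(np.ceil(n_markers / block_size))
    calls = np.empty((n_samples, n_markers), dtype=np.int8)
    for f in range(n_families):
        members = np.flatnonzero(fam_of == f)
        # four founder haplotypes (sire pair, dam pair) per family
        founders = rng.binomial(1, p, size=(4, n_markers))
        for i in members:
            pick_s = rng.integers(0, 2, size=n_blocks)
            pick_d = rng.integers(0, 2, size=n_blocks) + 2
            hap1 = np.concatenate(
                [founders[pick_s[b], b * block_size : (b + 1) * block_size] for b in range(n_blocks)]
            )
            hap2 = np.concatenate(
                [founders[pick_d[b], b * block_size : (b + 1) * block_size] for b in range(n_blocks)]
            )
            calls[i] = hap1 + hap2
    return GenotypeMatrix(samples, markers, calls, allele_freq=None)


def _maf_mask(maf: np.ndarray, strategy: str) -> np.ndarray:
    if strategy == "gt1pct":
        return maf > 0.01
    if strategy == "gt5pct":
        return maf > 0.05
    if strategy == "rare_1to5pct":
        return (maf > 0.01) & (maf <= 0.05)
    raise ValueError(f"unknown MAF strategy {strategy!r}; choose from {MAF_STRATEGIES}")


def filter_by_maf(g: GenotypeMatrix, strategy: str) -> GenotypeMatrix:
    """Return the marker subset passing a MAF strategy (samples unchanged).

    Allele frequencies on the result are recomputed from the retained calls,
    so downstream kinship centering uses subset frequencies.
    """
    keep = _maf_mask(g.maf, strategy)
    if not keep.any():
        raise ValueError(f"no markers survive MAF filter {strategy!r}")
    return GenotypeMatrix(
        samples=list(g.samples),
        markers=[m for m, k in zip(g.markers, keep) if k],
        calls=g.calls[:, keep],
        allele_freq=None,
    )


def panel_summary(g: GenotypeMatrix) -> dict:
    """Mean/SD of per-marker MAF and the overall heterozygous-call fraction."""
    maf = g.maf
    return {
        "n_samples": g.n_samples,
        "n_markers": g.n_markers,
        "mean_maf": float(maf.mean()),
        "sd_maf": float(maf.std()),
        "heterozygosity": float((g.calls == 1).mean()),
    }
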