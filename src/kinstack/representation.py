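"""Kinship-image representation: sample seriation, 3D stack, 2D slices.

The 15 kinship matrices are reordered for data locality and stacked into an
``n x n x 15`` tensor ("polyhedron"). Each sample contributes one 2D slice
— its kinship row against a reference sample set across all 15 channels —
which is treated as a single-channel grayscale image by the CNN.

Sample ordering comes from average-linkage hierarchical clustering of the
dissimilarity ``d(i, j) = 1 - K[i, j] / sqrt(K[i, i] K[j, j])`` computed on
the MAF>5% additive kinship (the reference matrix); the dendrogram leaf
order is the permutation, and all channels are sorted by it.

Held-out samples reuse the training-sample columns as reference so slice
width matches the trained network; no validation phenotype is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .kinship import KinshipMatrix

__all__ = [
    "KinshipStack",
    "SampleSlice",
    "optimal_sample_order",
    "build_stack",
    "slice_for_sample",
    "slices_for_samples",
    "augment",
    "save_stack",
    "load_stack",
]


@dataclass
class KinshipStack:
    """n x n x 15 tensor of reordered kinship channels."""

    tensor: np.ndarray
    channel_labels: list[tuple[str, str]]  # (maf_tag, rel_type)
    samples: list[str]                     # in stack (permuted) order
    sample_order: np.ndarray               # permutation of original indices

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        n = self.tensor.shape[0]
        if self.tensor.ndim != 3 or self.tensor.shape[0] != self.tensor.shape[1]:
            raise ValueError("stack tensor must be n x n x channels")
        if self.tensor.shape[2] != len(self.channel_labels):
            raise ValueError("channel label count does not match tensor depth")
        if len(self.samples) != n:
            raise ValueError("sample labels do not match tensor size")
        order = np.asarray(self.sample_order)
        if sorted(order.tolist()) != list(range(n)):
            raise ValueError("sample_order is not a valid permutation")

    @property
    def n(self) -> int:
        return self.tensor.shape[0]

    def row_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in stack") from None


@dataclass
class SampleSlice:
    """One sample's kinship image: reference samples x 15 channels."""

    image: np.ndarray
    sample_id: str
    reference_ids: list[str]

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.shape[0] != len(self.reference_ids):
            raise ValueError("image rows do not match reference set size")


def optimal_sample_order(ka: KinshipMatrix) -> np.ndarray:
    """Dendrogram leaf order of the reference additive kinship.

    Converts kinship to a correlation-like dissimilarity, runs
    average-linkage agglomerative clustering, and returns the leaf order.
    Deterministic for a fixed input.
    """
    k = ka.values
    if np.abs(k - k.T).max() > 1e-10:
        raise ValueError("kinship must be symmetric")
    diag = np.diag(k).copy()
    # guard: self-kinship should be positive; fall back to 1 for degenerate rows
    diag[diag <= 0] = 1.0
    norm = np.sqrt(np.outer(diag, diag))
    d = 1.0 - k / norm
    np.fill_diagonal(d, 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    return np.asarray(leaves_list(z), dtype=int)


def build_stack(kinships: list[KinshipMatrix], order=None) -> KinshipStack:
    """Permute every channel by one sample order and stack to n x n x 15."""
    if len(kinships) != 15:
        raise ValueError(f"expected 15 kinship matrices, got {len(kinships)}")
    samples = kinships[0].samples
    for k in kinships:
        if k.samples != samples:
            raise ValueError("kinship matrices have inconsistent sample sets")
    n = len(samples)
    order = np.arange(n) if order is None else np.asarray(order, dtype=int)
    tensor = np.stack([k.values[np.ix_(order, order)] for k in kinships], axis=2)
    return KinshipStack(
        tensor=tensor,
        channel_labels=[(k.maf_tag or "", k.rel_type) for k in kinships],
        samples=[samples[i] for i in order],
        sample_order=order,
    )


def slice_for_sample(stack: KinshipStack, sample_id: str, reference_ids=None) -> SampleSlice:
    """Extract one sample's (n_ref x 15) kinship image.

    Reference rows follow stack order when ``reference_ids`` is None (all
    samples); otherwise the given order is used.
    """
    row = stack.row_index(sample_id)
    refs = list(stack.samples) if reference_ids is None else list(reference_ids)
    ref_rows = [stack.row_index(r) for r in refs]
    image = stack.tensor[row, ref_rows, :]
    return SampleSlice(image=image, sample_id=sample_id, reference_ids=refs)


def slices_for_samples(stack: KinshipStack, sample_ids, reference_ids=None) -> np.ndarray:
    """Batch of kinship images, shape (len(sample_ids), n_ref, 15)."""
    return np.stack(
        [slice_for_sample(stack, s, reference_ids).image for s in sample_ids], axis=0
    )


def augment(slices: np.ndarray, labels: np.ndarray, reps: int = 1, sigma: float = 0.1, seed=0):
    """Originals plus ``reps`` noisy copies (elementwise Gaussian, SD sigma).

    Labels are duplicated alongside. ``reps=0`` returns the inputs unchanged.
    """
    if reps < 0:
        raise ValueError("reps must be >= 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    slices = np.asarray(slices, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if reps == 0:
        return slices, labels
    rng = np.random.default_rng(seed)
    copies = [slices]
    for _ in range(reps):
        copies.append(slices + rng.normal(0.0, sigma, size=slices.shape))
    return np.concatenate(copies, axis=0), np.tile(labels, reps + 1)


def save_stack(stack: KinshipStack, path) -> None:
    """Persist to HDF5: one dataset for the tensor, attributes for metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("tensor", data=stack.tensor)
        f.attrs["channel_labels"] = [f"{t}:{r}" for t, r in stack.channel_labels]
        f.attrs["samples"] = stack.samples
        f.attrs["sample_order"] = stack.sample_order


def load_stack(path) -> KinshipStack:
    with h5py.File(path, "r") as f:
        tensor = f["tensor"][...]
        labels = [tuple(s.split(":")) for s in f.attrs["channel_labels"]]
        samples = [str(s) for s in f.attrs["samples"]]
        order = np.asarray(f.attrs["sample_order"], dtype=int)
    return KinshipStack(tensor, labels, samples, order)
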