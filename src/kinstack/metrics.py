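"""Prediction-quality metrics: Pearson correlation, RMSE, NDCG and bias.

All metrics compare a vector of true phenotypes ``y`` against predictions
``yhat`` on a validation set; phenotypes are assumed standardized upstream
so values are directly comparable across models and scenarios.

NDCG ranks by *descending* true value (higher phenotypes are desirable).
``DCG(y, yhat) = sum_i yhat[rank_i] / log2(i + 1)`` where ``rank_i`` walks
the samples in descending order of ``y`` (1-based ``i``), and
``NDCG = DCG(y, yhat) / DCG(y, y)``. With non-negative gains NDCG is
bounded above by 1; standardized phenotypes can be negative, in which case
the formula is computed verbatim (no clipping) and a near-zero ideal DCG is
flagged as undefined.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["pearson", "rmse", "ndcg", "prediction_bias", "MetricUndefinedError"]


class MetricUndefinedError(ValueError):
    """Raised when a metric is undefined for the given inputs (reported as
    missing, never silently coerced to a number)."""


def _check_lengths(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"length mismatch: y {y.shape} vs yhat {yhat.shape}")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean squared error, sqrt(mean((y - yhat)^2))."""
    y, yhat = _check_lengths(y, yhat)
    if y.size < 1:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def pearson(y, yhat) -> float:
    """Product-moment correlation; raises if either vector has zero variance."""
    y, yhat = _check_lengths(y, yhat)
    if y.std() == 0.0 or yhat.std() == 0.0:
        raise MetricUndefinedError("Pearson undefined: zero-variance input")
    return float(np.corrcoef(y, yhat)[0, 1])


def ndcg(y, yhat) -> float:
    """Normalized discounted cumulative gain over the descending-y ranking.

    Ties in ``y`` are broken by original index order (stable sort).
    """
    y, yhat = _check_lengths(y, yhat)
    if y.size < 2:
        raise ValueError("need at least two samples")
    order = np.argsort(-y, kind="stable")
    discounts = np.log2(np.arange(1, y.size + 1) + 1.0)
    ideal = float(np.sum(y[order] / discounts))
    if abs(ideal) < 1e-9:
        raise MetricUndefinedError("NDCG undefined: ideal DCG is (near) zero")
    dcg = float(np.sum(yhat[order] / discounts))
    return dcg / ideal


def prediction_bias(replicate_predictions, y_true) -> float:
    """Mean over samples of (mean prediction across replicates - truth).

    ``replicate_predictions`` is a list of prediction vectors over the same
    samples; missing coverage is marked with NaN. Samples with no replicate
    coverage are excluded with a warning.
    """
    y_true = np.asarray(y_true, dtype=float)
    preds = np.asarray(replicate_predictions, dtype=float)
    if preds.ndim == 1:
        preds = preds[None, :]
    if preds.shape[1] != y_true.size:
        raise ValueError("replicate predictions do not match y_true length")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_pred = np.nanmean(preds, axis=0)
    covered = ~np.isnan(mean_pred)
    if not covered.all():
        warnings.warn(
            f"{(~covered).sum()} sample(s) without replicate coverage excluded from bias",
            stacklevel=2,
        )
    if not covered.any():
        raise MetricUndefinedError("no sample has replicate coverage")
    return float(np.mean(mean_pred[covered] - y_true[covered]))
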