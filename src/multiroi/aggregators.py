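"""Weighted-mean aggregation of per-ROI summaries into one value per sample.

Five strategies are supported, identified by name:

========  ==============================================================
name      per-ROI weight on K_hat_ir(t)
========  ==============================================================
mean      1 (arithmetic mean)
diggle    n_ir               (cell count)
baddeley  n_ir^2
landau    n_ir^2 / A_ir, rescaled by (sum_r A_ir) / (sum_r n_ir)^2
none      no pooling: the per-ROI summaries are passed through unchanged
========  ==============================================================

All weighted variants are convex combinations of the per-ROI values and are
invariant to rescaling the weights; when the per-ROI intensities n_ir / A_ir
are equal, ``diggle``, ``baddeley``, and ``landau`` coincide.

``none`` is retained only as a diagnostics baseline; treating ROIs as
independent observations badly inflates type I error in association testing.
"""

from __future__ import annotations

import numpy as np

from .data_model import ROISummary, SampleSummarySet
from .errors import DegenerateWeightsError

__all__ = ["AGGREGATORS", "aggregation_weights", "aggregate"]

AGGREGATORS = ("mean", "diggle", "baddeley", "landau", "none")


def aggregation_weights(
    method: str, counts: np.ndarray, areas: np.ndarray | None = None
) -> np.ndarray:
    """Unnormalised per-ROI weights for a named aggregation method.

    For ``landau`` the leading factor (sum A) / (sum n)^2 is a constant across
    ROIs and cancels in the weighted mean, so the weights reduce to n^2 / A.
    """
    counts = np.asarray(counts, dtype=float)
    if method == "mean":
        return np.ones_like(counts)
    if method == "diggle":
        return counts
    if method == "baddeley":
        return counts**2
    if method == "landau":
        if areas is None:
            raise ValueError("landau weights require per-ROI areas")
        areas = np.asarray(areas, dtype=float)
        if np.any(areas <= 0):
            raise ValueError("areas must be positive for landau weights")
        return counts**2 / areas
    raise ValueError(f"unknown aggregation method {method!r}; choose from {AGGREGATORS}")


def weighted_mean(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted mean along the first (ROI) axis; rejects degenerate weights."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise DegenerateWeightsError("aggregation weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise DegenerateWeightsError("aggregation weights sum to zero")
    return np.tensordot(weights, np.asarray(values, dtype=float), axes=(0, 0)) / total


def aggregate(summary_set: SampleSummarySet, method: str):
    """Aggregate one sample's ROI summaries into a single summary per radius.

    Returns an :class:`~multiroi.data_model.ROISummary` holding the
    aggregated curve (with the pooled cell count and area as metadata), or
    the untouched :class:`~multiroi.data_model.SampleSummarySet` when
    ``method == "none"``.
    """
    if method == "none":
        return summary_set
    counts = summary_set.counts()
    areas = summary_set.areas()
    w = aggregation_weights(method, counts, areas)
    value = weighted_mean(summary_set.values_matrix(), w)
    first = summary_set.summaries[0]
    return ROISummary(
        radii=summary_set.radii,
        value=value,
        n_cells=int(counts.sum()),
        area=float(areas.sum()),
        sample_id=summary_set.sample_id,
        roi_id=f"<{method} of {len(summary_set)} ROIs>",
        statistic=first.statistic,
        marks=first.marks,
    )
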