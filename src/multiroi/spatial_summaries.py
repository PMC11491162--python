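"""Ripley's K (univariate and bivariate) with edge correction, and Besag's L.

Estimators
----------
Univariate, for cells of phenotype ``a`` in one ROI::

    K_hat(t) = (A / n_a^2) * sum_{j != j'} (1 / w_jj') * 1(d_jj' <= t)

Bivariate (cross) K between phenotypes ``a`` and ``b``::

    K_hat_ab(t) = (A / (n_a * n_b)) * sum_{j in a} sum_{j' in b}
                  (1 / w_jj') * 1(d_jj' <= t)

where ``w`` is an edge-correction factor in (0, 1]:

- ``"isotropic"`` (default): the fraction of the circumference of the circle
  centred at the first point of the pair, with radius equal to the pair
  distance, that lies inside the rectangular window.  Valid for pair
  distances below half of the shorter window side.
- ``"translation"``: overlap fraction of the window with itself translated
  by the pair's displacement vector.
- ``"none"``: w = 1 (no correction).

Besag's L is the variance-stabilising transform ``L(t) = sqrt(K(t) / pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import PointPattern, ROISummary, Window
from .errors import InsufficientDataError

__all__ = [
    "RadiusGrid",
    "default_radius_grid",
    "ripley_k_univariate",
    "ripley_k_bivariate",
    "besag_l",
    "summaries_to_frame",
]

CORRECTIONS = ("isotropic", "translation", "none")


@dataclass(frozen=True)
class RadiusGrid:
    """A strictly increasing grid of radii (microns) at which K/L is evaluated."""

    radii: np.ndarray
    rule: str = "explicit"

    def __post_init__(self):
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))
        if self.radii.ndim != 1 or len(self.radii) < 1:
            raise ValueError("radius grid must be a non-empty 1-D array")
        if self.radii[0] < 0 or np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be non-negative and strictly increasing")

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def r_max(self) -> float:
        return float(self.radii[-1])


def default_radius_grid(
    patterns: Sequence[PointPattern], n_radii: int = 100
) -> RadiusGrid:
    """Quarter-of-shortest-side rule: ``n_radii`` even radii on [0, r_max].

    ``r_max`` is one quarter of the smallest window side across all ROIs,
    the conventional default for rectangular windows.
    """
    if len(patterns) == 0:
        raise ValueError("need at least one pattern to build a radius grid")
    if n_radii < 2:
        raise ValueError("n_radii must be at least 2")
    r_max = min(p.window.shorter_side for p in patterns) / 4.0
    return RadiusGrid(np.linspace(0.0, r_max, n_radii), rule="ripley_quarter")


def _isotropic_weights(
    cx: np.ndarray, cy: np.ndarray, r: np.ndarray, window: Window
) -> np.ndarray:
    """Fraction of the circle (centre (cx, cy), radius r) inside the window.

    Uses the nearest vertical and nearest horizontal edge, which is exact
    while r < shorter_side / 2 (a circle can then reach at most two
    adjacent edges).
    """
    dx = np.minimum(cx - window.x_min, window.x_max - cx)
    dy = np.minimum(cy - window.y_min, window.y_max - cy)
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.arccos(np.minimum(dx / r, 1.0))
        a2 = np.arccos(np.minimum(dy / r, 1.0))
    corner = r * r > dx * dx + dy * dy
    exterior = np.where(corner, a1 + a2 + np.pi / 2, 2 * a1 + 2 * a2)
    frac = 1.0 - exterior / (2 * np.pi)
    # a zero-radius "circle" is entirely inside
    return np.where(r == 0, 1.0, frac)


def _translation_weights(
    dx: np.ndarray, dy: np.ndarray, window: Window
) -> np.ndarray:
    """Overlap fraction of the window with its copy shifted by (dx, dy)."""
    w = (window.width - np.abs(dx)) * (window.height - np.abs(dy))
    return w / window.area


def _check_isotropic_range(radii: RadiusGrid, window: Window) -> None:
    if radii.r_max >= window.shorter_side / 2:
        raise ValueError(
            "isotropic correction needs radii below half the shorter window "
            f"side ({window.shorter_side / 2:g}); use correction='translation' "
            "for larger radii"
        )


def _pair_k(
    ax, ay, bx, by, keep, radii: RadiusGrid, window: Window, correction: str, norm: float
) -> np.ndarray:
    """K curve from the ordered pairs selected by the boolean matrix ``keep``.

    Only pairs within the largest grid radius contribute; edge-correction
    weights are evaluated at the pair distance.  Distance ties at exactly
    d = t count as within radius (the indicator uses <=).
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}; choose from {CORRECTIONS}")
    dx = ax[:, None] - bx[None, :]
    dy = ay[:, None] - by[None, :]
    d = np.hypot(dx, dy)
    keep = keep & (d <= radii.r_max)
    d_sel = d[keep]
    if correction == "none":
        contrib = np.ones_like(d_sel)
    elif correction == "translation":
        contrib = 1.0 / _translation_weights(dx[keep], dy[keep], window)
    else:
        _check_isotropic_range(radii, window)
        cx = np.broadcast_to(ax[:, None], d.shape)[keep]
        cy = np.broadcast_to(ay[:, None], d.shape)[keep]
        contrib = 1.0 / _isotropic_weights(cx, cy, d_sel, window)
    order = np.argsort(d_sel, kind="stable")
    csum = np.concatenate([[0.0], np.cumsum(contrib[order])])
    idx = np.searchsorted(d_sel[order], radii.radii, side="right")
    return norm * csum[idx]


def ripley_k_univariate(
    pattern: PointPattern,
    mark,
    radii: RadiusGrid,
    correction: str = "isotropic",
) -> ROISummary:
    """Ripley's K for a single phenotype on one ROI.

    Requires at least two cells of the phenotype; callers should have
    filtered low-count ROIs beforehand (:func:`~multiroi.data_model.filter_low_count_rois`).
    """
    pts = pattern.coords(mark)
    n = len(pts)
    if n < 2:
        raise InsufficientDataError(
            f"need >= 2 cells of mark {mark!r} (got {n}) in ROI "
            f"{pattern.roi_id!r} of sample {pattern.sample_id!r}"
        )
    x, y = pts[:, 0], pts[:, 1]
    off = ~np.eye(n, dtype=bool)
    A = pattern.window.area
    value = _pair_k(x, y, x, y, off, radii, pattern.window, correction, A / (n * n))
    return ROISummary(
        radii=radii.radii,
        value=value,
        n_cells=n,
        area=A,
        sample_id=pattern.sample_id,
        roi_id=pattern.roi_id,
        statistic="K",
        marks=(mark,),
    )


def ripley_k_bivariate(
    pattern: PointPattern,
    mark_a,
    mark_b,
    radii: RadiusGrid,
    correction: str = "isotropic",
) -> ROISummary:
    """Cross-type (bivariate) Ripley's K between two phenotypes on one ROI.

    ``n_cells`` on the returned summary is the combined count of the two
    phenotypes, the quantity used as the aggregation weight downstream.
    """
    pa = pattern.coords(mark_a)
    pb = pattern.coords(mark_b)
    na, nb = len(pa), len(pb)
    if na == 0 or nb == 0:
        raise InsufficientDataError(
            f"need >= 1 cell of each mark ({mark_a!r}: {na}, {mark_b!r}: {nb}) "
            f"in ROI {pattern.roi_id!r} of sample {pattern.sample_id!r}"
        )
    ax, ay = pa[:, 0], pa[:, 1]
    bx, by = pb[:, 0], pb[:, 1]
    keep = np.ones((na, nb), dtype=bool)
    A = pattern.window.area
    value = _pair_k(ax, ay, bx, by, keep, radii, pattern.window, correction, A / (na * nb))
    return ROISummary(
        radii=radii.radii,
        value=value,
        n_cells=na + nb,
        area=A,
        sample_id=pattern.sample_id,
        roi_id=pattern.roi_id,
        statistic="K",
        marks=(mark_a, mark_b),
    )


def besag_l(k_summary: ROISummary) -> ROISummary:
    """Besag's L transform: ``L(t) = sqrt(K(t) / pi)``, metadata preserved."""
    if np.any(k_summary.value < 0):
        raise ValueError("Besag's L requires non-negative K values")
    return ROISummary(
        radii=k_summary.radii,
        value=np.sqrt(k_summary.value / np.pi),
        n_cells=k_summary.n_cells,
        area=k_summary.area,
        sample_id=k_summary.sample_id,
        roi_id=k_summary.roi_id,
        statistic="L",
        marks=k_summary.marks,
    )


def summaries_to_frame(summaries) -> "pd.DataFrame":
    """Long-format export: one row per (ROI, radius)."""
    import pandas as pd

    rows = []
    for s in summaries:
        for t, v in zip(s.radii, s.value):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "roi_id": s.roi_id,
                    "statistic": s.statistic,
                    "marks": "|".join(str(m) for m in s.marks),
                    "radius": t,
                    "value": v,
                    "n_cells": s.n_cells,
                    "area": s.area,
                }
            )
    return pd.DataFrame(rows)
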