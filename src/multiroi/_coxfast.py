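"""Vectorised single-covariate Cox regression (Newton-Raphson, Breslow ties).

The simulation study and ensemble tests need hundreds of thousands of Cox
fits, each with a single predictor and no adjustment covariates.  Fitting
them one at a time with a general-purpose library dominates the runtime, so
this module solves many such models simultaneously: the predictor matrix has
one column per model, all sharing the same (time, event) data.  Agreement
with lifelines' CoxPHFitter is asserted in the test suite; covariate-adjusted
models go through lifelines directly (see :mod:`multiroi.association`).
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

__all__ = ["cox_wald_pvalues"]

_MAX_ABS_BETA = 50.0  # standardized scale; beyond this the likelihood is monotone


def _revcumsum(a: np.ndarray) -> np.ndarray:
    """Suffix sums along axis 0: out[i] = sum_{j >= i} a[j]."""
    return np.cumsum(a[::-1], axis=0)[::-1]


def cox_wald_pvalues(
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-9,
):
    """Fit one Cox model per column of ``X``; return Wald statistics.

    Parameters
    ----------
    times, events
        Shared survival data: positive times and 0/1 event indicators.
    X
        (n, B) predictor matrix; column b is the sole covariate of model b.

    Returns
    -------
    beta, se, p : arrays of shape (B,)
        Coefficient, standard error, and two-sided Wald p-value per column.
        Columns with a constant predictor or a non-converged fit yield NaN.

    Notes
    -----
    Tied event times are handled with the Breslow approximation.  Simulated
    exponential times are almost surely tie-free, so the choice only matters
    for the "no aggregation" strategy where sample outcomes are duplicated
    across ROIs.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2 or X.shape[0] != len(times):
        raise ValueError("X must be (n, B) with n matching times")
    n, B = X.shape

    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    Xs = X[order]

    # Breslow risk sets: rows in a tie group share the suffix sum taken at
    # the group's first index.
    _, first, inverse = np.unique(t, return_index=True, return_inverse=True)
    gs = first[inverse]
    ev = e == 1
    if not ev.any():
        raise ValueError("need at least one event")

    mu = Xs.mean(axis=0)
    sd = Xs.std(axis=0)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)
    Z = (Xs - mu) / sd_safe

    beta = np.zeros(B)
    info = np.full(B, np.nan)
    converged = np.zeros(B, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(Z * beta, -500, 500)
        w = np.exp(eta)
        zw = Z * w
        s0 = _revcumsum(w)[gs]
        s1 = _revcumsum(zw)[gs]
        s2 = _revcumsum(Z * zw)[gs]
        m1 = s1 / s0
        score = (Z[ev] - m1[ev]).sum(axis=0)
        info = (s2[ev] / s0[ev] - m1[ev] ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 0, score / info, 0.0)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + np.where(converged, 0.0, step)
        newly = np.abs(step) < tol
        converged |= newly
        if np.all(converged | degenerate | (np.abs(beta) > _MAX_ABS_BETA)):
            break

    bad = degenerate | ~converged | (np.abs(beta) > _MAX_ABS_BETA) | (info <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se_std = 1.0 / np.sqrt(info)
    zstat = beta / se_std
    p = 2.0 * ndtr(-np.abs(zstat))
    beta_out = np.where(bad, np.nan, beta / sd_safe)
    se_out = np.where(bad, np.nan, se_std / sd_safe)
    p = np.where(bad, np.nan, p)
    return beta_out, se_out, p
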