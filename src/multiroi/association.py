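"""Association tests between per-sample aggregated summaries and outcomes.

``test_fixed_radius`` relates a scalar summary per sample to a survival
endpoint (Cox proportional hazards, lifelines) or a binary endpoint
(logistic regression, statsmodels), reporting the two-sided Wald p-value of
the summary coefficient with covariates entered additively.

``spot_test`` is the radius-omnibus wrapper: the association is tested at
every positive radius of the grid and the per-radius p-values are combined
with the (untruncated) Cauchy combination test.

For the high-volume unadjusted survival fits issued by the ensemble and
simulation machinery, ``batch_test`` dispatches to the vectorised Newton
solver in :mod:`multiroi._coxfast` (exact agreement with lifelines is
covered by the test suite).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._coxfast import cox_wald_pvalues
from .aggregators import AGGREGATORS, aggregation_weights, weighted_mean
from .data_model import OutcomeTable
from .errors import ConvergenceError, DegeneratePredictorError
from .ensemble import EnsembleConfig, cauchy_combine, ensemble_test_scalar

logger = logging.getLogger(__name__)

__all__ = ["AssociationSpec", "SpotResult", "test_fixed_radius", "batch_test", "spot_test"]


@dataclass
class AssociationSpec:
    """What outcome model to fit and which covariates to adjust for."""

    outcome_type: str = "survival"  # {"survival", "binary"}
    covariates: list = field(default_factory=list)

    def __post_init__(self):
        if self.outcome_type not in {"survival", "binary"}:
            raise ValueError("outcome_type must be 'survival' or 'binary'")


@dataclass
class SpotResult:
    """Radius-omnibus test output."""

    p_value: float
    per_radius: pd.DataFrame  # columns: radius, p_value
    aggregator: str


def _check_predictor(values: np.ndarray) -> None:
    if np.any(~np.isfinite(values)):
        raise ValueError("aggregated summary values contain non-finite entries")
    if np.ptp(values) == 0:
        raise DegeneratePredictorError("aggregated summary is constant across samples")


def _fit_cox(df: pd.DataFrame, covariates: list) -> float:
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError as LifelinesConvergence

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df[["time", "event", "value", *covariates]],
                duration_col="time",
                event_col="event",
            )
    except (LifelinesConvergence, np.linalg.LinAlgError, ValueError) as exc:
        raise ConvergenceError(f"Cox model failed to converge: {exc}") from exc
    return float(cph.summary.loc["value", "p"])


def _fit_logistic(df: pd.DataFrame, covariates: list) -> float:
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    X = sm.add_constant(df[["value", *covariates]].astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter(
                "error"
            )  # perfect separation surfaces as a warning in newer statsmodels
            res = sm.Logit(df["label"].astype(float), X).fit(disp=0, method="newton")
    except (PerfectSeparationError, np.linalg.LinAlgError, Warning) as exc:
        raise ConvergenceError(f"logistic model degenerate or non-convergent: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError("logistic model failed to converge")
    return float(res.pvalues["value"])


def test_fixed_radius(
    aggregated: pd.Series,
    outcomes: OutcomeTable,
    spec: AssociationSpec | None = None,
) -> float:
    """Wald p-value for one scalar summary per sample against the outcome.

    ``aggregated`` is indexed by sample_id; rows are aligned to the outcome
    table by that index, so the row order of either input is irrelevant.
    A repeated index is allowed (the "no aggregation" baseline duplicates
    each sample's outcome across its ROIs).
    """
    if spec is None:
        spec = AssociationSpec(outcome_type=outcomes.outcome_type)
    if spec.outcome_type != outcomes.outcome_type:
        raise ValueError(
            f"spec expects a {spec.outcome_type} outcome but the table holds "
            f"{outcomes.outcome_type}"
        )
    aggregated = pd.Series(aggregated)
    values = aggregated.to_numpy(dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 observations")
    _check_predictor(values)
    out = outcomes.aligned([str(i) for i in aggregated.index])
    df = out.reset_index(drop=True).assign(value=values)
    missing = [c for c in spec.covariates if c not in df.columns]
    if missing:
        raise ValueError(f"covariates missing from outcome table: {missing}")
    if spec.outcome_type == "survival":
        return _fit_cox(df, spec.covariates)
    return _fit_logistic(df, spec.covariates)


def batch_test(
    X: np.ndarray,
    sample_ids: list,
    outcomes: OutcomeTable,
    spec: AssociationSpec,
) -> np.ndarray:
    """P-values for each column of ``X`` tested against the shared outcome.

    Returns NaN for columns whose fit is degenerate or fails to converge.
    Unadjusted survival models use the vectorised solver; everything else
    falls back to per-column fits.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = outcomes.aligned([str(i) for i in sample_ids])
    if spec.outcome_type == "survival" and not spec.covariates:
        _, _, p = cox_wald_pvalues(
            out["time"].to_numpy(float), out["event"].to_numpy(float), X
        )
        return p
    p = np.full(X.shape[1], np.nan)
    idx = pd.Index(sample_ids)
    for b in range(X.shape[1]):
        try:
            p[b] = test_fixed_radius(pd.Series(X[:, b], index=idx), outcomes, spec)
        except (ConvergenceError, DegeneratePredictorError):
            p[b] = np.nan
    return p


def _fixed_aggregate_matrix(summary_sets: list, method: str) -> np.ndarray:
    """(n_samples, n_radii) matrix of fixed-weight aggregates."""
    rows = []
    for s in summary_sets:
        w = aggregation_weights(method, s.counts(), s.areas())
        rows.append(weighted_mean(s.values_matrix(), w))
    return np.vstack(rows)


def spot_test(
    summary_sets: list,
    outcomes: OutcomeTable,
    aggregator,
    spec: AssociationSpec | None = None,
) -> SpotResult:
    """Radius-omnibus association test.

    For every positive radius of the shared grid, aggregate each sample's
    ROI summaries (with a named fixed aggregator, an
    :class:`~multiroi.ensemble.EnsembleConfig`, or ``"none"``), test the
    per-sample values against the outcome, and combine the per-radius
    p-values with an untruncated, uniformly weighted Cauchy combination.

    Radius 0 is excluded (the summary there is degenerate) and radii whose
    test fails are dropped with a warning.  The reported p-values carry no
    multiple-testing adjustment.
    """
    if spec is None:
        spec = AssociationSpec(outcome_type=outcomes.outcome_type)
    radii = summary_sets[0].radii
    for s in summary_sets[1:]:
        if not np.array_equal(s.radii, radii):
            raise ValueError("all samples must share one radius grid")
    keep = np.flatnonzero(radii > 0)
    if keep.size == 0:
        raise ValueError("no positive radii available for SPOT")
    sample_ids = [s.sample_id for s in summary_sets]

    if isinstance(aggregator, EnsembleConfig):
        name = aggregator.method
        p = np.full(keep.size, np.nan)
        children = np.random.SeedSequence(aggregator.seed).spawn(keep.size)
        counts = [s.counts() for s in summary_sets]
        for j, idx in enumerate(keep):
            values = [s.values_matrix()[:, idx] for s in summary_sets]
            try:
                res = ensemble_test_scalar(
                    sample_ids,
                    values,
                    counts,
                    outcomes,
                    aggregator,
                    spec,
                    rng=np.random.default_rng(children[j]),
                )
                p[j] = res.p_value
            except ConvergenceError:
                p[j] = np.nan
    elif aggregator == "none":
        name = "none"
        rep_ids = [s.sample_id for s in summary_sets for _ in range(len(s))]
        V = np.vstack([s.values_matrix() for s in summary_sets])
        p = batch_test(V[:, keep], rep_ids, outcomes, spec)
    elif aggregator in AGGREGATORS:
        name = aggregator
        V = _fixed_aggregate_matrix(summary_sets, aggregator)
        p = batch_test(V[:, keep], sample_ids, outcomes, spec)
    else:
        raise ValueError(
            f"aggregator must be one of {AGGREGATORS}, an EnsembleConfig, "
            f"or 'none'; got {aggregator!r}"
        )

    ok = np.isfinite(p)
    if not ok.any():
        raise ConvergenceError("every per-radius association test failed")
    if (~ok).any():
        logger.warning("dropping %d radii with failed tests", int((~ok).sum()))
    per_radius = pd.DataFrame({"radius": radii[keep], "p_value": p})
    return SpotResult(
        p_value=cauchy_combine(p[ok]),
        per_radius=per_radius,
        aggregator=name,
    )
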