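import numpy as np
import pandas as pd
import pytest
from scipy import stats

import multiroi.association as assoc
from multiroi._coxfast import cox_wald_pvalues
from multiroi.association import AssociationSpec, batch_test, spot_test
from multiroi.association import test_fixed_radius as fixed_radius_test
from multiroi.data_model import OutcomeTable
from multiroi.ensemble import EnsembleConfig
from multiroi.errors import ConvergenceError, DegeneratePredictorError

from test_aggregators import make_set


def survival_table(rng, n, values=None, beta=0.0):
    """Exponential survival; hazard exp(1 + beta * value) when values given."""
    lin = 1.0 if values is None else 1.0 + beta * np.asarray(values)
    times = -np.log(rng.random(n)) / np.exp(lin)
    return OutcomeTable(
        pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(n)], "time": times,
             "event": np.ones(n, dtype=int)}
        )
    )


class TestFixedRadius:
    def test_survival_matches_lifelines_directly(self, rng):
        from lifelines import CoxPHFitter

        n = 80
        x = rng.standard_normal(n)
        outcomes = survival_table(rng, n, x, beta=-0.5)
        p = fixed_radius_test(pd.Series(x, index=[f"s{i}" for i in range(n)]), outcomes)
        df = outcomes.data.assign(value=x)[["time", "event", "value"]]
        expected = CoxPHFitter().fit(df, "time", "event").summary.loc["value", "p"]
        assert p == pytest.approx(expected, rel=1e-9)

    def test_survival_power_under_strong_effect(self, rng):
        hits = 0
        reps = 50
        for _ in range(reps):
            x = rng.uniform(0, 1, 100)
            outcomes = survival_table(rng, 100, x, beta=-3.0)
            p = fixed_radius_test(pd.Series(x, index=outcomes.sample_ids), outcomes)
            hits += p < 0.05
        assert hits / reps > 0.8

    def test_binary_null_calibration(self, rng):
        pvals = []
        for _ in range(200):
            labels = rng.integers(0, 2, 200)
            outcomes = OutcomeTable(
                pd.DataFrame({"sample_id": [f"s{i}" for i in range(200)], "label": labels})
            )
            x = rng.standard_normal(200)
            pvals.append(
                fixed_radius_test(pd.Series(x, index=outcomes.sample_ids), outcomes)
            )
        pvals = np.array(pvals)
        # roughly uniform: KS and rejection rate sanity checks
        assert stats.kstest(pvals, "uniform").pvalue > 1e-4
        assert 0.0 <= np.mean(pvals < 0.05) <= 0.12

    def test_covariate_adjustment_changes_p(self, rng):
        n = 120
        x = rng.standard_normal(n)
        age = rng.uniform(40, 80, n)
        outcomes = OutcomeTable(
            pd.DataFrame(
                {"sample_id": [f"s{i}" for i in range(n)],
                 "time": -np.log(rng.random(n)) / np.exp(0.05 * age - 3),
                 "event": np.ones(n, dtype=int), "age": age}
            )
        )
        s = pd.Series(x, index=outcomes.sample_ids)
        p_unadj = fixed_radius_test(s, outcomes)
        p_adj = fixed_radius_test(s, outcomes, AssociationSpec("survival", ["age"]))
        assert p_adj != p_unadj

    def test_perfect_separation_reported_as_error(self):
        n = 30
        x = np.linspace(-2, 2, n)
        outcomes = OutcomeTable(
            pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)], "label": (x > 0).astype(int)})
        )
        with pytest.raises(ConvergenceError):
            fixed_radius_test(pd.Series(x, index=outcomes.sample_ids), outcomes)

    def test_constant_predictor_rejected(self, rng):
        outcomes = survival_table(rng, 20)
        with pytest.raises(DegeneratePredictorError):
            fixed_radius_test(pd.Series(1.0, index=outcomes.sample_ids), outcomes)

    def test_row_order_of_outcome_table_irrelevant(self, rng):
        n = 40
        x = rng.standard_normal(n)
        outcomes = survival_table(rng, n, x, beta=-1.0)
        shuffled = OutcomeTable(
            outcomes.data.sample(frac=1, random_state=1).reset_index(drop=True)
        )
        s = pd.Series(x, index=[f"s{i}" for i in range(n)])
        assert fixed_radius_test(s, outcomes) == pytest.approx(
            fixed_radius_test(s, shuffled), rel=1e-12
        )

    def test_outcome_type_mismatch(self, rng):
        outcomes = survival_table(rng, 10)
        with pytest.raises(ValueError, match="binary"):
            fixed_radius_test(
                pd.Series(rng.random(10), index=outcomes.sample_ids),
                outcomes,
                AssociationSpec("binary"),
            )


class TestWaldVsLikelihoodRatio:
    def test_rejection_decisions_agree_on_large_n(self, rng):
        from lifelines import CoxPHFitter

        agree = 0
        reps = 60
        for _ in range(reps):
            n = 500
            x = rng.standard_normal(n)
            beta = rng.choice([0.0, -0.12])
            times = -np.log(rng.random(n)) / np.exp(beta * x)
            df = pd.DataFrame({"time": times, "event": 1, "value": x})
            fit = CoxPHFitter().fit(df, "time", "event")
            p_wald = fit.summary.loc["value", "p"]
            p_lrt = fit.log_likelihood_ratio_test().p_value
            agree += (p_wald < 0.05) == (p_lrt < 0.05)
        assert agree / reps >= 0.95


class TestBatchTest:
    def test_fast_path_matches_general_path(self, rng):
        n, B = 60, 4
        X = rng.standard_normal((n, B))
        outcomes = survival_table(rng, n, X[:, 0], beta=-1.0)
        ids = outcomes.sample_ids
        spec = AssociationSpec("survival")
        p_fast = batch_test(X, ids, outcomes, spec)
        p_slow = np.array(
            [fixed_radius_test(pd.Series(X[:, b], index=ids), outcomes) for b in range(B)]
        )
        np.testing.assert_allclose(p_fast, p_slow, rtol=1e-3, atol=1e-9)

    def test_coxfast_agrees_with_lifelines_with_censoring(self, rng):
        from lifelines import CoxPHFitter

        n = 120
        x = rng.standard_normal((n, 3))
        times = rng.exponential(scale=np.exp(-0.4 * x[:, 0]))
        events = (rng.random(n) < 0.7).astype(float)
        b, se, p = cox_wald_pvalues(times, events, x)
        for j in range(3):
            df = pd.DataFrame({"t": times, "e": events, "x": x[:, j]})
            fit = CoxPHFitter().fit(df, "t", "e", fit_options={"precision": 1e-10})
            assert b[j] == pytest.approx(fit.params_.iloc[0], abs=1e-7)
            assert p[j] == pytest.approx(fit.summary["p"].iloc[0], abs=1e-7)

    def test_degenerate_column_gives_nan(self, rng):
        n = 30
        outcomes = survival_table(rng, n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        p = batch_test(X, outcomes.sample_ids, outcomes, AssociationSpec("survival"))
        assert np.isnan(p[0]) and np.isfinite(p[1])


def _summary_sets(rng, n_samples=40, n_radii=4, effect=0.0):
    radii = tuple(np.linspace(0, 15, n_radii))
    sets, signal = [], rng.uniform(0, 2, n_samples)
    for i in range(n_samples):
        R = int(rng.integers(2, 5))
        vals = [signal[i] + rng.normal(0, 0.3, n_radii) for _ in range(R)]
        s = make_set(vals, rng.integers(2, 40, R), rng.uniform(1, 5, R), radii=radii)
        s.sample_id = f"s{i}"
        sets.append(s)
    return sets, signal


class TestSpot:
    def test_radius_zero_excluded(self, rng):
        sets, signal = _summary_sets(rng)
        outcomes = survival_table(rng, len(sets), signal, beta=-1.0)
        res = spot_test(sets, outcomes, "diggle")
        assert 0.0 not in set(res.per_radius["radius"])
        assert len(res.per_radius) == len(sets[0].radii) - 1

    def test_single_radius_reduces_to_fixed_test(self, rng):
        sets, signal = _summary_sets(rng, n_radii=2)  # radii (0, r): one usable
        outcomes = survival_table(rng, len(sets), signal, beta=-2.0)
        res = spot_test(sets, outcomes, "diggle")
        from multiroi.aggregators import aggregate

        vals = pd.Series(
            {s.sample_id: aggregate(s, "diggle").value[1] for s in sets}
        )
        expected = fixed_radius_test(vals, outcomes)
        if expected <= 0.5:
            # batch path converges tighter than lifelines' default precision
            assert res.p_value == pytest.approx(expected, rel=1e-3)

    def test_all_half_pvalues_give_half(self, rng, monkeypatch):
        sets, signal = _summary_sets(rng)
        outcomes = survival_table(rng, len(sets), signal)
        monkeypatch.setattr(
            assoc, "batch_test", lambda X, ids, o, s: np.full(X.shape[1], 0.5)
        )
        res = spot_test(sets, outcomes, "mean")
        assert res.p_value == pytest.approx(0.5)

    def test_failed_radii_dropped(self, rng, monkeypatch):
        sets, signal = _summary_sets(rng)
        outcomes = survival_table(rng, len(sets), signal)

        def patchy(X, ids, o, s):
            p = np.full(X.shape[1], 0.2)
            p[0] = np.nan
            return p

        monkeypatch.setattr(assoc, "batch_test", patchy)
        res = spot_test(sets, outcomes, "mean")
        assert res.p_value == pytest.approx(0.2, rel=1e-9)

    def test_ensemble_aggregator(self, rng):
        sets, signal = _summary_sets(rng, n_radii=3)
        outcomes = survival_table(rng, len(sets), signal, beta=-1.0)
        cfg = EnsembleConfig(method="combo", B=10, seed=5)
        res = spot_test(sets, outcomes, cfg)
        assert 0.0 <= res.p_value <= 1.0
        assert res.aggregator == "combo"
        res2 = spot_test(sets, outcomes, cfg)
        assert res.p_value == res2.p_value  # seeded per-radius children

    def test_none_aggregator_runs(self, rng):
        sets, signal = _summary_sets(rng, n_radii=3)
        outcomes = survival_table(rng, len(sets), signal, beta=-1.0)
        res = spot_test(sets, outcomes, "none")
        assert 0.0 <= res.p_value <= 1.0

    def test_unknown_aggregator(self, rng):
        sets, signal = _summary_sets(rng)
        outcomes = survival_table(rng, len(sets), signal)
        with pytest.raises(ValueError, match="aggregator"):
            spot_test(sets, outcomes, "median")


@pytest.mark.slow
class TestSpotNullCalibration:
    def test_omnibus_rejection_near_nominal(self, rng):
        # diggle aggregation, 20 positive radii, null data
        n_samples, n_rep = 100, 1000
        rejections = 0
        ids = [f"s{i}" for i in range(n_samples)]
        for _ in range(n_rep):
            V = rng.normal(0, 1, (n_samples, 20))
            times = rng.exponential(size=n_samples)
            outcomes = OutcomeTable(
                pd.DataFrame({"sample_id": ids, "time": times, "event": 1})
            )
            p = batch_test(V, ids, outcomes, AssociationSpec("survival"))
            from multiroi.ensemble import cauchy_combine

            rejections += cauchy_combine(p) < 0.05
        rate = rejections / n_rep
        # binomial 99% band around 0.05 at 1000 reps, widened for the
        # mild conservatism of combining correlated-by-construction p-values
        assert 0.02 <= rate <= 0.071
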