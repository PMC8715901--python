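"""Multivariate test statistics, hierarchical regressions, and orchestration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gamemarkers import (
    RoomConfig,
    SimulationConfig,
    hierarchical_regression,
    multivariate_linear_test,
    run_full_analysis,
    simulate_cohort,
    within_subject_multivariate_test,
)
from gamemarkers.inference import (
    GENDER_CODE,
    RankError,
    multivariate_stats_from_eigs,
)
from gamemarkers.markers import compute_markers
from gamemarkers.synthetic_cohort import simulate_trajectory
from gamemarkers.telemetry import Emotion, Gender, Side


def _random_mv_problem(seed, n=40, p=4):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    Y = rng.normal(size=(n, p))
    return Y, X


def _by_stat(results):
    return {r.statistic: r for r in results}


class TestMultivariateStatistics:
    @pytest.mark.parametrize("seed", range(8))
    def test_rank_one_identities(self, seed):
        """Single-df effects: Pillai + Wilks = 1, Hotelling = Roy =
        Pillai/(1-Pillai), partial eta^2 = Pillai — all four share one F."""
        Y, X = _random_mv_problem(seed)
        res = _by_stat(multivariate_linear_test(Y, X, [[0.0, 1.0, 0.0]]))
        V = res["pillai"].value
        assert V + res["wilks"].value == pytest.approx(1.0, abs=1e-12)
        assert res["hotelling"].value == pytest.approx(V / (1 - V), rel=1e-12)
        assert res["roy"].value == pytest.approx(res["hotelling"].value, rel=1e-12)
        for r in res.values():
            assert r.partial_eta_sq == pytest.approx(V, rel=1e-12)
            assert r.p == pytest.approx(res["pillai"].p, rel=1e-9)

    def test_univariate_reduction_matches_t_test(self):
        """With one response variable every statistic collapses to the
        squared t of the tested coefficient."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 2.0 + 0.5 * X[:, 1] + rng.normal(size=n)
        res = _by_stat(multivariate_linear_test(y[:, None], X, [[0.0, 1.0]]))
        fit = sm.OLS(y, X).fit()
        t2 = fit.tvalues[1] ** 2
        assert res["hotelling"].f_stat == pytest.approx(t2, rel=1e-9)
        assert res["wilks"].value == pytest.approx(1 / (1 + t2 / fit.df_resid), rel=1e-9)
        assert res["pillai"].p == pytest.approx(fit.pvalues[1], rel=1e-9)

    def test_matches_statsmodels_manova(self):
        """Cross-check the four statistics and F tests against the
        reference implementation on a shared random dataset."""
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(11)
        n, p = 50, 3
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        Y = rng.normal(size=(n, p)) + 0.4 * x1[:, None]
        X = np.column_stack([np.ones(n), x1, x2])

        mine = _by_stat(multivariate_linear_test(Y, X, [[0.0, 1.0, 0.0]]))
        mv = MANOVA(endog=Y, exog=X)
        frame = mv.mv_test(
            hypotheses=[("x1", np.array([[0.0, 1.0, 0.0]]))]
        ).results["x1"]["stat"]
        ref = {
            "wilks": frame.loc["Wilks' lambda"],
            "pillai": frame.loc["Pillai's trace"],
            "hotelling": frame.loc["Hotelling-Lawley trace"],
            "roy": frame.loc["Roy's greatest root"],
        }
        for name, r in mine.items():
            assert r.value == pytest.approx(float(ref[name]["Value"]), rel=1e-9)
            assert r.f_stat == pytest.approx(float(ref[name]["F Value"]), rel=1e-9)
            assert r.p == pytest.approx(float(ref[name]["Pr > F"]), abs=1e-12)

    def test_singular_error_matrix_raises_rank_error(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(6, 5))
        X = np.column_stack([np.ones(6), rng.normal(size=(6, 2))])
        with pytest.raises(RankError, match="error df"):
            multivariate_linear_test(Y, X, [[0.0, 1.0, 0.0]])


class TestWithinSubjectTest:
    def test_detects_a_real_emotion_shift(self):
        rng = np.random.default_rng(2)
        n, p = 60, 3
        cm = rng.normal(size=(n, 2, 2, p))
        cm[:, :, 1, :] += 1.0  # all markers shift under the angry condition
        res = _by_stat(
            r
            for r in within_subject_multivariate_test(
                cm, rng.normal(40, 10, n), rng.choice([-1.0, 1.0], n)
            )
            if r.effect == "emotion"
        )
        assert res["pillai"].p < 1e-6

    def test_null_side_effect_not_rejected_on_average(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(40):
            cm = rng.normal(size=(30, 2, 2, 2))
            res = within_subject_multivariate_test(
                cm, rng.normal(40, 10, 30), rng.choice([-1.0, 1.0], 30)
            )
            pvals.append(next(r.p for r in res if r.effect == "side"))
        assert np.mean(np.array(pvals) < 0.05) < 0.25

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            within_subject_multivariate_test(
                np.zeros((10, 3, 2, 2)), np.zeros(10), np.zeros(10)
            )


def brute_force_ols(X, y):
    """Normal equations with an explicit inverse — the independent oracle."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.inv(Xd.T @ Xd) @ Xd.T @ y
    resid = y - Xd @ beta
    df = len(y) - Xd.shape[1]
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(Xd.T @ Xd)
    return beta, np.sqrt(np.diag(cov)), df


class TestHierarchicalRegression:
    def test_matches_normal_equations_oracle(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        n = 24
        age = rng.normal(40, 10, n)
        g = rng.choice([-1.0, 1.0], n)
        x = rng.normal(2, 0.5, n)
        y = 30 + 0.5 * age + 3 * g + 9 * x + rng.normal(0, 10, n)
        res = hierarchical_regression(x, y, age, g)
        beta, se, df = brute_force_ols(np.column_stack([age, g, x]), y)
        assert res.b_unstandardized == pytest.approx(beta[3], rel=1e-9)
        t = beta[3] / se[3]
        assert res.p_predictor == pytest.approx(2 * stats.t.sf(abs(t), df), rel=1e-9)
        yhat = np.column_stack([np.ones(n), age, g, x]) @ beta
        r_sq = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        assert res.r_sq_model == pytest.approx(r_sq, rel=1e-9)
        assert res.r_model == pytest.approx(math.sqrt(r_sq), rel=1e-9)

    def test_perfect_predictor_saturates_fit(self):
        rng = np.random.default_rng(6)
        n = 40
        age = rng.normal(40, 10, n)
        g = rng.choice([-1.0, 1.0], n)
        y = rng.normal(60, 25, n)
        res = hierarchical_regression(y, y, age, g)
        assert res.r_sq_model == pytest.approx(1.0, abs=1e-12)
        assert res.b_unstandardized == pytest.approx(1.0, abs=1e-9)
        assert res.beta_standardized == pytest.approx(1.0, abs=1e-9)

    def test_beta_invariant_to_marker_rescaling(self):
        rng = np.random.default_rng(7)
        n = 50
        age, g = rng.normal(40, 10, n), rng.choice([-1.0, 1.0], n)
        x = rng.normal(2, 0.5, n)
        y = 50 + 8 * x + rng.normal(0, 15, n)
        a = hierarchical_regression(x, y, age, g)
        b = hierarchical_regression(100 * x + 7, y, age, g)
        assert b.beta_standardized == pytest.approx(a.beta_standardized, rel=1e-9)
        assert b.b_unstandardized == pytest.approx(a.b_unstandardized / 100, rel=1e-9)
        assert math.copysign(1, a.beta_standardized) == math.copysign(
            1, a.b_unstandardized
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="insufficient df"):
            hierarchical_regression([1, 2, 3], [1, 2, 3], [1, 2, 3], [1, -1, 1])
        n = 10
        with pytest.raises(ValueError, match="zero variance"):
            hierarchical_regression(
                np.ones(n), np.arange(n), np.arange(n), np.resize([1.0, -1.0], n)
            )


class TestParameterRecovery:
    def test_noise_free_simulation_recovers_configured_slopes(self, room):
        """Regressing extracted markers on the latent trait returns the
        configured trait effects to numerical precision."""
        cfg = SimulationConfig(seed=0).noise_free()
        rng = np.random.default_rng(0)
        zs = np.linspace(-2.0, 2.0, 9)
        ipd, mind = [], []
        for z in zs:
            t = simulate_trajectory(
                z, 1, (Side.RIGHT, Emotion.FRIENDLY, "alpha"), cfg, rng
            )
            ms = compute_markers(t, room)
            ipd.append(ms.ipd_m)
            mind.append(ms.min_dist_m)
        A = np.column_stack([np.ones_like(zs), zs])
        slope_ipd = np.linalg.lstsq(A, np.array(ipd), rcond=None)[0][1]
        slope_clr = np.linalg.lstsq(A, np.array(mind), rcond=None)[0][1]
        assert slope_ipd == pytest.approx(cfg.ipd_slope_m, abs=1e-6)
        assert slope_clr == pytest.approx(cfg.clearance_slope_m, abs=1e-6)


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(SimulationConfig(n_participants=24, seed=31))


class TestFullAnalysis:
    def test_report_structure(self, cohort):
        rep = run_full_analysis(cohort)
        assert set(rep.regressions["marker"]) == {
            "ipd_m", "time_in_room_s", "path_length_m", "min_dist_m",
            "mean_dist_m", "dist_skew", "dist_kurtosis",
        }
        assert set(rep.mancova["effect"]) == {
            "intercept", "age", "gender", "emotion", "side"
        }
        assert ((rep.regressions["R_sq"] >= 0) & (rep.regressions["R_sq"] <= 1)).all()
        assert np.allclose(rep.regressions["R"], np.sqrt(rep.regressions["R_sq"]))

    def test_non_binary_excluded_from_models_only(self, cohort):
        rep = run_full_analysis(cohort)
        n_nb = sum(1 for r in cohort if r.gender is Gender.NON_BINARY)
        assert (rep.regressions["n_used"] == len(cohort) - n_nb).all()
        assert sorted(rep.exclusions["non_binary"]) == sorted(
            r.participant_id for r in cohort if r.gender is Gender.NON_BINARY
        )

    def test_incomplete_participant_dropped(self, cohort):
        import copy

        broken = copy.deepcopy(cohort)
        del broken[0].trials[0]
        rep = run_full_analysis(broken)
        assert broken[0].participant_id in rep.exclusions["incomplete"]
        assert rep.n_participants == len(cohort) - 1

    def test_holm_correction_flag(self, cohort):
        rep = run_full_analysis(cohort, holm=True)
        assert "p_predictor_holm" in rep.regressions.columns
        assert (rep.regressions["p_predictor_holm"] >= rep.regressions["p_predictor"] - 1e-12).all()
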