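import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from mapr import (
    EstimationError,
    ValueFunction,
    fit_clogit_pairs,
    fit_mapr,
    fit_rasch_cml,
    fit_rasch_jml,
    loglik_and_gradient,
    sample_population,
    simulate_mapr_responses,
)
from mapr.estimation import log_esf
from tests.conftest import SPANNING_STATES


def central_fd_grad(f, x, h=1e-6):
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def rasch_matrix(v, theta, seed):
    rng = np.random.default_rng(seed)
    p = expit(v[None, :] - theta[:, None])
    return (rng.random(p.shape) < p).astype(float)


# ----------------------------------------------------------------------


class TestElementarySymmetric:
    def test_matches_polynomial_convolution_oracle(self):
        rng = np.random.default_rng(1)
        for J in (1, 3, 8, 15):
            v = rng.normal(scale=2, size=J)
            eps = np.exp(v)
            coeffs = np.array([1.0])
            for e in eps:
                # multiply by (1 + eps_j x); coefficient of x^r is esf_r
                coeffs = np.convolve(coeffs, [1.0, e])
            oracle = coeffs
            got = np.exp(log_esf(v))
            assert got == pytest.approx(oracle, rel=1e-10)


class TestClogitPairs:
    def test_two_state_closed_form(self):
        pairs = pd.DataFrame(
            {"winner": ["s"] * 30 + ["t"] * 10, "loser": ["t"] * 30 + ["s"] * 10}
        )
        fit = fit_clogit_pairs(pairs)
        diff = fit.estimates["v"]["s"] - fit.estimates["v"]["t"]
        assert diff == pytest.approx(np.log(3.0), abs=1e-8)
        assert fit.converged

    def test_symmetric_wins_give_equal_values(self):
        states = list("abcd")
        rows = []
        for s, t in itertools.combinations(states, 2):
            rows.append({"winner": s, "loser": t, "count": 20})
            rows.append({"winner": t, "loser": s, "count": 20})
        fit = fit_clogit_pairs(pd.DataFrame(rows))
        v = fit.estimates["v"]
        assert np.allclose(v.to_numpy(), v.iloc[0], atol=1e-8)

    def test_recovery_within_three_se(self, saturated_system):
        v_true = np.linspace(-1.4, 1.4, 8)
        rng = np.random.default_rng(23)
        rows = []
        labels = [str(k) for k in range(1, 9)]
        for i, j in itertools.combinations(range(8), 2):
            p = expit(v_true[i] - v_true[j])
            wins = rng.binomial(500, p)
            rows.append({"winner": labels[i], "loser": labels[j], "count": wins})
            rows.append({"winner": labels[j], "loser": labels[i], "count": 500 - wins})
        fit = fit_clogit_pairs(pd.DataFrame(rows), constraint="sumzero")
        v_hat = fit.estimates["v"][labels].to_numpy()
        se = fit.se["v"][labels].to_numpy()
        resid = (v_hat - v_hat.mean()) - (v_true - v_true.mean())
        assert np.all(np.abs(resid) <= 3 * se)

    def test_matches_statsmodels_logit_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        states = list("abcde")
        v_true = rng.normal(size=5)
        rows, X_rows, y_rows = [], [], []
        for s, t in itertools.combinations(range(5), 2):
            for _ in range(60):
                p = expit(v_true[s] - v_true[t])
                win_s = rng.random() < p
                w, l = (s, t) if win_s else (t, s)
                rows.append({"winner": states[w], "loser": states[l]})
                x = np.zeros(5)
                x[s], x[t] = 1.0, -1.0
                X_rows.append(x[1:])  # state 'a' is the reference
                y_rows.append(1.0 if win_s else 0.0)
        fit = fit_clogit_pairs(pd.DataFrame(rows), states=states, constraint="ref")
        sm_fit = sm.Logit(np.array(y_rows), np.array(X_rows)).fit(disp=0)
        assert fit.estimates["v"][states[1:]].to_numpy() == pytest.approx(
            sm_fit.params, abs=1e-5
        )
        assert fit.se["v"][states[1:]].to_numpy() == pytest.approx(
            sm_fit.bse, rel=1e-3
        )

    def test_disconnected_graph_reports_components(self):
        pairs = pd.DataFrame(
            {"winner": ["a", "c"], "loser": ["b", "d"], "count": [5, 5]}
        )
        with pytest.raises(EstimationError, match="disconnected"):
            fit_clogit_pairs(pairs)

    def test_separation_reported_as_nonfinite(self):
        rows = [
            {"winner": "a", "loser": "b", "count": 10},
            {"winner": "b", "loser": "c", "count": 7},
            {"winner": "c", "loser": "b", "count": 9},
        ]
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_clogit_pairs(pd.DataFrame(rows))
        assert fit.estimates["v"]["a"] == np.inf
        assert np.isnan(fit.se["v"]["a"])
        assert ("state", "a") in fit.excluded
        assert np.isfinite(fit.estimates["v"]["b"])


class TestRaschCml:
    def test_extreme_respondents_do_not_move_estimates(self):
        v = np.array([-1.0, -0.2, 0.5, 1.2])
        theta = np.linspace(-2, 2, 120)
        mat = rasch_matrix(v, theta, seed=31)
        informative = mat[(mat.sum(1) > 0) & (mat.sum(1) < 4)]
        extremes = np.vstack([np.zeros((6, 4)), np.ones((5, 4))])
        fit_a = fit_rasch_cml(informative)
        fit_b = fit_rasch_cml(np.vstack([informative, extremes]))
        assert fit_a.estimates["v"].to_numpy() == pytest.approx(
            fit_b.estimates["v"].to_numpy(), abs=1e-9
        )
        assert len(fit_b.excluded) == 11

    def test_two_state_discordant_ratio(self):
        # conditioning on score 1: P(1,0) = eps1/(eps1+eps2)
        mat = np.array([[1, 0]] * 30 + [[0, 1]] * 10 + [[1, 1]] * 5, dtype=float)
        fit = fit_rasch_cml(mat)
        diff = fit.estimates["v"].iloc[0] - fit.estimates["v"].iloc[1]
        assert diff == pytest.approx(np.log(3.0), abs=1e-8)

    def test_matches_bruteforce_conditional_likelihood(self):
        # independent oracle: enumerate all response patterns per score
        v_true = np.array([0.0, -0.7, 0.9])
        mat = rasch_matrix(v_true, np.linspace(-1.5, 1.5, 60), seed=33)
        fit = fit_rasch_cml(mat, constraint="ref")

        patterns = [np.array(p) for p in itertools.product([0, 1], repeat=3)]

        def nll(u):
            v = np.concatenate([[0.0], u])
            total = 0.0
            for row in mat:
                r = int(row.sum())
                if r in (0, 3):
                    continue
                num = np.exp(row @ v)
                den = sum(np.exp(p @ v) for p in patterns if p.sum() == r)
                total -= np.log(num / den)
            return total

        res = minimize(nll, np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert fit.estimates["v"].to_numpy()[1:] == pytest.approx(res.x, abs=1e-5)
        assert -fit.loglik == pytest.approx(nll(res.x - res.x + np.array(
            fit.estimates["v"].to_numpy()[1:])), abs=1e-8)

    def test_missing_data_handled_by_pattern_groups(self):
        v = np.array([-0.8, 0.0, 0.8, 1.5])
        mat = rasch_matrix(v, np.linspace(-2, 2, 300), seed=35)
        mat_miss = mat.copy()
        mat_miss[::3, 0] = np.nan  # a third of respondents skip state 0
        fit = fit_rasch_cml(mat_miss, constraint="sumzero")
        assert fit.converged
        vc = fit.estimates["v"].to_numpy()
        assert np.corrcoef(vc, v)[0, 1] > 0.9

    def test_degenerate_state_flagged(self):
        mat = np.array([[1, 1, 0], [1, 0, 1], [1, 1, 0], [1, 0, 0]], dtype=float)
        fit = fit_rasch_cml(mat)
        assert ("state", "0") in fit.excluded
        assert "0" not in fit.estimates["v"].index

    def test_empty_matrix_rejected(self):
        with pytest.raises((EstimationError, ValueError)):
            fit_rasch_cml(np.zeros((0, 0)))

    def test_jml_correlates_with_cml(self):
        v = np.linspace(-2, 2, 12)
        theta = np.random.default_rng(37).normal(0, 1.2, 400)
        mat = rasch_matrix(v, theta, seed=38)
        f_cml = fit_rasch_cml(mat, constraint="sumzero")
        f_jml = fit_rasch_jml(mat, constraint="sumzero")
        r = np.corrcoef(
            f_cml.estimates["v"].to_numpy(), f_jml.estimates["v"].to_numpy()
        )[0, 1]
        assert r > 0.99

    def test_invariance_across_theta_distributions(self):
        # separability: subsamples with shifted theta distributions give
        # the same recentered state values (up to sampling noise)
        v = np.linspace(-2, 2, 12)
        rng = np.random.default_rng(39)
        fit_lo = fit_rasch_cml(
            rasch_matrix(v, rng.normal(-1, 1, 800), seed=40), constraint="sumzero"
        )
        fit_hi = fit_rasch_cml(
            rasch_matrix(v, rng.normal(+1, 1, 800), seed=41), constraint="sumzero"
        )
        from mapr import invariance_check

        rep = invariance_check(fit_lo, fit_hi)
        assert rep.frac_within(3.0) >= 0.9


class TestMapr:
    def _sim(self, system53, vf53, n, seed, theta_mode="structured"):
        pop = sample_population(n, ("normal", -2.0, 1.5), seed=seed, vf=vf53)
        states = [system53.profile(c) for c in SPANNING_STATES]
        return simulate_mapr_responses(
            pop, states, vf53, seed=seed + 1, theta_mode=theta_mode
        )

    def test_structured_matches_statsmodels_logit(self, system53, vf53):
        import statsmodels.api as sm

        from mapr.estimation import _extract_binary_tasks, _mapr_design

        tab = self._sim(system53, vf53, 300, seed=51)
        fit = fit_mapr(tab, system53, theta_mode="structured")
        tasks = _extract_binary_tasks(tab)
        X, Zown, names = _mapr_design(tasks, system53)
        sm_fit = sm.Logit(tasks["y"].to_numpy(), X - Zown).fit(disp=0)
        assert fit.estimates["gamma"].to_numpy() == pytest.approx(
            sm_fit.params, abs=1e-6
        )
        assert fit.se["gamma"].to_numpy() == pytest.approx(sm_fit.bse, rel=1e-4)

    def test_structured_recovery(self, system53, vf53, gamma53):
        tab = self._sim(system53, vf53, 1200, seed=53)
        fit = fit_mapr(tab, system53, theta_mode="structured")
        rmse = np.sqrt(np.mean((fit.estimates["gamma"].to_numpy() - gamma53) ** 2))
        assert fit.converged and rmse < 0.15

    def test_free_mode_excludes_perfect_responders(self, system53, vf53):
        tab = self._sim(system53, vf53, 250, seed=55, theta_mode="free")
        with pytest.warns(UserWarning, match="perfect-response"):
            fit = fit_mapr(tab, system53, theta_mode="free")
        assert fit.converged
        excluded_ids = {e[1] for e in fit.excluded}
        assert excluded_ids  # some exist at this n
        assert not set(fit.estimates["theta"].index) & excluded_ids

    def test_all_agree_is_nonestimable(self, saturated_system):
        # every respondent prefers every presented state: complete
        # separation in the person dimension, flagged rather than patched
        rows = []
        for rid in range(5):
            for sid, code in enumerate([str(k) for k in range(2, 9)]):
                rows.append(dict(respondent_id=rid, choice_set_id=sid,
                                 alternative_id=0, state_code="8",
                                 role="own", response=0))
                rows.append(dict(respondent_id=rid, choice_set_id=sid,
                                 alternative_id=1, state_code=code,
                                 role="hypothetical", response=1))
        with pytest.raises(EstimationError, match="perfect"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_mapr(pd.DataFrame(rows), saturated_system,
                         theta_mode="free")

    def test_rank_deficiency_names_columns(self, system53, vf53):
        pop = sample_population(100, ("normal", -2, 1.5), seed=57, vf=vf53)
        # single presented state spans one column only
        tab = simulate_mapr_responses(
            pop, [system53.profile("21111")], vf53, seed=58,
            theta_mode="structured",
        )
        with pytest.raises(EstimationError, match="mobility:3"):
            fit_mapr(tab, system53, theta_mode="free")

    def test_dead_state_gets_free_parameter(self, system53, vf53):
        pop = sample_population(600, ("normal", -2.5, 1.5), seed=59, vf=vf53)
        states = [system53.profile(c) for c in SPANNING_STATES] + ["dead"]
        tab = simulate_mapr_responses(
            pop, states, vf53, seed=60, theta_mode="structured", dead_value=-3.0
        )
        fit = fit_mapr(tab, system53, theta_mode="structured")
        assert "dead" in fit.estimates["gamma"].index
        v_dead = fit.estimates["v"]["dead"]
        assert v_dead == pytest.approx(-3.0, abs=3 * fit.se["v"]["dead"])


class TestLoglikGradient:
    def test_clogit_gradient_matches_fd(self):
        rng = np.random.default_rng(61)
        pairs = pd.DataFrame({
            "winner": ["a", "b", "c", "a"], "loser": ["b", "c", "a", "c"],
            "count": [5, 3, 4, 2],
        })
        data = {"pairs": pairs, "states": list("abc")}
        x = rng.normal(size=3)
        ll, g = loglik_and_gradient(x, data, "clogit_pairs")
        fd = central_fd_grad(lambda p: loglik_and_gradient(p, data, "clogit_pairs")[0], x)
        assert g == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_rasch_cml_gradient_matches_fd(self):
        mat = rasch_matrix(np.linspace(-1, 1, 5),
                           np.linspace(-2, 2, 40), seed=63)
        x = np.random.default_rng(64).normal(size=5)
        ll, g = loglik_and_gradient(x, mat, "rasch_cml")
        fd = central_fd_grad(lambda p: loglik_and_gradient(p, mat, "rasch_cml")[0], x)
        assert g == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_mapr_free_gradient_matches_fd(self, system53, vf53):
        pop = sample_population(12, ("normal", -2, 1.5), seed=65, vf=vf53)
        states = [system53.profile(c) for c in SPANNING_STATES[:6]]
        tab = simulate_mapr_responses(pop, states, vf53, seed=66)
        data = (tab, system53)
        x = np.random.default_rng(67).normal(scale=0.5, size=10 + 12)
        ll, g = loglik_and_gradient(x, data, "mapr_free")
        fd = central_fd_grad(lambda p: loglik_and_gradient(p, data, "mapr_free")[0], x)
        assert g == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_true_params_score_below_fit(self, system53, vf53, gamma53):
        pop = sample_population(400, ("normal", -2, 1.5), seed=68, vf=vf53)
        states = [system53.profile(c) for c in SPANNING_STATES]
        tab = simulate_mapr_responses(pop, states, vf53, seed=69,
                                      theta_mode="structured")
        fit = fit_mapr(tab, system53, theta_mode="structured")
        ll_true, _ = loglik_and_gradient(gamma53, (tab, system53), "mapr_structured")
        assert ll_true <= fit.loglik + 1e-9

    def test_gradient_vanishes_at_optimum(self, system53, vf53):
        tab_pop = sample_population(300, ("normal", -2, 1.5), seed=70, vf=vf53)
        states = [system53.profile(c) for c in SPANNING_STATES]
        tab = simulate_mapr_responses(tab_pop, states, vf53, seed=71,
                                      theta_mode="structured")
        fit = fit_mapr(tab, system53, theta_mode="structured")
        _, g = loglik_and_gradient(
            fit.estimates["gamma"].to_numpy(), (tab, system53), "mapr_structured"
        )
        assert np.max(np.abs(g)) <= 1e-6
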