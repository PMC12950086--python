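"""Simulator and maximum-likelihood fitter."""

import numpy as np
import pandas as pd
import pytest

from dtcrdesign.information import Design, group_fim
from dtcrdesign.model import hazard_path
from dtcrdesign.validate import (
    fit_mle,
    log_likelihood,
    person_period_counts,
    simulate_trial,
)

from conftest import make_spec, random_theta


@pytest.fixture(scope="module")
def sim_setup():
    spec = make_spec(2, "multinomial", 3)
    theta = np.array([-1.5, -1.2, -1.6, -1.3, -1.7, -1.4, 0.4, -0.3, 0.0])
    design = Design(support=(0.0, 1.0), weights=(0.5, 0.5), q=3, N=400)
    return spec, theta, design


class TestSimulateTrial:
    def test_seeded_determinism(self, sim_setup):
        spec, theta, design = sim_setup
        a = simulate_trial(spec, design, theta, seed=11)
        b = simulate_trial(spec, design, theta, seed=11)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_trial(spec, design, theta, seed=12)
        assert not a.equals(c)

    def test_full_attrition_single_period(self, sim_setup):
        spec, theta, design = sim_setup
        rec = simulate_trial(spec, design, theta, rho=0.999999, seed=3)
        assert rec.groupby("subject")["t"].max().max() == 1

    def test_degenerate_hazards_no_events(self, sim_setup):
        spec, _, design = sim_setup
        theta = np.concatenate([np.full(6, -30.0), [0.0, 0.0, 0.0]])
        rec = simulate_trial(spec, design, theta, seed=5)
        assert (rec["outcome"] == "survive").all()
        assert rec.groupby("subject")["t"].max().eq(3).all()

    def test_contiguous_periods_single_terminal_event(self, sim_setup):
        spec, theta, design = sim_setup
        rec = simulate_trial(spec, design, theta, seed=7)
        for _, g in rec.groupby("subject"):
            ts = g["t"].to_numpy()
            assert np.array_equal(ts, np.arange(1, len(ts) + 1))
            events = g["outcome"] != "survive"
            assert events.sum() <= 1
            if events.any():
                assert events.to_numpy()[-1]

    def test_group_sizes_largest_remainder(self, sim_setup):
        spec, theta, _ = sim_setup
        design = Design(support=(0.0, 1.0), weights=(1 / 3, 2 / 3), q=3, N=100)
        assert design.group_sizes() == (33, 67)
        design = Design(support=(0.0, 0.5, 1.0), weights=(1 / 3,) * 3, q=3, N=100)
        assert sum(design.group_sizes()) == 100

    def test_event_fractions_match_expectation(self, sim_setup):
        """Per-period cause-specific event fractions vs the product formula."""
        spec, theta, _ = sim_setup
        design = Design(support=(0.0, 1.0), weights=(0.5, 0.5), q=3, N=50_000)
        rho = 0.1
        rec = simulate_trial(spec, design, theta, rho=rho, seed=99)
        counts = person_period_counts(rec, spec, design.support, 3)
        for gi, x in enumerate(design.support):
            n_g = design.group_sizes()[gi]
            lam = hazard_path(spec, x, theta)
            surv_prev = np.concatenate([[1.0], np.cumprod(lam[:, 2])[:-1]])
            for t in range(3):
                at_risk = surv_prev[t] * (1 - rho) ** t
                for r in range(2):
                    p = lam[t, r] * at_risk
                    se = np.sqrt(p * (1 - p) / n_g)
                    frac = counts[gi, t, r] / n_g
                    assert abs(frac - p) < 3.2 * se


class TestLogLikelihood:
    def test_empty_records(self, sim_setup):
        spec, theta, _ = sim_setup
        empty = pd.DataFrame(
            columns=["subject", "group", "x", "t", "outcome", "attrition"])
        assert log_likelihood(theta, empty, spec) == 0.0

    def test_single_record_value(self):
        spec = make_spec(2, "multinomial", 1)
        theta = np.zeros(5)  # hazards (1/3, 1/3, 1/3)
        rec = pd.DataFrame(
            {"subject": [0], "group": [0], "x": [0.0], "t": [1],
             "outcome": ["survive"], "attrition": [False]})
        ll = log_likelihood(theta, rec, spec, support=(0.0,), q=1)
        assert np.isclose(ll, np.log(1 / 3))

    def test_matches_brute_force_product(self, sim_setup, rng):
        spec, theta, design = sim_setup
        rec = simulate_trial(spec, design, theta, seed=21)
        th = random_theta(spec, rng)
        ll = log_likelihood(th, rec, spec, support=design.support, q=3)
        lam = {x: hazard_path(spec, x, th) for x in design.support}
        idx = {"event_1": 0, "event_2": 1, "survive": 2}
        brute = sum(
            np.log(lam[row.x][row.t - 1, idx[row.outcome]])
            for row in rec.itertuples()
        )
        assert np.isclose(ll, brute, atol=1e-8)


class TestFitMle:
    def test_closed_form_single_period(self):
        """Saturated J=2, q=1, one group: gamma_hat = log(n_r / n_survive)."""
        spec = make_spec(2, "multinomial", 1)
        counts = {"event_1": 30, "event_2": 18, "survive": 52}
        rows = []
        sid = 0
        for out, n in counts.items():
            for _ in range(n):
                rows.append((sid, 0, 0.0, 1, out, False))
                sid += 1
        rec = pd.DataFrame(
            rows, columns=["subject", "group", "x", "t", "outcome", "attrition"])
        fit = fit_mle(rec, spec, support=(0.0,), q=1)
        assert fit.converged
        assert np.isclose(fit.theta[0], np.log(30 / 52), atol=1e-6)
        assert np.isclose(fit.theta[1], np.log(18 / 52), atol=1e-6)

    def test_init_at_truth_converges_fast(self, sim_setup):
        spec, theta, design = sim_setup
        rec = simulate_trial(spec, design, theta, N=2000, seed=31)
        fit = fit_mle(rec, spec, init=theta, support=design.support, q=3)
        assert fit.converged
        assert fit.grad_norm < 1e-6
        assert fit.theta[-1] == 0.0  # structural zero untouched

    def test_recovery_within_sampling_error(self, sim_setup):
        spec, theta, design = sim_setup
        rec = simulate_trial(spec, design, theta, N=5000, seed=41)
        fit = fit_mle(rec, spec, init=None, support=design.support, q=3)
        se = np.sqrt(np.diag(fit.covariance))
        err = np.abs(fit.theta[:-1] - theta[:-1])
        assert np.all(err < 4 * se[:-1])

    def test_matches_statsmodels_mnlogit(self, sim_setup):
        """Independent MLE cross-check on the same person-period data."""
        sm = pytest.importorskip("statsmodels.api")
        spec, theta, design = sim_setup
        rec = simulate_trial(spec, design, theta, N=3000, seed=51)
        fit = fit_mle(rec, spec, support=design.support, q=3)
        endog = rec["outcome"].map({"survive": 0, "event_1": 1, "event_2": 2})
        exog = np.column_stack(
            [(rec["t"] == t).astype(float) for t in (1, 2, 3)] + [rec["x"]])
        res = sm.MNLogit(endog.to_numpy(), exog).fit(disp=0, maxiter=200)
        # statsmodels coefficients: column r-1 holds (g_{01r}..g_{03r}, g_r)
        ours = np.array(
            [[fit.theta[2 * t + r] for t in range(3)] + [fit.theta[6 + r]]
             for r in range(2)]).T
        assert np.allclose(res.params, ours, atol=5e-4)


class TestEmpiricalFisher:
    def test_score_outer_product_matches_group_fim(self, sim_setup):
        """Average outer product of per-subject scores at theta0 ~ FIM."""
        from dtcrdesign.information import _jacobian_from_lambda
        from dtcrdesign.model import design_matrix

        spec, theta, _ = sim_setup
        design = Design(support=(1.0,), weights=(1.0,), q=3, N=20_000)
        rec = simulate_trial(spec, design, theta, seed=61)
        lam = hazard_path(spec, 1.0, theta)
        G = [
            _jacobian_from_lambda(spec, lam[t - 1], design_matrix(spec, t, 1.0))
            for t in (1, 2, 3)
        ]
        idx = {"event_1": 0, "event_2": 1, "survive": 2}
        d = spec.theta_dim()
        S = np.zeros((len(rec), d))
        y = rec["outcome"].map(idx).to_numpy()
        trow = rec["t"].to_numpy()
        subj = rec["subject"].to_numpy()
        scores = np.zeros((design.N, d))
        for i in range(len(rec)):
            t = trow[i]
            e = np.zeros(3)
            e[y[i]] = 1.0
            scores[subj[i]] += G[t - 1].T @ (e / lam[t - 1])
        emp = scores.T @ scores / design.N
        M = group_fim(spec, 1.0, theta, 3)
        # entrywise within Monte-Carlo error (~ 1/sqrt(N) of the scale)
        scale = np.abs(M).max()
        assert np.allclose(emp[:-1, :-1], M[:-1, :-1], atol=3 * scale / np.sqrt(design.N) * 3)
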