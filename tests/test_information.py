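"""Fisher information: hazard Jacobian, period/group FIMs, costs."""

import itertools

import numpy as np
import pytest

from dtcrdesign.information import (
    CostSpec,
    Design,
    cost_per_subject,
    cost_weights,
    derived_sample_size,
    group_fim,
    hazard_jacobian,
    period_fim,
    risk_set_weight,
    standardized_fim,
)
from dtcrdesign.model import hazard_path, hazards, survival

from conftest import make_spec, random_theta


def fd_jacobian(spec, t, x, theta, h=1e-6):
    """Finite-difference hazard Jacobian (off-simplex through the last coord)."""
    d = len(theta)
    out = np.zeros((spec.n_risks + 1, d))
    for j in range(d):
        tp = np.array(theta, float)
        tm = tp.copy()
        tp[j] += h
        tm[j] -= h
        # the last coordinate moves the reference predictor off its zero,
        # which the unified-link jacobian treats as unnormalized mass; the
        # comparison below therefore skips that column
        lp = hazards(spec, t, x, np.concatenate([tp[:-1], [tp[-1]]]))
        lm = hazards(spec, t, x, np.concatenate([tm[:-1], [tm[-1]]]))
        out[:, j] = (lp - lm) / (2 * h)
    return out


class TestHazardJacobian:
    @pytest.mark.parametrize(
        "n_risks, link",
        list(itertools.product([1, 2, 3], ["multinomial", "cumulative"])),
    )
    def test_matches_finite_differences(self, n_risks, link, rng):
        spec = make_spec(n_risks, link, 3)
        for _ in range(5):
            theta = random_theta(spec, rng)
            t = int(rng.integers(1, 4))
            x = float(rng.normal())
            G = hazard_jacobian(spec, t, x, theta)
            F = fd_jacobian(spec, t, x, theta)
            # all columns except the structural-zero one
            assert np.allclose(G[:, :-1], F[:, :-1], atol=1e-6)

    def test_free_columns_sum_to_zero(self, spec_j2_q3, rng):
        theta = random_theta(spec_j2_q3, rng)
        G = hazard_jacobian(spec_j2_q3, 2, 1.0, theta)
        assert np.allclose(G[:, :-1].sum(axis=0), 0.0, atol=1e-10)

    def test_j1_logistic_derivative(self):
        spec = make_spec(1, "multinomial", 1)
        theta = np.array([-0.3, 0.8, 0.0])
        lam = hazards(spec, 1, 0.0, theta)[0]
        G = hazard_jacobian(spec, 1, 0.0, theta)
        assert np.isclose(G[0, 0], lam * (1 - lam), atol=1e-10)


class TestPeriodFim:
    def test_symmetric_psd_low_rank(self, spec_j2_q3, rng):
        theta = random_theta(spec_j2_q3, rng)
        M = period_fim(spec_j2_q3, 2, 1.0, theta)
        assert np.allclose(M, M.T, atol=1e-12)
        ev = np.linalg.eigvalsh(M)
        assert ev.min() > -1e-10
        assert np.sum(ev > 1e-12 * ev.max()) <= spec_j2_q3.n_risks + 1

    def test_j1_binomial_information(self):
        spec = make_spec(1, "multinomial", 1)
        theta = np.array([0.4, 0.0, 0.0])
        lam = hazards(spec, 1, 0.0, theta)[0]
        M = period_fim(spec, 1, 0.0, theta)
        assert np.isclose(M[0, 0], lam * (1 - lam), atol=1e-12)

    def test_equals_negative_expected_hessian(self, spec_j2_q3, rng):
        """Against a finite-difference Hessian of the expected log-likelihood.

        The expectation over the multinomial outcome tree of one person-period
        is sum_o lambda_o(theta0) log lambda_o(theta); its negative Hessian in
        theta at theta0 is the period information.
        """
        spec = spec_j2_q3
        theta0 = random_theta(spec, rng)
        t, x = 2, 1.0
        lam0 = hazards(spec, t, x, theta0)

        def expected_ll(th):
            lam = hazards(spec, t, x, th)
            return float(np.sum(lam0 * np.log(lam)))

        d = len(theta0)
        h = 1e-4
        H = np.zeros((d, d))
        for i in range(d):
            for j in range(i, d):
                pp = theta0.copy(); pp[i] += h; pp[j] += h
                pm = theta0.copy(); pm[i] += h; pm[j] -= h
                mp = theta0.copy(); mp[i] -= h; mp[j] += h
                mm = theta0.copy(); mm[i] -= h; mm[j] -= h
                H[i, j] = H[j, i] = (
                    expected_ll(pp) - expected_ll(pm) - expected_ll(mp) + expected_ll(mm)
                ) / (4 * h * h)
        M = period_fim(spec, t, x, theta0)
        # the structural-zero row/column lives in the off-simplex extension
        # and has no counterpart in the actual likelihood; compare free block
        assert np.allclose(M[:-1, :-1], -H[:-1, :-1],
                           atol=2e-5 * max(1.0, np.abs(M).max()))


class TestRiskSetWeight:
    def test_first_period_is_one(self, spec_j2_q3, rng):
        theta = random_theta(spec_j2_q3, rng)
        assert risk_set_weight(spec_j2_q3, 1, 1.0, theta, 0.3) == 1.0

    def test_attrition_free_weight_is_survival(self, spec_j2_q3, rng):
        theta = random_theta(spec_j2_q3, rng)
        w = risk_set_weight(spec_j2_q3, 3, 0.0, theta, 0.0)
        assert np.isclose(w, survival(spec_j2_q3, 2, 0.0, theta))

    def test_half_hazard_example(self):
        spec = make_spec(1, "multinomial", 3)
        theta = np.concatenate([np.zeros(3), [0.0, 0.0]])  # overall hazard 1/2
        w = risk_set_weight(spec, 3, 0.0, theta, 0.2)
        assert np.isclose(w, 0.25 * 0.64)


class TestGroupFim:
    def test_single_period(self, spec_j2_q3, rng):
        theta = random_theta(spec_j2_q3, rng, q=1)
        M1 = group_fim(make_spec(2, "multinomial", 1), 1.0, theta, 1)
        Mp = period_fim(make_spec(2, "multinomial", 1), 1, 1.0, theta)
        assert np.allclose(M1, Mp, atol=1e-12)

    def test_weighted_sum_oracle(self, spec_j2_q3, rng):
        theta = random_theta(spec_j2_q3, rng)
        rho = 0.15
        expected = sum(
            risk_set_weight(spec_j2_q3, t, 1.0, theta, rho)
            * period_fim(spec_j2_q3, t, 1.0, theta)
            for t in range(1, 4)
        )
        assert np.allclose(group_fim(spec_j2_q3, 1.0, theta, 3, rho), expected,
                           atol=1e-12)

    def test_loewner_monotone_in_duration(self, spec_j2_q3, rng):
        """More periods never lose information (in the Loewner order)."""
        theta_full = random_theta(spec_j2_q3, rng)
        for q in (1, 2):
            theta_q = np.concatenate([theta_full[: 2 * q], theta_full[6:]])
            theta_q1 = np.concatenate([theta_full[: 2 * (q + 1)], theta_full[6:]])
            M_small = group_fim(make_spec(2, "multinomial", q), 1.0, theta_q, q)
            M_big = group_fim(
                make_spec(2, "multinomial", q + 1), 1.0, theta_q1, q + 1
            )
            # embed the q-duration FIM into the (q+1)-duration layout
            embed = np.zeros_like(M_big)
            keep = np.concatenate(
                [np.arange(2 * q), np.arange(2 * (q + 1), 2 * (q + 1) + 3)]
            )
            embed[np.ix_(keep, keep)] = M_small
            assert np.linalg.eigvalsh(M_big - embed).min() > -1e-10


class TestCosts:
    def test_all_visits_formula(self, spec_j2_q3, rng):
        theta = random_theta(spec_j2_q3, rng)
        cs = CostSpec(c1=1.0, c2=1.0, variant="all_visits")
        assert cost_per_subject(spec_j2_q3, 0.0, 1, theta, cs) == 3.0

    def test_until_event_expected_measurements(self):
        spec = make_spec(1, "multinomial", 2)
        theta = np.concatenate([np.zeros(2), [0.0, 0.0]])  # hazard 1/2
        cs = CostSpec(c1=1.0, c2=1.0, variant="until_event",
                      baseline_measurement=True)
        # S_i(a_0) = S_i(a_1) = 1, S_i(a_2) = S(1) = 0.5
        assert np.isclose(cost_per_subject(spec, 0.0, 2, theta, cs), 3.5)

    def test_until_event_matches_all_visits_without_events(self):
        spec = make_spec(1, "multinomial", 3)
        base = np.full(3, -30.0)  # hazards ~ 0: nobody leaves
        theta = np.concatenate([base, [0.0, 0.0]])
        until = CostSpec(variant="until_event", baseline_measurement=True)
        allv = CostSpec(variant="all_visits")
        cu = cost_per_subject(spec, 0.0, 3, theta, until)
        ca = cost_per_subject(spec, 0.0, 3, theta, allv)
        assert np.isclose(cu, ca, atol=1e-10)
        assert cu <= ca + 1e-12

    def test_rejects_bad_specs(self):
        with pytest.raises(ValueError):
            CostSpec(rho=-0.1)
        with pytest.raises(ValueError):
            CostSpec(c2=0.0)
        with pytest.raises(ValueError):
            CostSpec(variant="per_diem")


class TestStandardizedFim:
    def test_single_group_unit_cost(self, spec_j2_q3, rng):
        theta = random_theta(spec_j2_q3, rng)
        design = Design(support=(1.0,), weights=(1.0,), q=3)
        cs = CostSpec(c1=0.0, c2=1.0 / 4.0, variant="all_visits")  # cost 1
        Mc = standardized_fim(spec_j2_q3, design, theta, cs)
        assert np.allclose(Mc, group_fim(spec_j2_q3, 1.0, theta, 3), atol=1e-12)

    def test_cost_scale_homogeneity(self, spec_j2_q3, rng):
        theta = random_theta(spec_j2_q3, rng)
        design = Design(support=(0.0, 1.0), weights=(0.4, 0.6), q=3)
        a = standardized_fim(spec_j2_q3, design, theta,
                             CostSpec(c1=2.0, c2=1.0, variant="all_visits"))
        b = standardized_fim(spec_j2_q3, design, theta,
                             CostSpec(c1=10.0, c2=5.0, variant="all_visits"))
        assert np.allclose(a, 5.0 * b, atol=1e-12)

    def test_two_group_direct_formula(self, spec_j2_q3, rng):
        theta = random_theta(spec_j2_q3, rng)
        design = Design(support=(0.0, 1.0), weights=(0.3, 0.7), q=3)
        cs = CostSpec(c1=(1.0, 4.0), c2=1.0, variant="all_visits")
        Mc = standardized_fim(spec_j2_q3, design, theta, cs)
        M = 0.3 * group_fim(spec_j2_q3, 0.0, theta, 3) + 0.7 * group_fim(
            spec_j2_q3, 1.0, theta, 3)
        cbar = 0.3 * 5.0 + 0.7 * 8.0
        assert np.allclose(Mc, M / cbar, atol=1e-12)
        pc = cost_weights(spec_j2_q3, design, theta, cs)
        assert np.isclose(pc.sum(), 1.0)
        assert np.allclose(pc, [0.3 * 5.0 / cbar, 0.7 * 8.0 / cbar])


class TestDerivedSampleSize:
    def test_single_group(self, spec_j2_q3, rng):
        theta = random_theta(spec_j2_q3, rng)
        design = Design(support=(1.0,), weights=(1.0,), q=1)
        cs = CostSpec(c1=1.0, c2=1.0, variant="all_visits")  # c = 3
        n = derived_sample_size(310.0, 10.0, spec_j2_q3, design, theta, cs)
        assert np.isclose(n, 100.0)

    def test_budget_identity_and_two_groups(self, spec_j2_q3, rng):
        theta = random_theta(spec_j2_q3, rng)
        design = Design(support=(0.0, 1.0), weights=(0.5, 0.5), q=1)
        cs = CostSpec(c1=(1.0, 2.0), c2=1.0, variant="all_visits")  # c = 3, 4
        n = derived_sample_size(700.0, 0.0, spec_j2_q3, design, theta, cs)
        assert np.isclose(n, 200.0)
        avg = sum(
            w * cost_per_subject(spec_j2_q3, x, 1, theta, cs, i)
            for i, (x, w) in enumerate(zip(design.support, design.weights))
        )
        assert abs(n * avg - 700.0) < 1e-9
        with pytest.raises(ValueError):
            derived_sample_size(5.0, 10.0, spec_j2_q3, design, theta, cs)


class TestFimLikelihoodConsistency:
    def test_group_fim_is_negative_expected_hessian(self, spec_j2_q3, rng):
        """Expectation over the full outcome tree of a q=2 trial.

        Enumerates every survival path through two periods, weights each
        person-period term by the probability of reaching it, and compares
        the finite-difference Hessian of that expected log-likelihood with
        the analytic group information.
        """
        spec = make_spec(2, "multinomial", 2)
        theta0 = random_theta(spec, rng, q=2)
        x = 1.0

        def expected_ll(th):
            lam0 = hazard_path(spec, x, theta0)
            lam = hazard_path(spec, x, th)
            total = 0.0
            reach = 1.0
            for t in range(2):
                total += reach * float(np.sum(lam0[t] * np.log(lam[t])))
                reach *= lam0[t][2]
            return total

        d = spec.theta_dim()
        h = 1e-4
        H = np.zeros((d, d))
        for i in range(d):
            for j in range(i, d):
                pp = theta0.copy(); pp[i] += h; pp[j] += h
                pm = theta0.copy(); pm[i] += h; pm[j] -= h
                mp = theta0.copy(); mp[i] -= h; mp[j] += h
                mm = theta0.copy(); mm[i] -= h; mm[j] -= h
                H[i, j] = H[j, i] = (
                    expected_ll(pp) - expected_ll(pm) - expected_ll(mp)
                    + expected_ll(mm)
                ) / (4 * h * h)
        M = group_fim(spec, x, theta0, 2)
        assert np.allclose(M[:-1, :-1], -H[:-1, :-1],
                           atol=1e-4 * max(1.0, np.abs(M).max()))
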