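"""Extinction risk: exact marginal chain, Monte-Carlo calibration, RLI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from driftindex import (
    DEFAULT_CRITERIA,
    CategoryThresholds,
    SimulationConfig,
    ThreatTrajectory,
    category_proportions,
    classify_trajectory,
    compute_rli,
    derive_thresholds,
    estimate_risk_curves,
    exact_extinction_curve,
    exact_extinction_probability,
    marginal_step_distribution,
    simulate,
)
from driftindex.risk import ExtinctionRiskCurve, RiskCriterion, transition_matrix


class TestMarginalStep:
    def test_absorbing_endpoints_are_point_masses(self):
        assert marginal_step_distribution(0, 10)[0] == 1.0
        assert marginal_step_distribution(10, 10)[10] == 1.0

    def test_extinction_mass_closed_form(self):
        pmf = marginal_step_distribution(1, 10)
        assert pmf[0] == pytest.approx(0.9**10)
        assert pmf.sum() == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            marginal_step_distribution(11, 10)

    def test_transition_matrix_rows_are_the_marginals(self):
        P = transition_matrix(6)
        for a in range(7):
            np.testing.assert_allclose(P[a], marginal_step_distribution(a, 6))


class TestExactOracle:
    def test_absorbing_identities(self):
        assert exact_extinction_probability(0, 7, 12) == 1.0
        assert exact_extinction_probability(12, 7, 12) == 0.0

    def test_one_step_equals_marginal_mass_at_zero(self):
        assert exact_extinction_probability(1, 1, 10) == pytest.approx(0.9**10)

    def test_monotone_in_horizon_and_abundance(self):
        c10 = exact_extinction_curve(10, 12)
        c20 = exact_extinction_curve(20, 12)
        assert (np.diff(c10[:-1]) <= 1e-12).all()  # non-increasing in a
        assert (c20[1:-1] >= c10[1:-1]).all()

    def test_resource_guard(self):
        with pytest.raises(ValueError, match="limited"):
            exact_extinction_probability(1, 1, 100_000)


class TestEstimateRiskCurves:
    def test_monte_carlo_matches_exact_oracle(self):
        # first-visit trials are independent, so binomial SEs apply
        cfg = SimulationConfig(J=8, S=2, n_years=15, seed=13)
        curve = estimate_risk_curves(cfg, n_iterations=5_000, visits="first")
        for h in curve.horizons:
            exact = exact_extinction_curve(h, 8)
            for a in range(1, 8):
                n = curve.n_trials[a]
                if n == 0:
                    continue
                se = np.sqrt(exact[a] * (1 - exact[a]) / n)
                assert abs(curve.p_raw[h][a] - exact[a]) <= 4 * se + 1e-12

    def test_community_mode_agrees_with_marginal_mode(self):
        # tracking species inside full community replicates is the same chain
        cfg = SimulationConfig(J=10, S=2, n_years=10, seed=21)
        com = estimate_risk_curves(cfg, horizons=(10,), n_iterations=2_000,
                                   mode="community")
        exact = exact_extinction_curve(10, 10)
        for a in range(1, 10):
            n = com.n_trials[a]
            if n < 50:
                continue
            se = np.sqrt(exact[a] * (1 - exact[a]) / n)
            # all-visit trials are correlated; allow a generous envelope
            assert abs(com.p_raw[10][a] - exact[a]) <= 8 * se + 0.02

    def test_smoothed_curves_are_monotone_with_pinned_endpoints(self):
        cfg = SimulationConfig(J=30, S=3, n_years=20, seed=8)
        curve = estimate_risk_curves(cfg, n_iterations=3_000)
        prev = np.zeros(31)
        for h in curve.horizons:
            sm = curve.p_smooth[h]
            assert sm[0] == 1.0 and sm[30] == 0.0
            assert (np.diff(sm) <= 1e-12).all()
            assert (sm[:-1] >= prev[:-1] - 1e-12).all()
            prev = sm

    def test_probability_accessor_validates(self):
        cfg = SimulationConfig(J=12, S=3, n_years=10, seed=2)
        curve = estimate_risk_curves(cfg, horizons=(10,), n_iterations=500)
        assert curve.probability(0, 10) == 1.0
        with pytest.raises(KeyError):
            curve.probability(1, 55)
        with pytest.raises(ValueError):
            curve.probability(13, 10)

    def test_curve_frame_schema(self):
        cfg = SimulationConfig(J=12, S=3, n_years=10, seed=2)
        frame = estimate_risk_curves(cfg, horizons=(10, 20),
                                     n_iterations=500).to_frame()
        assert list(frame.columns) == [
            "horizon", "abundance", "n_trials", "p_raw", "p_smoothed"
        ]
        assert set(frame["horizon"]) == {10, 20}


def _curve_from_arrays(J, smooth_by_horizon):
    grid_trials = np.ones(J + 1, dtype=np.int64)
    return ExtinctionRiskCurve(
        J=J,
        horizons=tuple(sorted(smooth_by_horizon)),
        n_trials=grid_trials,
        p_raw={h: p.copy() for h, p in smooth_by_horizon.items()},
        p_smooth={h: p.copy() for h, p in smooth_by_horizon.items()},
    )


class TestDeriveThresholds:
    def test_step_curve(self):
        # P(a, 10y) = 1 for a <= 3, else 0 -> CR cutoff at 3
        J = 10
        p10 = np.where(np.arange(J + 1) <= 3, 1.0, 0.0)
        p20 = np.where(np.arange(J + 1) <= 4, 1.0, 0.0)
        p100 = np.where(np.arange(J + 1) <= 5, 1.0, 0.0)
        th = derive_thresholds(
            _curve_from_arrays(J, {10: p10, 20: p20, 100: p100})
        )
        assert th == CategoryThresholds(A_CR=3, A_EN=4, A_VU=5)

    def test_criterion_boundary_is_inclusive(self):
        # a bin sitting exactly on the criterion probability is threatened
        J = 10
        base = np.array([1.0, 0.9, 0.5, 0.05, 0.04, 0.03, 0.02, 0.01,
                         0.005, 0.001, 0.0])
        th = derive_thresholds(
            _curve_from_arrays(J, {10: base, 20: base, 100: base})
        )
        assert th.A_CR == 2  # P = 0.50 exactly at a = 2

    def test_matches_brute_force_on_exact_curves(self):
        J = 12
        curves = {h: exact_extinction_curve(h, J) for h in (10, 20, 100)}
        th = derive_thresholds(_curve_from_arrays(J, curves))
        for crit in DEFAULT_CRITERIA:
            expect = max(
                a for a in range(J + 1)
                if exact_extinction_probability(a, crit.horizon, J)
                >= crit.probability
            )
            assert getattr(th, f"A_{crit.category}") == expect

    def test_degenerate_curve_rejected(self):
        J = 5
        flat = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            derive_thresholds(_curve_from_arrays(J, {10: flat, 20: flat,
                                                     100: flat}))

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            CategoryThresholds(A_CR=5, A_EN=3, A_VU=10)

    def test_criterion_validation(self):
        with pytest.raises(ValueError):
            RiskCriterion("CR", 0, 0.5)
        with pytest.raises(ValueError):
            RiskCriterion("CR", 10, 1.5)


THRESH = CategoryThresholds(A_CR=3, A_EN=16, A_VU=119)


class TestClassification:
    @pytest.mark.parametrize(
        "N,expected",
        [(0, "EX"), (1, "CR"), (3, "CR"), (4, "EN"), (16, "EN"),
         (17, "VU"), (119, "VU"), (120, "LC"), (5000, "LC")],
    )
    def test_category_boundaries_inclusive_above(self, N, expected):
        threat = classify_trajectory(np.array([[N]]), THRESH)
        assert threat.categories[0, 0] == expected

    def test_extinction_is_absorbing_in_categories(self):
        cfg = SimulationConfig(J=40, S=8, n_years=60, seed=31)
        threat = classify_trajectory(
            simulate(cfg, 0), CategoryThresholds(A_CR=2, A_EN=4, A_VU=8)
        )
        ex = threat.categories == "EX"
        assert not ((~ex[:, 1:]) & ex[:, :-1]).any()

    @given(hnp.arrays(np.int64, (3, 4), elements=st.integers(0, 200)),
           st.integers(1, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_classification_is_total(self, N, a, b, c):
        th = CategoryThresholds(A_CR=a, A_EN=a + b, A_VU=a + b + c)
        cats = classify_trajectory(N, th).categories
        assert cats.shape == N.shape  # every cell got exactly one category

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ThreatTrajectory(categories=np.array([["??"]]),
                             years=np.array([1970]))


class TestRLI:
    def _threats(self, cats):
        cats = np.array(cats, dtype="<U2").reshape(-1, 1)
        return ThreatTrajectory(categories=cats,
                                years=np.array([1970]))

    @pytest.mark.parametrize("scheme", ["standard", "equal"])
    def test_all_least_concern_gives_one(self, scheme):
        rli = compute_rli(self._threats(["LC"] * 5), scheme=scheme)
        assert rli.rli[0] == 1.0

    @pytest.mark.parametrize("scheme", ["standard", "equal"])
    def test_all_extinct_gives_zero(self, scheme):
        rli = compute_rli(self._threats(["EX"] * 5), scheme=scheme)
        assert rli.rli[0] == 0.0

    def test_mixed_community_standard_weights(self):
        # weights (0,2,3,4,5) over w_EX * S = 25 -> 1 - 14/25
        rli = compute_rli(self._threats(["LC", "VU", "EN", "CR", "EX"]))
        assert rli.rli[0] == pytest.approx(1 - 14 / 25)

    def test_mixed_community_equal_weights(self):
        rli = compute_rli(self._threats(["LC", "VU", "EN", "CR", "EX"]),
                          scheme="equal")
        assert rli.rli[0] == pytest.approx(1 - 10 / 20)

    def test_extinct_species_stay_in_the_denominator(self):
        # one extinction in an otherwise LC community of 4
        rli = compute_rli(self._threats(["LC", "LC", "LC", "EX"]))
        assert rli.rli[0] == pytest.approx(1 - 5 / 20)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            compute_rli(self._threats(["LC"]), scheme="bogus")

    @given(st.lists(st.sampled_from(["LC", "VU", "EN", "CR", "EX"]),
                    min_size=1, max_size=30))
    @settings(max_examples=80, deadline=None)
    def test_rli_bounded_and_endpoint_exact(self, cats):
        rli = compute_rli(self._threats(cats)).rli[0]
        assert 0.0 <= rli <= 1.0
        if set(cats) == {"LC"}:
            assert rli == 1.0
        if set(cats) == {"EX"}:
            assert rli == 0.0


class TestCategoryProportions:
    def test_all_safe_community_is_fully_least_concern(self):
        N = np.full((4, 6), 500)
        props = category_proportions(classify_trajectory(N, THRESH))
        assert (props["LC"] == 1.0).all()
        assert (props[["VU", "EN", "CR", "EX"]] == 0.0).all().all()

    def test_fractions_partition_every_year(self, small_ensemble):
        th = CategoryThresholds(A_CR=2, A_EN=5, A_VU=12)
        for traj in small_ensemble[:5]:
            props = category_proportions(classify_trajectory(traj, th))
            np.testing.assert_allclose(props.sum(axis=1), 1.0)

    def test_threatened_fraction_rises_under_drift(self, small_ensemble):
        # with thresholds below the initial mean abundance (as calibrated
        # thresholds are), drift spreads abundances and pushes an
        # increasing share of species below them
        th = CategoryThresholds(A_CR=1, A_EN=3, A_VU=6)
        stacked = []
        for traj in small_ensemble:
            props = category_proportions(classify_trajectory(traj, th))
            stacked.append((props[["VU", "EN", "CR", "EX"]].sum(axis=1)))
        mean = pd.concat(stacked, axis=1).mean(axis=1)
        assert mean.iloc[-1] > mean.iloc[0]
        # allow small sampling wiggles year-on-year, no systematic dips
        assert (np.diff(mean.to_numpy()) > -0.05).all()
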