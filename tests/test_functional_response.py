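"""Unit and property tests for type classification and disc-equation fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from predfr import (
    HollingFit,
    PredationTrial,
    ResponseType,
    TrialSet,
    classify_expectation,
    classify_response,
    derived_metrics,
    fit_holling,
    fit_polynomial_type,
    predict_consumption,
    rank_predators,
    search_efficiency,
)
from predfr.errors import (
    DegenerateDataError,
    InvalidInputError,
    NoPredationError,
    UnderdeterminedError,
)

from conftest import grid_search_sse, make_noise_free_trials

DENSITIES = (5, 10, 15, 20, 25, 30)


def make_trials(values, predator="p", stage="nymph_4_5", densities=DENSITIES):
    """TrialSet from a {density: [consumed...]} mapping or callable."""
    trials = []
    for d in densities:
        vals = values(d) if callable(values) else values[d]
        for r, v in enumerate(vals, start=1):
            trials.append(PredationTrial(predator, stage, d, v, r))
    return TrialSet(predator, stage, tuple(trials))


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "b, expected",
        [
            (-0.008, ResponseType.II),
            (-0.105, ResponseType.II),
            (0.01, ResponseType.III),
            (0.0, ResponseType.INDETERMINATE),
        ],
    )
    def test_sign_rule(self, b, expected):
        assert classify_response(b) is expected

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            classify_response(bad)


class TestPolynomialTypeFit:
    def test_constant_ratio_is_indeterminate(self):
        ts = make_trials(lambda d: [d / 2.0])
        fit = fit_polynomial_type(ts)
        assert fit.a == pytest.approx(0.5, abs=1e-9)
        for coef in (fit.b, fit.c, fit.d):
            assert coef == pytest.approx(0.0, abs=1e-9)
        assert fit.response_type is ResponseType.INDETERMINATE

    def test_exact_cubic_recovery_matches_normal_equations(self):
        # noise-free polynomial data: OLS is exact; oracle = direct solve
        coefs = np.array([0.9, -0.01, 0.0002, -1e-6])
        ratios = {
            d: [coefs @ np.array([1.0, d, d**2, d**3])] * 3 for d in DENSITIES
        }
        ts = make_trials(ratios_to_consumed(ratios))
        fit = fit_polynomial_type(ts)
        dens = ts.densities
        X = np.column_stack([np.ones_like(dens), dens, dens**2, dens**3])
        oracle = np.linalg.solve(X.T @ X, X.T @ ts.ratios)
        assert np.allclose([fit.a, fit.b, fit.c, fit.d], oracle, atol=1e-9)
        assert np.allclose(oracle, coefs, atol=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_published_type_ii_curve_classifies_ii(self):
        # disc-equation expectation with the published O. sertatus nymph
        # parameters declines in density, so the cubic's b is negative
        fit = classify_expectation(1.339, 0.022, 1.0, "II")
        assert fit.b < 0
        assert fit.response_type is ResponseType.II

    def test_underdetermined_with_three_densities(self):
        ts = make_trials(lambda d: [d // 2], densities=(5, 10, 15))
        with pytest.raises(UnderdeterminedError):
            fit_polynomial_type(ts)

    def test_all_zero_ratios_degenerate(self):
        ts = make_trials(lambda d: [0, 0])
        with pytest.raises(DegenerateDataError):
            fit_polynomial_type(ts)

    def test_glm_variant_agrees_on_type_call(self):
        ts = make_trials(lambda d: [max(1, round(d * 0.9 / (1 + 0.05 * d)))] * 4)
        ols = fit_polynomial_type(ts, method="ols")
        glm = fit_polynomial_type(ts, method="glm")
        assert ols.response_type is glm.response_type is ResponseType.II


def ratios_to_consumed(ratios):
    return {d: [r * d for r in vals] for d, vals in ratios.items()}


class TestHollingFit:
    def test_exact_recovery_type_ii(self):
        ts = make_noise_free_trials(1.276, 0.023)
        fit = fit_holling(ts, "II")
        assert fit.attack_rate == pytest.approx(1.276, rel=1e-6)
        assert fit.handling_time == pytest.approx(0.023, rel=1e-6)
        assert fit.converged
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_exact_recovery_type_iii(self):
        ts = make_noise_free_trials(
            0.05, 0.03, densities=DENSITIES, model="III"
        )
        fit = fit_holling(ts, "III")
        assert fit.attack_rate == pytest.approx(0.05, rel=1e-6)
        assert fit.handling_time == pytest.approx(0.03, rel=1e-6)

    def test_nls_beats_exhaustive_grid(self):
        ts = make_noise_free_trials(1.276, 0.023, replicates=2)
        # perturb one bottle so the optimum is interior and non-trivial
        trials = list(ts.trials)
        trials[0] = PredationTrial(
            trials[0].predator_id, trials[0].prey_stage,
            trials[0].density, trials[0].consumed - 1.0, trials[0].replicate,
        )
        ts = TrialSet(ts.predator_id, ts.prey_stage, tuple(trials), ts.exposure_T)
        fit = fit_holling(ts, "II")
        fitted = predict_consumption(fit, ts.densities)
        sse_nls = float(((fitted - ts.consumed) ** 2).sum())
        sse_grid = grid_search_sse(
            ts, "II",
            np.arange(0.5, 2.0 + 1e-12, 1e-3),
            np.arange(0.005, 0.08 + 1e-12, 1e-3),
        )
        assert sse_nls <= sse_grid * (1 + 1e-8)

    def test_linear_unsaturating_data_hits_handling_time_bound(self):
        ts = make_trials(lambda d: [0.9 * d] * 2)
        with pytest.warns(RuntimeWarning, match="handling_time"):
            fit = fit_holling(ts, "II")
        assert fit.attack_rate == pytest.approx(0.9, rel=1e-3)
        assert fit.handling_time <= 1e-5
        assert not fit.converged
        assert any("handling_time" in w for w in fit.warnings)

    def test_all_zero_consumption_rejected(self):
        ts = make_trials(lambda d: [0, 0, 0])
        with pytest.raises(NoPredationError):
            fit_holling(ts, "II")

    def test_mean_aggregation_matches_raw_on_balanced_noise_free_data(self):
        ts = make_noise_free_trials(1.0, 0.04, densities=DENSITIES)
        raw = fit_holling(ts, "II", aggregate="raw")
        mean = fit_holling(ts, "II", aggregate="mean")
        assert raw.attack_rate == pytest.approx(mean.attack_rate, rel=1e-9)
        assert raw.handling_time == pytest.approx(mean.handling_time, rel=1e-9)
        assert mean.n_points == len(DENSITIES)


class TestPredictionAndMetrics:
    @pytest.fixture()
    def fit_et(self):
        return HollingFit(
            model=ResponseType.II, attack_rate=1.276, handling_time=0.023,
            exposure_T=1.0, r_squared=0.975, n_points=24,
            predator_id="E. tricuspidata",
        )

    def test_zero_density_gives_zero(self, fit_et):
        assert predict_consumption(fit_et, 0.0) == 0.0

    def test_hand_evaluated_consumption(self, fit_et):
        expected = 12.76 / (1 + 1.276 * 0.023 * 10)
        assert predict_consumption(fit_et, 10) == pytest.approx(expected, rel=1e-12)
        assert predict_consumption(fit_et, 10) == pytest.approx(9.865, abs=5e-4)

    def test_type_ii_asymptote_near_daily_maximum(self, fit_et):
        asym = predict_consumption(fit_et, 1e6)
        assert asym == pytest.approx(1.0 / 0.023, rel=0.01)
        assert asym == pytest.approx(43.48, rel=0.01)

    def test_negative_density_rejected(self, fit_et):
        with pytest.raises(InvalidInputError):
            predict_consumption(fit_et, -1.0)

    @pytest.mark.parametrize(
        "a, th, expected_tth, expected_ath",
        [(1.339, 0.022, 45.45, 60.86), (1.067, 0.045, 22.22, 23.71),
         (1.0, 1.0, 1.0, 1.0)],
    )
    def test_derived_metrics(self, a, th, expected_tth, expected_ath):
        fit = HollingFit(
            model=ResponseType.II, attack_rate=a, handling_time=th,
            exposure_T=1.0, r_squared=1.0, n_points=24,
        )
        tth, ath = derived_metrics(fit)
        assert tth == pytest.approx(expected_tth, abs=0.005)
        assert ath == pytest.approx(expected_ath, abs=0.005)
        assert tth == fit.daily_max_predation
        assert ath == fit.theoretical_predation


class TestSearchEfficiency:
    def test_published_low_density_values(self):
        nymph = HollingFit(
            model=ResponseType.II, attack_rate=1.067, handling_time=0.045,
            exposure_T=1.0, r_squared=0.955, n_points=24,
        )
        adult = HollingFit(
            model=ResponseType.II, attack_rate=1.085, handling_time=0.049,
            exposure_T=1.0, r_squared=0.951, n_points=24,
        )
        s_nymph = search_efficiency(nymph, [5]).efficiency[0]
        s_adult = search_efficiency(adult, [5]).efficiency[0]
        assert round(s_nymph, 2) == 0.86
        assert round(s_adult, 3) == 0.857

    def test_efficiency_at_zero_density_equals_attack_rate(self):
        fit = HollingFit(
            model=ResponseType.II, attack_rate=1.2, handling_time=0.03,
            exposure_T=1.0, r_squared=1.0, n_points=24,
        )
        assert search_efficiency(fit, [0]).efficiency[0] == pytest.approx(1.2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(0.01, 10.0),
        th=st.floats(1e-4, 1.0),
        n1=st.floats(0.0, 100.0),
        delta=st.floats(0.1, 100.0),
    )
    def test_strictly_decreasing_in_density(self, a, th, n1, delta):
        fit = HollingFit(
            model=ResponseType.II, attack_rate=a, handling_time=th,
            exposure_T=1.0, r_squared=1.0, n_points=24,
        )
        s = search_efficiency(fit, [n1, n1 + delta]).efficiency
        assert s[0] > s[1]

    def test_negative_density_rejected(self):
        fit = HollingFit(
            model=ResponseType.II, attack_rate=1.0, handling_time=0.1,
            exposure_T=1.0, r_squared=1.0, n_points=24,
        )
        with pytest.raises(InvalidInputError):
            search_efficiency(fit, [5, -1])


class TestRanking:
    def test_published_order_both_stages(self, published_fits):
        expected = [
            "O. sertatus", "E. tricuspidata", "X. ephippiatus", "H. graminicola",
        ]
        for stage in ("nymph_4_5", "adult"):
            fits = [f for f in published_fits if f.prey_stage.value == stage]
            assert [f.predator_id for f in rank_predators(fits)] == expected

    def test_single_fit_is_itself(self, published_fits):
        assert rank_predators([published_fits[0]]) == [published_fits[0]]

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            rank_predators([])


class TestInvariantsOnConstruction:
    def test_consumed_must_not_exceed_density(self):
        with pytest.raises(InvalidInputError):
            PredationTrial("p", "adult", 30, 31, 1)

    def test_mixed_predators_rejected(self):
        t1 = PredationTrial("a", "adult", 5, 1, 1)
        t2 = PredationTrial("b", "adult", 10, 1, 1)
        t3 = PredationTrial("a", "adult", 15, 1, 1)
        with pytest.raises(InvalidInputError):
            TrialSet("a", "adult", (t1, t2, t3))

    def test_too_few_distinct_densities_rejected(self):
        trials = tuple(
            PredationTrial("a", "adult", d, 1, r)
            for d in (5, 10) for r in (1, 2, 3)
        )
        with pytest.raises(UnderdeterminedError):
            TrialSet("a", "adult", trials)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(InvalidInputError):
            HollingFit(
                model=ResponseType.II, attack_rate=0.0, handling_time=0.02,
                exposure_T=1.0, r_squared=1.0, n_points=6,
            )
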