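"""Wood-curve trait calculus: peaks, persistency, integrals, summaries."""

import numpy as np
import pandas as pd
import pytest

from lactofit.exceptions import DomainError, InsufficientData, NoPeak
from lactofit.families import evaluate
from lactofit.model import LactationCurveModel
from lactofit.traits import (compute_traits, lactation_length, peak_date,
                             peak_production, persistency, summarize_traits,
                             total_production, total_production_quad,
                             traits_table)

from conftest import make_lactation


class TestPeakDate:
    def test_flat_rise_peaks_at_kidding(self):
        assert peak_date(0.0, 0.09) == 0.0

    def test_population_mean_parameters(self):
        assert peak_date(0.26, 0.09) == pytest.approx(2.8889, abs=1e-4)

    def test_no_decline_has_no_peak(self):
        with pytest.raises(NoPeak):
            peak_date(0.26, 0.0)

    def test_matches_grid_argmax(self):
        rng = np.random.default_rng(8)
        grid = np.arange(1e-3, 300.0, 1e-3)
        for _ in range(10):
            B = rng.uniform(0.05, 1.5)
            C = rng.uniform(0.01, 0.2)
            y = np.asarray(evaluate("wood", (700.0, B, C), grid))
            assert peak_date(B, C) == pytest.approx(grid[np.argmax(y)], abs=1e-3)


class TestPeakProduction:
    def test_flat_rise_gives_initial_scale(self):
        assert peak_production(730.0, 0.0, 0.09) == pytest.approx(730.0)

    def test_population_mean_parameters(self):
        assert peak_production(730.0, 0.26, 0.09) == pytest.approx(741.645, abs=1e-2)

    def test_equals_curve_at_peak_and_dominates_neighbourhood(self):
        A, B, C = 730.0, 0.26, 0.09
        pp = peak_production(A, B, C)
        t_pk = peak_date(B, C)
        assert pp == pytest.approx(evaluate("wood", (A, B, C), t_pk), rel=1e-12)
        for dt in (-0.1, 0.1):
            assert pp >= evaluate("wood", (A, B, C), t_pk + dt)

    def test_no_decline_is_error(self):
        with pytest.raises(NoPeak):
            peak_production(730.0, 0.26, 0.0)


class TestPersistency:
    def test_unit_rise_rate_is_exactly_100(self):
        assert persistency(1.0, 0.5) == pytest.approx(100.0)

    def test_unit_decline_rate_is_exactly_100(self):
        assert persistency(0.3, 1.0) == pytest.approx(100.0)

    def test_population_mean_parameters(self):
        # the statistic as defined exceeds 100% for sub-unit C in 1/day
        assert persistency(0.26, 0.09) == pytest.approx(101.78, abs=1e-2)

    def test_nonpositive_decline_is_error(self):
        with pytest.raises(DomainError):
            persistency(0.26, 0.0)


class TestTotalProduction:
    def test_constant_curve_integrates_linearly(self):
        assert total_production(1000.0, 0.0, 0.0, 10.0) == pytest.approx(10.0)

    def test_population_mean_parameters(self):
        assert total_production(730.0, 0.26, 0.09, 146.0) == pytest.approx(
            13.719, abs=1e-3)

    def test_closed_form_matches_quadrature_over_random_draws(self):
        """Incomplete-gamma closed form vs adaptive quadrature, 100 draws."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            A = rng.uniform(100.0, 2000.0)
            B = rng.uniform(0.0, 2.0)
            C = rng.uniform(0.001, 0.3)
            t_end = rng.uniform(30.0, 300.0)
            cf = total_production(A, B, C, t_end)
            q = total_production_quad(A, B, C, t_end)
            assert cf == pytest.approx(q, rel=1e-6)

    def test_monotone_in_horizon(self):
        assert total_production(730.0, 0.26, 0.09, 292.0) >= \
            total_production(730.0, 0.26, 0.09, 146.0)

    def test_nonpositive_horizon_is_error(self):
        with pytest.raises(DomainError):
            total_production(730.0, 0.26, 0.09, 0.0)


class TestLactationLength:
    def test_last_recording_plus_seven(self):
        assert lactation_length(make_lactation([14, 70, 140], [500, 400, 300])) == 147.0

    def test_single_record(self):
        assert lactation_length(make_lactation([14.0], [500.0])) == 21.0

    def test_no_records_is_error(self):
        with pytest.raises(InsufficientData):
            lactation_length(np.array([]))


def _fit_pairs(param_sets, t=None):
    t = np.arange(14.0, 141.0, 14.0) if t is None else t
    pairs = []
    for i, (A, B, C) in enumerate(param_sets):
        y = np.asarray(evaluate("wood", (A, B, C), t))
        lact = make_lactation(t, y, lact_id=f"L{i+1}")
        pairs.append((lact, LactationCurveModel.from_record(lact, "wood").fit()))
    return pairs


class TestTraitsTable:
    def test_single_lactation_summary_is_the_value_with_zero_sd(self):
        pairs = _fit_pairs([(730.0, 0.26, 0.09)])
        table = traits_table(pairs)
        assert len(table) == 1
        summ = summarize_traits(table).set_index("key")
        assert summ.loc["A", "mean"] == pytest.approx(730.0, rel=1e-6)
        assert (summ["sd"] == 0.0).all()
        assert summ.loc["TP", "mean"] == pytest.approx(
            total_production(730.0, 0.26, 0.09, 147.0), rel=1e-6)

    def test_duplicated_lactation_rows_identical(self):
        pairs = _fit_pairs([(730.0, 0.26, 0.09)]) * 2
        table = traits_table(pairs)
        assert len(table) == 2
        pd.testing.assert_series_equal(table.iloc[0], table.iloc[1],
                                       check_names=False)
        assert summarize_traits(table)["sd"].eq(0.0).all()

    def test_empty_input_gives_empty_table(self):
        assert traits_table([]).empty

    def test_mp_times_ll_equals_tp(self):
        pairs = _fit_pairs([(730.0, 0.26, 0.09), (500.0, 0.4, 0.02),
                            (900.0, 0.1, 0.05)])
        table = traits_table(pairs)
        np.testing.assert_allclose(table["MP"] * table["LL"], table["TP"],
                                   rtol=1e-9)

    def test_pp_is_the_curve_maximum_on_a_fine_grid(self):
        pairs = _fit_pairs([(730.0, 0.26, 0.09), (500.0, 0.4, 0.02)])
        grid = np.arange(1e-2, 300.0, 1e-2)
        for lact, fit in pairs:
            tr = compute_traits(fit)
            curve_max = float(np.max(np.asarray(fit.predict(grid))))
            assert tr["PP"] >= curve_max - 1e-9
            assert tr["PP"] == pytest.approx(curve_max, rel=1e-4)

    def test_mean_of_peak_dates_differs_from_ratio_of_means(self):
        """mean(B_i/C_i) != mean(B)/mean(C) on a heterogeneous cohort — the
        internal-consistency caveat for cohort-level trait summaries."""
        pairs = _fit_pairs([(700.0, 0.1, 0.08), (700.0, 0.5, 0.01),
                            (700.0, 0.3, 0.04)])
        table = traits_table(pairs)
        mean_pd = table["PD"].mean()
        ratio = table["B"].mean() / table["C"].mean()
        assert abs(mean_pd - ratio) > 1.0


def test_trait_bundle_from_results_object(noiseless_wood_lactation):
    res = LactationCurveModel.from_record(noiseless_wood_lactation, "wood").fit()
    tr = res.traits()
    assert tr["LL"] == 147.0
    assert tr["MP"] == pytest.approx(tr["TP"] / tr["LL"], rel=1e-9)
    assert tr["PD"] == pytest.approx(2.8889, abs=1e-4)
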