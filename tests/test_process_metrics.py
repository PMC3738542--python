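"""Growth rates, replicate summaries, stoichiometry and carbon balances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fermscope import elements
from fermscope.elements import ElementalComposition, carbon_fraction
from fermscope.errors import DomainError, InsufficientDataError, MissingDataError
from fermscope.process_metrics import (
    PROCESS_COLUMNS,
    ProcessTimeSeries,
    average_growth_rate,
    carbon_balance,
    fit_growth_rate,
    glucose_equivalent,
    integrate_offgas,
    summarize_replicates,
    yield_coefficients,
)


def make_series(time, cdm=1.0, glucose=0.0, acetate=0.0, formate=0.0,
                pyruvate=0.0, lactate=0.0, co2_rate=0.0, **kwargs):
    frame = pd.DataFrame({"time_h": np.asarray(time, dtype=float)})
    for col, val in zip(PROCESS_COLUMNS[1:],
                        (cdm, glucose, acetate, formate, pyruvate, lactate, co2_rate)):
        frame[col] = val
    return ProcessTimeSeries(frame, **kwargs)


class TestSummarizeReplicates:
    @pytest.mark.parametrize(
        "values, mean, sem",
        [
            ((13.33, 14.41, 13.43), 13.72, 0.34),  # HMS174 end CDM
            ((6.25, 6.00, 5.54), 5.93, 0.21),  # HMS174 max acetate
            ((15.16, 14.88, 17.49), 15.84, 0.83),  # RV308 end CDM
            ((6.01, 4.70, 5.89), 5.53, 0.42),  # RV308 max acetate
            ((5, 5, 5), 5.0, 0.0),
        ],
    )
    def test_reported_summaries(self, values, mean, sem):
        s = summarize_replicates(values)
        assert round(s.mean, 2) == mean
        assert round(s.sem, 2) == sem
        assert s.n == len(values)

    def test_single_value_has_zero_sem(self):
        s = summarize_replicates([3.0])
        assert (s.mean, s.sem, s.n) == (3.0, 0.0, 1)

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            summarize_replicates([])

    @given(st.lists(st.floats(0.1, 100.0), min_size=2, max_size=8),
           st.randoms(use_true_random=False))
    def test_permutation_invariant(self, values, rnd):
        ref = summarize_replicates(values)
        shuffled = list(values)
        rnd.shuffle(shuffled)
        s = summarize_replicates(shuffled)
        assert s.mean == pytest.approx(ref.mean, rel=1e-12)
        assert s.sem == pytest.approx(ref.sem, rel=1e-9, abs=1e-12)


class TestGrowthRate:
    def test_exact_exponential(self, exponential_series):
        fit = fit_growth_rate(exponential_series)
        assert fit.rate == pytest.approx(0.5, abs=1e-12)
        assert fit.stderr == pytest.approx(0.0, abs=1e-9)

    def test_window_invariance_on_exponential(self, exponential_series):
        full = fit_growth_rate(exponential_series).rate
        windowed = fit_growth_rate(exponential_series, window=(1.0, 4.0)).rate
        assert windowed == pytest.approx(full, abs=1e-10)

    def test_constant_cdm_gives_zero(self):
        series = make_series([0, 1, 2, 3], cdm=2.5)
        assert fit_growth_rate(series).rate == pytest.approx(0.0, abs=1e-14)
        assert average_growth_rate(series) == pytest.approx(0.0, abs=1e-14)

    def test_too_few_points_raises(self):
        series = make_series([0, 1, 2, 3], cdm=1.0)
        with pytest.raises(InsufficientDataError):
            fit_growth_rate(series, window=(0.0, 1.0))

    def test_nonpositive_cdm_raises(self):
        frame = make_series([0, 1, 2, 3], cdm=1.0).data.copy()
        frame.loc[1, "cdm_g_per_L"] = 0.0
        with pytest.raises(DomainError):
            fit_growth_rate(ProcessTimeSeries(frame))


class TestCarbonFraction:
    @pytest.mark.parametrize(
        "comp, expected",
        [
            (ElementalComposition(c=1), 1.0),
            (elements.BIOMASS, 0.4805),  # 12.011 / 24.997 by hand
            (elements.ACETATE, 0.4068),  # 24.022 / 59.044 by hand
        ],
    )
    def test_known_fractions(self, comp, expected):
        assert carbon_fraction(comp) == pytest.approx(expected, abs=5e-5)

    def test_zero_carbon_rejected(self):
        with pytest.raises(DomainError):
            ElementalComposition(c=0, h=2, o=1)


class TestGlucoseEquivalent:
    def test_reported_stoichiometry(self):
        assert round(glucose_equivalent(6.0), 2) == 9.00
        assert round(glucose_equivalent(1.3), 2) == 1.95
        assert glucose_equivalent(0.0) == 0.0

    def test_negative_mass_raises(self):
        with pytest.raises(DomainError):
            glucose_equivalent(-1.0)


class TestYieldCoefficients:
    @pytest.mark.parametrize(
        "cdm, s0, acetate, corrected",
        [
            (15.84, 40.0, 6.0, 0.51),  # RV308
            (17.41, 40.0, 1.3, 0.46),  # BL21
            (13.72, 40.0, 6.0, 0.44),  # HMS174
        ],
    )
    def test_corrected_yields(self, cdm, s0, acetate, corrected):
        assert round(yield_coefficients(cdm, s0, acetate).yxs_corrected, 2) == corrected

    def test_no_byproduct_equals_raw(self):
        res = yield_coefficients(10.0, 40.0, 0.0)
        assert res.yxs_corrected == res.yxs_raw

    def test_excess_byproduct_raises(self):
        with pytest.raises(DomainError):
            yield_coefficients(10.0, 10.0, 20.0)

    @given(st.floats(0.0, 10.0), st.floats(0.1, 10.0))
    def test_monotone_in_byproduct(self, acetate, delta):
        lo = yield_coefficients(15.0, 40.0, acetate).yxs_corrected
        hi = yield_coefficients(15.0, 40.0, min(acetate + delta, 20.0)).yxs_corrected
        assert hi >= lo


class TestOffgasAndBalance:
    def test_constant_rate_integrates_to_rtv(self):
        series = make_series(np.linspace(0, 5, 11), co2_rate=2.0, volume=4.0)
        assert integrate_offgas(series) == pytest.approx(2.0 * 5.0 * 4.0)

    def test_cumulative_flag_uses_last_value(self):
        series = make_series([0, 1, 2], co2_rate=0.0, volume=2.0, co2_cumulative=True)
        series.data["co2_rate_gC_per_L_h"] = [0.0, 1.5, 3.0]
        assert integrate_offgas(series) == pytest.approx(6.0)

    def test_missing_channel_raises(self):
        series = make_series([0, 1, 2])
        series.data["co2_rate_gC_per_L_h"] = np.nan
        with pytest.raises(MissingDataError):
            integrate_offgas(series)

    def test_reported_pool_percentage_consistency(self):
        # a biomass pool of 32.81 g stated as 59.68% of input fixes the total;
        # a 16.16 g CO2 pool must then come out at 29.40%
        total = 32.81 / 0.5968
        cdm = 32.81 / carbon_fraction(elements.BIOMASS) / 4.0
        series = make_series([0, 1, 2], cdm=cdm, co2_rate=16.16 / 4.0 / 2.0)
        balance = carbon_balance(series, total_input_carbon=total)
        assert balance.pools_g["biomass"] == pytest.approx(32.81, abs=1e-9)
        # 29.394% computed vs 29.40% printed: both percentages were rounded
        # independently from an unprinted common total
        assert balance.percentages["co2"] == pytest.approx(29.40, abs=0.01)

    def test_zero_metabolites_leave_two_pools(self):
        series = make_series([0, 1, 2], cdm=5.0, co2_rate=1.0)
        balance = carbon_balance(series, total_input_carbon=30.0)
        nonzero = {k for k, v in balance.pools_g.items() if v > 0}
        assert nonzero == {"biomass", "co2"}
        assert balance.recovery == pytest.approx(sum(balance.percentages.values()))

    def test_nonpositive_total_raises(self):
        series = make_series([0, 1, 2], cdm=5.0, co2_rate=1.0)
        with pytest.raises(DomainError):
            carbon_balance(series, total_input_carbon=0.0)


class TestSeriesValidation:
    def test_time_must_increase(self):
        with pytest.raises(DomainError):
            make_series([0.0, 1.0, 1.0])

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            make_series([0, 1, 2], cdm=-1.0)

    def test_tsv_roundtrip(self, tmp_path, exponential_series):
        path = tmp_path / "run.tsv"
        exponential_series.to_tsv(path)
        back = ProcessTimeSeries.from_tsv(path)
        pd.testing.assert_frame_equal(back.data, exponential_series.data)
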