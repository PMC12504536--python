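"""Curve inversion, equivalence ratios, and published-table arithmetic."""

import math

import numpy as np
import pytest

from paequiv import (
    DoseResponseCurve,
    cross_outcome_median,
    derive_secondary_ratio,
    equivalence_grid,
    invert_curve,
)
from paequiv.errors import ArgumentError, PipelineError
from paequiv.reference import (
    NON_CANCER_OUTCOMES,
    PUBLISHED_MEDIANS,
    cross_outcome_summaries,
    derived_secondary_ratios,
)


def loglinear_curve(slope, outcome="acm", intensity="vpa", dmax=40.0, referent=0.0):
    dose = np.arange(referent, dmax, 0.1)
    return DoseResponseCurve(
        intensity=intensity,
        outcome=outcome,
        dose=dose,
        hr=np.exp(slope * (dose - referent)),
        se_log_hr=np.zeros_like(dose),
        referent=referent,
    )


class TestInvertCurve:
    def test_target_one_returns_referent(self):
        curve = loglinear_curve(-0.04)
        assert invert_curve(curve, 1.0) == 0.0

    def test_closed_form_inversion(self):
        # HR(d) = exp(-0.04 d), target 0.80 -> d = -ln(0.80)/0.04
        curve = loglinear_curve(-0.04)
        expected = -math.log(0.80) / 0.04
        assert invert_curve(curve, 0.80) == pytest.approx(expected, abs=1e-3)

    def test_flat_null_curve_undefined(self):
        curve = loglinear_curve(0.0)
        assert math.isnan(invert_curve(curve, 0.95))

    def test_first_crossing_on_nonmonotone_curve(self):
        dose = np.arange(0.0, 30.0, 0.1)
        hr = 1.0 - 0.01 * dose  # down ...
        hr[dose > 20] = 1.0  # ... then back up
        curve = DoseResponseCurve("vpa", "acm", dose, hr, np.zeros_like(dose), 0.0)
        assert invert_curve(curve, 0.9) == pytest.approx(10.0, abs=0.1)

    def test_invalid_target_raises(self):
        curve = loglinear_curve(-0.04)
        with pytest.raises(ArgumentError):
            invert_curve(curve, 0.0)
        with pytest.raises(ArgumentError):
            invert_curve(curve, 1.2)


class TestEquivalenceGrid:
    def test_identical_curves_give_unit_ratio(self):
        v = loglinear_curve(-0.04, intensity="vpa")
        m = loglinear_curve(-0.04, intensity="mpa")
        l = loglinear_curve(-0.005, intensity="lpa", dmax=400.0)
        table = equivalence_grid(v, m, l)
        defined = table.ratio_mpa[~np.isnan(table.ratio_mpa)]
        assert np.allclose(defined, 1.0, atol=1e-9)
        assert table.median_ratio_mpa == pytest.approx(1.0)

    def test_loglinear_ratio_level_independent(self):
        v = loglinear_curve(-0.04, intensity="vpa")
        m = loglinear_curve(-0.01, intensity="mpa", dmax=200.0)
        l = loglinear_curve(-0.002, intensity="lpa", dmax=900.0)
        for step in (0.1, 5.0):  # continuous and reporting modes
            table = equivalence_grid(v, m, l, step=step)
            # flat up to the 0.1-min dose-grid interpolation error
            assert np.nanmax(table.ratio_mpa) - np.nanmin(table.ratio_mpa) < 1e-3
            assert table.median_ratio_mpa == pytest.approx(4.0, abs=1e-3)
            assert table.median_ratio_lpa == pytest.approx(20.0, abs=5e-3)

    def test_weaker_curve_ratio_above_one_everywhere(self):
        v = loglinear_curve(-0.04, intensity="vpa")
        m = loglinear_curve(-0.02, intensity="mpa", dmax=100.0)
        l = loglinear_curve(-0.001, intensity="lpa", dmax=2000.0)
        table = equivalence_grid(v, m, l)
        assert np.all(table.ratio_mpa[~np.isnan(table.ratio_mpa)] > 1.0)

    def test_partial_lpa_definition_median_over_defined(self):
        # LPA curve only reaches ~15% reduction: levels beyond are undefined
        v = loglinear_curve(-0.04, intensity="vpa")
        m = loglinear_curve(-0.01, intensity="mpa", dmax=200.0)
        dose = np.arange(0.0, 200.0, 0.1)
        hr = np.maximum(np.exp(-0.002 * dose), 0.85)
        l = DoseResponseCurve("lpa", "acm", dose, hr, np.zeros_like(dose), 0.0)
        table = equivalence_grid(v, m, l)
        reachable = table.rr_levels <= 15.0 + 1e-9
        assert np.all(np.isnan(table.ratio_lpa[~reachable]))
        assert np.all(~np.isnan(table.ratio_lpa[reachable]))
        assert table.n_defined_lpa == int(reachable.sum())
        # median over the defined part equals the level-independent value
        assert table.median_ratio_lpa == pytest.approx(20.0, abs=1e-2)

    def test_cap_mode_imputes_max_dose(self):
        v = loglinear_curve(-0.04, intensity="vpa")
        m = loglinear_curve(-0.01, intensity="mpa", dmax=200.0)
        l = loglinear_curve(0.0, intensity="lpa", dmax=100.0)
        table = equivalence_grid(v, m, l, undefined="cap")
        assert table.undefined_handling == "cap"
        assert not np.any(np.isnan(table.ratio_lpa))

    def test_all_undefined_vpa_raises(self):
        v = loglinear_curve(0.0, intensity="vpa")
        m = loglinear_curve(-0.01, intensity="mpa", dmax=200.0)
        l = loglinear_curve(-0.002, intensity="lpa", dmax=900.0)
        with pytest.raises(PipelineError):
            equivalence_grid(v, m, l)

    def test_mixed_outcomes_raise(self):
        v = loglinear_curve(-0.04, outcome="acm")
        m = loglinear_curve(-0.01, outcome="cvd", intensity="mpa", dmax=200.0)
        l = loglinear_curve(-0.002, intensity="lpa", dmax=900.0)
        with pytest.raises(ArgumentError):
            equivalence_grid(v, m, l)


class TestSecondaryRatioArithmetic:
    @pytest.mark.parametrize(
        "lpa,mpa,expected",
        [
            (52.65, 4.09, 12.87),
            (156.23, 3.47, 45.02),
            (72.47, 7.78, 9.31),
        ],
    )
    def test_published_examples(self, lpa, mpa, expected):
        assert derive_secondary_ratio(lpa, mpa) == expected

    def test_equal_inputs_give_one(self):
        assert derive_secondary_ratio(7.5, 7.5) == 1.00

    def test_nan_propagates(self):
        assert math.isnan(derive_secondary_ratio(math.nan, 4.0))

    def test_all_published_rows_reproduced(self):
        derived = derived_secondary_ratios()
        for outcome, (_, _, printed) in PUBLISHED_MEDIANS.items():
            assert derived[outcome] == printed


class TestCrossOutcomeMedian:
    def test_published_mpa_values(self):
        med = cross_outcome_median([4.09, 7.78, 5.44, 9.40])
        assert med == pytest.approx(6.61)
        assert round(med, 1) == 6.6

    def test_published_lpa_values(self):
        med = cross_outcome_median([52.65, 72.47, 86.13, 94.03])
        assert med == pytest.approx(79.30)
        assert round(med, 1) == 79.3

    def test_singleton(self):
        assert cross_outcome_median([3.3]) == 3.3

    def test_empty_raises(self):
        with pytest.raises(ArgumentError):
            cross_outcome_median([])

    def test_summary_helper_consistent(self):
        s = cross_outcome_summaries()
        vals_m = [PUBLISHED_MEDIANS[o][0] for o in NON_CANCER_OUTCOMES]
        assert s["median_mpa_per_vpa"] == float(np.median(vals_m))
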