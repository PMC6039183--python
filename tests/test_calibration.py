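"""Standard-curve fitting, ABC interpolation and genotype corrections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hlabquant import calibration, cohort
from hlabquant.exceptions import (CalibrationError, DomainError, PairingError,
                                  RangeError, InsufficientDataError)

from conftest import make_cohort_design


def _ols(x, y):
    """Closed-form simple OLS oracle."""
    x, y = np.asarray(x), np.asarray(y)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    return slope, y.mean() - slope * x.mean()


class TestStandardCurve:
    def test_identity_log_log(self):
        curve = calibration.StandardCurve([10, 100, 1000],
                                          [10, 100, 1000]).fit("log-log")
        assert curve.slope == pytest.approx(1.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_proportional_linear(self):
        mfi = np.array([10.0, 100.0, 1000.0])
        curve = calibration.StandardCurve(5 * mfi, mfi).fit("linear-linear")
        assert curve.slope == pytest.approx(5.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)

    def test_noisy_fit_matches_closed_form_ols(self, rng):
        mfi = np.array([50.0, 400.0, 3_000.0, 20_000.0])
        abc = np.exp(0.3 + 0.92 * np.log(mfi)) * rng.lognormal(0, 0.05, 4)
        curve = calibration.StandardCurve(abc, mfi).fit("log-log")
        slope, intercept = _ols(np.log(mfi), np.log(abc))
        assert curve.slope == pytest.approx(slope, rel=1e-12)
        assert curve.intercept == pytest.approx(intercept, rel=1e-12)

    def test_too_few_standards_rejected(self):
        with pytest.raises(CalibrationError):
            calibration.StandardCurve([10, 100], [10, 100])

    def test_nonpositive_mfi_rejected_in_log_mode(self):
        sc = calibration.StandardCurve([10, 100, 1000], [0, 100, 1000])
        with pytest.raises(CalibrationError):
            sc.fit("log-log")


class TestInterpolation:
    def test_identity_midpoint(self, identity_curve):
        assert identity_curve.interpolate(250.0) == pytest.approx(250.0)

    def test_round_trip_on_standards(self):
        beads = cohort.simulate_bead_standards(0.85, 0.4,
                                               [1e3, 1e4, 1e5, 1e6])
        curve = calibration.fit_standard_curve(beads, mode="log-log")
        for abc, mfi in zip(beads["abc"], beads["mfi"]):
            assert curve.interpolate(mfi) == pytest.approx(abc, rel=1e-9)

    def test_out_of_range_policies(self, identity_curve):
        with pytest.raises(RangeError):
            identity_curve.interpolate(1e9, out_of_range="error")
        with pytest.warns(UserWarning):
            clamped = identity_curve.interpolate(1e9, out_of_range="clamp")
        assert clamped == pytest.approx(1e7)
        extr = identity_curve.interpolate(1e9, out_of_range="extrapolate")
        assert extr == pytest.approx(1e9)

    @given(st.lists(st.floats(min_value=1.0, max_value=1e8),
                    min_size=2, max_size=12))
    def test_monotone_in_mfi(self, mfis):
        beads = cohort.simulate_bead_standards(0.9, 0.5, [1e2, 1e4, 1e6])
        curve = calibration.fit_standard_curve(beads)
        out = curve.interpolate(np.sort(mfis), out_of_range="extrapolate")
        assert np.all(np.diff(out) >= 0)


class TestSubtractIsotype:
    @pytest.mark.parametrize("spec,iso,expect,floored", [
        (500.0, 100.0, 400.0, False),
        (80.0, 100.0, 0.0, True),
        (500.0, 0.0, 500.0, False),
    ])
    def test_examples(self, spec, iso, expect, floored):
        res = calibration.subtract_isotype(spec, iso, floor=0.0)
        assert res.value == expect
        assert res.floored is floored

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            calibration.subtract_isotype(-1.0, 0.0)


class TestComputeAbc:
    def _stains(self, mfi, antibody="anti-Bw6"):
        return pd.DataFrame([{"donor": "d1", "draw": "x", "subset": "CD4T",
                              "antibody": antibody, "mfi": mfi,
                              "isotype_mfi": 0.0}])

    def _geno(self, homo):
        return pd.DataFrame([{"donor": "d1", "epitope_homozygous": homo,
                              "both_c_epitope_bearing": homo}])

    def test_heterozygous_identity(self, identity_curve):
        out = calibration.compute_abc(self._stains(40_000.0), identity_curve,
                                      self._geno(False))
        assert out["abc"].iloc[0] == pytest.approx(40_000.0)
        assert not out["corrected"].iloc[0]

    def test_homozygote_correction_halves_epitope(self, identity_curve):
        out = calibration.compute_abc(self._stains(40_000.0), identity_curve,
                                      self._geno(True))
        assert out["abc"].iloc[0] == pytest.approx(20_000.0)
        assert out["corrected"].iloc[0]

    def test_pan_class_i_never_halved(self, identity_curve):
        out = calibration.compute_abc(self._stains(40_000.0, "W6/32"),
                                      identity_curve, self._geno(True))
        assert out["abc"].iloc[0] == pytest.approx(40_000.0)

    def test_missing_isotype_pair_raises(self, identity_curve):
        stains = self._stains(40_000.0)
        stains.loc[0, "isotype_mfi"] = np.nan
        with pytest.raises(PairingError):
            calibration.compute_abc(stains, identity_curve, self._geno(False))

    def test_zero_noise_cohort_round_trip(self, zero_noise_cohort):
        design, stains, genotypes, truth = zero_noise_cohort
        beads = cohort.simulate_bead_standards(
            design.curve_slope, design.curve_intercept,
            [1e2, 1e3, 1e4, 1e5, 1e6])
        curve = calibration.fit_standard_curve(beads)
        cal = calibration.calibrate_stains(stains, curve, genotypes)
        merged = cal.merge(truth, on=["donor", "draw", "subset", "antibody"])
        rel = np.abs(merged["abc"] / merged["true_abc"] - 1.0)
        assert rel.max() < 1e-9


class TestAggregation:
    def test_textbook_mean_sem(self):
        s = calibration.aggregate_donor([10.0, 20.0, 30.0])
        assert s.mean == 20.0
        assert s.sem == pytest.approx(10.0 / np.sqrt(3))
        assert s.n == 3 and not s.single_draw

    def test_single_draw_flagged(self):
        s = calibration.aggregate_donor([7.0])
        assert (s.mean, s.sem, s.n, s.single_draw) == (7.0, 0.0, 1, True)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            calibration.aggregate_donor([])

    def test_epitope_ratio(self):
        assert calibration.epitope_ratio(20_000, 40_000) == 0.5
        assert calibration.epitope_ratio(3.0, 3.0) == 1.0
        with pytest.raises(DomainError):
            calibration.epitope_ratio(1.0, 0.0)

    def test_ratio_recovered_from_design(self, zero_noise_cohort):
        design, stains, genotypes, _ = zero_noise_cohort
        beads = cohort.simulate_bead_standards(
            design.curve_slope, design.curve_intercept,
            [1e2, 1e3, 1e4, 1e5, 1e6])
        curve = calibration.fit_standard_curve(beads)
        agg = calibration.aggregate_abc(
            calibration.calibrate_stains(stains, curve, genotypes))
        ratios = calibration.epitope_ratio_table(agg)
        # generator default epitope/pan ratio is 0.5
        assert ratios["ratio_to_pan"].to_numpy() == pytest.approx(0.5)


class TestReferenceSubsetNormalization:
    def _agg(self):
        return pd.DataFrame([
            {"donor": "d1", "subset": "CD4T", "antibody": "anti-Bw6",
             "mean_abc": 5_000.0},
            {"donor": "d1", "subset": "monocyte", "antibody": "anti-Bw6",
             "mean_abc": 20_000.0},
            {"donor": "d2", "subset": "CD4T", "antibody": "anti-Bw6",
             "mean_abc": 8_000.0},
        ])

    def test_reference_row_is_one_and_ratio(self):
        out = calibration.normalize_to_reference_subset(self._agg(),
                                                        "monocyte")
        d1 = out[out["donor"] == "d1"].set_index("subset")
        assert d1.loc["monocyte", "normalized"] == 1.0
        assert d1.loc["CD4T", "normalized"] == 0.25

    def test_missing_reference_flagged_not_dropped(self):
        out = calibration.normalize_to_reference_subset(self._agg(),
                                                        "monocyte")
        d2 = out[out["donor"] == "d2"]
        assert len(d2) == 1
        assert d2["missing_reference"].iloc[0]
        assert np.isnan(d2["normalized"].iloc[0])
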