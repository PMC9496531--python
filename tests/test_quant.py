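"""Region AUC, calibration with ICH figures of merit, quantification, MS comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from liqspec import (
    DomainError,
    GridError,
    InsufficientDataError,
    InvalidCurveError,
    MixtureSpec,
    NotBaselinedError,
    REGIONS,
    Region,
    Spectrum,
    SpectralRangeError,
    calibrate_from_titration,
    compare_to_ms,
    fit_calibration,
    generate_titration,
    measured_fraction,
    percent_error,
    quantify,
    region_auc,
    render_spectrum,
)
from liqspec.quant import CalibrationCurve
from liqspec.synth import analytic_region_integral

CH = REGIONS["CH"]


def flat_spectrum(value, low=2600.0, high=3200.0, step=8.0):
    w = np.arange(low, high + step / 2, step)
    return Spectrum(w, np.full(w.size, float(value)), baseline_corrected=True)


class TestRegionAuc:
    def test_constant_trace(self):
        s = flat_spectrum(1.0)
        assert region_auc(s, CH) == pytest.approx(200.0)
        assert region_auc(s, CH, local_baseline=True) == pytest.approx(0.0)

    def test_triangle_peak_closed_form(self):
        s = Spectrum(
            np.array([2800.0, 2900.0, 3000.0]), np.array([0.0, 1.0, 0.0]),
            baseline_corrected=True,
        )
        assert region_auc(s, CH) == pytest.approx(100.0)
        assert region_auc(s, CH, local_baseline=True) == pytest.approx(100.0)

    @settings(derandomize=True, max_examples=25)
    @given(
        a=st.floats(-3, 3, allow_nan=False),
        b=st.floats(-3, 3, allow_nan=False),
        local=st.booleans(),
    )
    def test_linearity_in_the_spectrum(self, a, b, local):
        s1 = render_spectrum(MixtureSpec({"lipid_ester": 1.0}))
        s2 = render_spectrum(MixtureSpec({"broad_OH": 0.5}))
        combo = s1.with_absorbance(a * s1.absorbance + b * s2.absorbance)
        lhs = region_auc(combo, CH, local)
        rhs = a * region_auc(s1, CH, local) + b * region_auc(s2, CH, local)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_local_baseline_invariant_under_added_line(self, lipid_spectrum):
        w = lipid_spectrum.wavenumbers
        tilted = lipid_spectrum.with_absorbance(
            lipid_spectrum.absorbance + 0.3 + 1e-4 * w
        )
        local0 = region_auc(lipid_spectrum, CH, local_baseline=True)
        local1 = region_auc(tilted, CH, local_baseline=True)
        assert local1 == pytest.approx(local0, rel=1e-9, abs=1e-9)
        # the plain AUC, by contrast, shifts by the area of the added line
        assert region_auc(tilted, CH) != pytest.approx(
            region_auc(lipid_spectrum, CH), rel=1e-3
        )

    def test_dense_gaussian_matches_analytic_integral(self):
        fine = np.arange(2700.0, 3101.0, 1.0)
        amounts = {"lipid_ester": 0.8}
        s = render_spectrum(MixtureSpec(amounts, grid=fine))
        expected = analytic_region_integral(amounts, CH.low, CH.high)
        assert region_auc(s, CH) == pytest.approx(expected, rel=1e-3)

    def test_requires_baselined_spectrum(self, lipid_spectrum):
        raw = lipid_spectrum.with_absorbance(
            lipid_spectrum.absorbance, baseline_corrected=False
        )
        with pytest.raises(NotBaselinedError):
            region_auc(raw, CH)
        region_auc(raw, CH, require_baselined=False)  # explicit override

    def test_region_outside_span(self):
        s = flat_spectrum(1.0, low=1000.0, high=1500.0)
        with pytest.raises(SpectralRangeError):
            region_auc(s, CH)

    def test_region_with_too_few_points(self):
        s = Spectrum(np.array([2000.0, 2900.0, 3600.0]), np.zeros(3),
                     baseline_corrected=True)
        with pytest.raises(GridError):
            region_auc(s, CH)  # only one grid point inside 2800-3000

    def test_region_bounds_validated(self):
        with pytest.raises(DomainError):
            Region("bad", 3000.0, 2800.0)


class TestFitCalibration:
    def test_exact_line_closed_form(self):
        masses = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        aucs = 2.0 * masses + 1.0
        curve = fit_calibration(masses, aucs, sd_blank=3.0)
        assert curve.slope == pytest.approx(2.0, abs=1e-12)
        assert curve.intercept == pytest.approx(1.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.slope_se == pytest.approx(0.0, abs=1e-9)
        assert curve.lod == pytest.approx(4.5)
        assert curve.loq == pytest.approx(15.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("log_log", [False, True])
    def test_loq_lod_ratio_is_ten_thirds(self, seed, log_log):
        rng = np.random.default_rng(seed)
        masses = np.repeat([0.0, 40.0, 125.0, 500.0, 2000.0], 3)
        aucs = 0.05 * masses + 0.2 + rng.normal(0, 0.05, masses.size)
        aucs = np.clip(aucs, 1e-6, None)
        curve = fit_calibration(masses, aucs, log_log=log_log)
        assert curve.loq / curve.lod == pytest.approx(10.0 / 3.0, rel=1e-12)

    def test_insufficient_levels(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration([1.0, 2.0], [2.0, 4.0], sd_blank=1.0)

    def test_negative_slope_rejected(self):
        masses = [1.0, 2.0, 3.0]
        with pytest.raises(InvalidCurveError):
            fit_calibration(masses, [5.0, 3.0, 1.0], sd_blank=1.0)

    def test_log_log_requires_positive_values(self):
        with pytest.raises(DomainError):
            fit_calibration([1.0, 2.0, 3.0], [-1.0, 2.0, 3.0],
                            sd_blank=1.0, log_log=True)

    def test_sd_blank_needs_blanks_or_value(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration([1.0, 2.0, 3.0], [1.1, 2.2, 3.1])

    def test_noiseless_titration_recovers_response_exactly(self):
        sset, truth = generate_titration(noise_sd=0.0)
        curve = calibrate_from_titration(sset, truth, sd_blank=0.5)
        unit = render_spectrum(MixtureSpec({"lipid_ester": 1.0}))
        true_slope = region_auc(unit, CH) / 1000.0
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.slope == pytest.approx(true_slope, rel=1e-9)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)

    def test_curve_json_roundtrip(self, tmp_path):
        curve = fit_calibration(
            [0.0, 0.0, 0.0, 1.0, 2.0, 3.0],
            [0.02, -0.01, 0.01, 2.1, 4.2, 6.1],
            sd_blank=0.3,
        )
        p = tmp_path / "curve.json"
        curve.to_json(p)
        back = CalibrationCurve.from_json(p)
        assert back == curve


class TestQuantify:
    @staticmethod
    def make_curve(slope=2.0, intercept=1.0, sd_blank=3.0):
        lod = 3.0 * sd_blank / slope
        return CalibrationCurve(
            region=CH, slope=slope, intercept=intercept, slope_se=0.0,
            r_squared=1.0, sd_blank=sd_blank, snr=float("nan"),
            lod=lod, loq=10.0 / 3.0 * lod,
        )

    def test_linear_inversion(self):
        q = quantify(21.0, self.make_curve(), sample_id="A")
        assert q.mass_ng == pytest.approx(10.0)
        assert not q.below_lod
        assert q.below_loq  # 10 ng sits between LOD (4.5) and LOQ (15)

    def test_boundary_flags_at_lod(self):
        curve = self.make_curve()
        auc_at_lod = curve.intercept + curve.slope * curve.lod
        q = quantify(auc_at_lod, curve)
        assert q.mass_ng == pytest.approx(curve.lod)
        assert not q.below_lod
        assert q.below_loq

    def test_negative_mass_reported_not_clipped(self):
        q = quantify(0.5, self.make_curve())  # below the intercept
        assert q.mass_ng < 0
        assert q.below_lod and q.below_loq

    def test_calibration_point_round_trip(self):
        sset, truth = generate_titration(seed=9)
        curve = calibrate_from_titration(sset, truth)
        point = next(s for s in sset if "1000ng_r1" in s.sample_id)
        q = quantify(region_auc(point, CH), curve)
        assert q.mass_ng == pytest.approx(1000.0, rel=0.05)

    def test_log_log_inversion(self):
        masses = np.array([10.0, 100.0, 1000.0])
        aucs = 0.05 * masses  # slope 1, intercept log2(0.05) on log2 scale
        curve = fit_calibration(masses, aucs, sd_blank=0.1, log_log=True)
        q = quantify(5.0, curve)
        assert q.mass_ng == pytest.approx(100.0, rel=1e-9)


class TestWorkedExamples:
    def test_splash_overestimate_percent(self):
        assert round(percent_error(921.5, 794.0)) == 16

    def test_stearic_underestimate_percent(self):
        assert round(percent_error(748.3, 794.0)) == -6

    def test_measured_fractions(self):
        assert measured_fraction(6.0, 100.0) == pytest.approx(0.06)
        assert measured_fraction(1.0, 12.0) == pytest.approx(0.0833, abs=5e-5)
        with pytest.raises(DomainError):
            measured_fraction(13.0, 12.0)


class TestCompareToMs:
    @staticmethod
    def tables(ftir, ms):
        q = pd.DataFrame({"sample_id": [f"S{i}" for i in range(len(ftir))],
                          "mass_ng": ftir})
        m = pd.DataFrame({"sample_id": [f"S{i}" for i in range(len(ms))],
                          "total_intensity": ms})
        return q, m

    def test_perfectly_proportional(self):
        q, m = self.tables([1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0])
        cmp = compare_to_ms(q, m)
        assert cmp.pearson_r == pytest.approx(1.0)
        assert cmp.r_squared == pytest.approx(1.0)
        assert cmp.n == 4

    def test_fraction_rescaling_affects_slope_not_r(self):
        rng = np.random.default_rng(0)
        ftir = rng.uniform(100, 1000, 20)
        ms = 3.0 * ftir + rng.normal(0, 20, 20)
        q, m = self.tables(ftir, ms)
        a = compare_to_ms(q, m, fraction_ftir=1 / 12, fraction_ms=0.06)
        b = compare_to_ms(q, m, fraction_ftir=0.06, fraction_ms=0.06)
        assert a.pearson_r == pytest.approx(b.pearson_r, rel=1e-12)
        ratio = (1 / 12) / 0.06
        assert a.slope == pytest.approx(b.slope / ratio, rel=1e-9)

    def test_too_few_pairs(self):
        q, m = self.tables([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            compare_to_ms(q, m)

    def test_zero_variance_degenerate(self):
        q, m = self.tables([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(DomainError):
            compare_to_ms(q, m)

    def test_sample_r_within_fisher_interval(self):
        # ρ = 0.8, n = 100: the sample correlation should land in the
        # Fisher-z-derived band [0.66, 0.89] in at least 95% of seeded draws
        n_runs, hits = 300, 0
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=100)
            y = 0.8 * x + np.sqrt(1 - 0.8**2) * rng.normal(size=100)
            q, m = self.tables(100 + 10 * x, 100 + 10 * y)
            cmp = compare_to_ms(q, m, fraction_ftir=1.0, fraction_ms=1.0)
            hits += 0.66 <= cmp.pearson_r <= 0.89
        assert hits / n_runs >= 0.95
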