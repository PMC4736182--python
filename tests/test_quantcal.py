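"""Well intensities, induction fold change, exponential calibration."""

import numpy as np
import pytest

from chipsyn import datasets
from chipsyn.fixtures import render_well_image
from chipsyn.quantcal import (
    CalibrationCurve,
    WellRegion,
    apply_calibration,
    fit_exponential,
    induction_fold,
    well_mean_intensity,
)


class TestWellIntensity:
    def test_uniform_field_recovers_value(self):
        img = np.full((100, 100), 0.42)
        reading = well_mean_intensity(img, WellRegion("w", 50, 50))
        assert reading.mean_intensity == pytest.approx(0.42)

    def test_rgb_uint8_uses_green_over_255(self):
        img = np.zeros((60, 60, 3), dtype=np.uint8)
        img[..., 1] = 102
        reading = well_mean_intensity(img, WellRegion("w", 30, 30))
        assert reading.mean_intensity == pytest.approx(102 / 255)

    def test_out_of_bounds_window_rejected(self):
        img = np.zeros((50, 50))
        with pytest.raises(ValueError, match="bounds"):
            well_mean_intensity(img, WellRegion("w", 5, 25))

    def test_rendered_wells_recover_amplitudes(self, rng):
        amps = {f"w{i}": a for i, a in enumerate([0.1, 0.25, 0.4, 0.6, 0.8, 0.95])}
        sigma = 0.01
        im = render_well_image(rng, amps, noise_sigma=sigma)
        for wid, (cx, cy) in im.centers.items():
            reading = well_mean_intensity(im.pixels, WellRegion(wid, cx, cy))
            # mean over 441 pixels: noise shrinks by 1/21
            assert reading.mean_intensity == pytest.approx(
                amps[wid], abs=3 * sigma / 21 + 1e-6
            )

    def test_off_center_window_sees_disk_falloff(self, rng):
        amps = {"w0": 0.8}
        im = render_well_image(rng, amps, noise_sigma=0.0, disk_radius=15.0)
        cx, cy = im.centers["w0"]
        centered = well_mean_intensity(im.pixels, WellRegion("w0", cx, cy))
        shifted = well_mean_intensity(im.pixels, WellRegion("w0", cx + 16, cy))
        assert centered.mean_intensity == pytest.approx(0.8, abs=1e-9)
        assert shifted.mean_intensity < centered.mean_intensity


class TestInductionFold:
    def test_printed_brightness_table_reproduces_fold(self):
        res = induction_fold(
            list(datasets.INDUCED_BRIGHTNESS.values()),
            list(datasets.UNINDUCED_BRIGHTNESS.values()),
        )
        assert res.induced_mean == pytest.approx(0.326, abs=5e-4)
        assert res.uninduced_mean == pytest.approx(0.0377, abs=5e-5)
        assert res.fold == pytest.approx(8.6, abs=0.05)

    def test_identical_groups_fold_one(self):
        res = induction_fold([0.3, 0.4], [0.3, 0.4])
        assert res.fold == pytest.approx(1.0)

    def test_elementwise_doubling_gives_fold_two(self):
        base = [0.1, 0.2, 0.15]
        res = induction_fold([2 * b for b in base], base)
        assert res.fold == pytest.approx(2.0)

    def test_scale_invariance(self):
        ind, non = [0.5, 0.6], [0.1, 0.2]
        f1 = induction_fold(ind, non).fold
        f2 = induction_fold([0.3 * x for x in ind], [0.3 * x for x in non]).fold
        assert f1 == pytest.approx(f2)


class TestFit:
    def test_noiseless_model_recovered_to_machine_precision(self):
        a, b = 5.0, 3.0
        pts = [(x, a * np.exp(b * x)) for x in (0.05, 0.1, 0.2, 0.3, 0.45)]
        curve = fit_exponential(pts, "offchip")
        assert curve.a == pytest.approx(a, rel=1e-12)
        assert curve.b == pytest.approx(b, rel=1e-12)
        for x, c in pts:
            assert apply_calibration(x, curve) == pytest.approx(c, rel=1e-10)

    def test_offchip_calibration_table_reproduces_printed_coefficients(self):
        curve = fit_exponential(datasets.OFFCHIP_CALIBRATION, "offchip")
        assert curve.b == pytest.approx(7.4512, rel=2e-3)
        assert curve.a == pytest.approx(3.2809, rel=5e-3)

    def test_noisy_recovery_within_standard_error(self):
        # Monte-Carlo: lognormal noise on concentrations; the ln-space OLS
        # slope estimate must cover the truth at its nominal standard error
        a, b, sigma = 5.0, 3.0, 0.05
        xs = np.array([0.05, 0.1, 0.2, 0.3, 0.4, 0.5])
        rng = np.random.default_rng(7)
        misses = 0
        n_trials = 200
        for _ in range(n_trials):
            cs = a * np.exp(b * xs) * rng.lognormal(0.0, sigma, size=xs.size)
            curve = fit_exponential(list(zip(xs, cs)), "offchip")
            resid = np.asarray(curve.residuals)
            se_b = np.sqrt(
                (resid @ resid / (len(xs) - 2)) / ((xs - xs.mean()) @ (xs - xs.mean()))
            )
            if abs(curve.b - b) > 3 * se_b:
                misses += 1
        assert misses <= 0.05 * n_trials  # 3-sigma misses should be rare

    def test_shift_equivariance(self):
        pts = [(x, 4.2 * np.exp(2.1 * x)) for x in (0.1, 0.2, 0.35, 0.5)]
        delta = 0.37
        c0 = fit_exponential(pts, "offchip")
        c1 = fit_exponential([(x + delta, c) for x, c in pts], "offchip")
        assert c1.b == pytest.approx(c0.b, rel=1e-9)
        assert c1.a == pytest.approx(c0.a * np.exp(-c0.b * delta), rel=1e-9)

    @pytest.mark.parametrize(
        "pts,err",
        [
            ([(0.1, 1.0), (0.2, 2.0)], "at least 3"),
            ([(0.1, 1.0), (0.2, -2.0), (0.3, 3.0)], "positive"),
            ([(0.1, 1.0), (0.1, 2.0), (0.1, 3.0)], "degenerate"),
        ],
    )
    def test_degenerate_inputs_rejected(self, pts, err):
        with pytest.raises(ValueError, match=err):
            fit_exponential(pts)


class TestApply:
    def test_printed_offchip_curve_at_od_0506(self):
        curve = CalibrationCurve("offchip", 3.2809, 7.4512)
        assert apply_calibration(0.506, curve) == pytest.approx(142.0, abs=1.0)

    def test_printed_onchip_curve_with_brightness_factor(self):
        curve = CalibrationCurve("onchip", 6e-19, 45.972)
        conc = apply_calibration(0.0077, curve, brightness_factor=3.6)
        assert conc == pytest.approx(140.0, abs=1.0)

    def test_predictor_zero_gives_factor_times_a(self):
        curve = CalibrationCurve("offchip", 2.5, 4.0)
        assert apply_calibration(0.0, curve, brightness_factor=3.6) == pytest.approx(9.0)

    def test_monotonicity(self):
        onchip = CalibrationCurve("onchip", 6e-19, 45.972)
        offchip = CalibrationCurve("offchip", 3.2809, 7.4512)
        intensities = np.linspace(0.0, 1.0, 25)
        preds = [apply_calibration(i, onchip) for i in intensities]
        assert all(a > b for a, b in zip(preds, preds[1:]))  # darker = more analyte
        ods = np.linspace(0.0, 0.6, 25)
        preds = [apply_calibration(o, offchip) for o in ods]
        assert all(a < b for a, b in zip(preds, preds[1:]))
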