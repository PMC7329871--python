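"""Propagation corrections, sensitivity calibration, directivity fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from echogaze import (MicCalibration, PropagationModel, calibrate_sensitivity,
                      correct_received_level, estimate_arrival_times,
                      fit_directivity, localize_pulse, pulse_direction)
from echogaze._angles import abs_diff_deg
from echogaze.localization import CalibrationError, DirectivityFitError
from echogaze.simulate import SimulationConfig, synthesize_received_levels


class TestPropagation:
    def test_correction_at_one_metre(self):
        # only absorption remains at the 1-m spreading reference
        assert correct_received_level(80.0, 1.0) == pytest.approx(82.4)

    def test_correction_at_two_metres(self):
        # 6.02 dB spreading + 4.8 dB absorption
        assert correct_received_level(80.0, 2.0) == pytest.approx(90.82, abs=0.01)

    def test_equal_ranges_equal_corrections(self):
        a = correct_received_level(70.0, 3.3)
        b = correct_received_level(55.0, 3.3)
        assert a - 70.0 == pytest.approx(b - 55.0)

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError):
            correct_received_level(80.0, 0.0)

    def test_doubling_range_without_absorption_is_spherical(self):
        model = PropagationModel(absorption_db_per_m=0.0)
        drop = model.loss_db(2.0) - model.loss_db(1.0)
        assert drop == pytest.approx(20.0 * np.log10(2.0), abs=1e-9)

    def test_synthesised_levels_follow_spherical_spreading(self, layout_perm):
        """Doubling source-mic distance with absorption off drops 6.02 dB."""
        config = SimulationConfig(condition="permeable", noise_sd_db=0.0,
                                  absorption_db_per_m=0.0)
        mic = layout_perm.mic_positions[0]  # frontal wall mic
        p1 = (mic[0] - 1.5, mic[1])
        p2 = (mic[0] - 3.0, mic[1])
        lv1, _, _ = synthesize_received_levels(p1, 0.0, layout_perm, config)
        lv2, _, _ = synthesize_received_levels(p2, 0.0, layout_perm, config)
        assert lv1[0] - lv2[0] == pytest.approx(20.0 * np.log10(2.0), abs=1e-9)

    def test_arrival_delay_ten_ms(self, layout_perm):
        mic = layout_perm.mic_positions[0]
        pos = (mic[0] - 3.44, mic[1])
        t = estimate_arrival_times(1.0, pos, layout_perm)
        assert t[0] == pytest.approx(1.010)

    def test_equidistant_channels_equal_arrivals(self, layout_perm):
        # frontal-wall mics symmetric about the aisle centre line
        pos = (6.0, 2.25)
        t = estimate_arrival_times(0.0, pos, layout_perm)
        mics = layout_perm.mic_positions
        sym = [(i, j) for i in range(6) for j in range(6)
               if i < j and np.isclose(mics[i][1] + mics[j][1], 4.5)]
        for i, j in sym:
            assert t[i] == pytest.approx(t[j])


class TestCalibration:
    def test_identical_responses_zero_offsets(self):
        cal = calibrate_sensitivity(np.full(20, 104.6))
        np.testing.assert_allclose(cal.sensitivity_offset_db, 0.0)

    def test_single_hot_channel(self):
        resp = np.full(20, 104.6)
        resp[7] += 3.0
        cal = calibrate_sensitivity(resp)
        assert cal.sensitivity_offset_db[7] == pytest.approx(3.0)
        mask = np.ones(20, bool)
        mask[7] = False
        np.testing.assert_allclose(cal.sensitivity_offset_db[mask], 0.0)

    def test_missing_channel_rejected(self):
        resp = np.full(20, 104.6)
        resp[3] = np.nan
        with pytest.raises(CalibrationError):
            calibrate_sensitivity(resp)

    def test_calibration_round_trip_restores_accuracy(self, layout_perm):
        """Per-channel offsets up to +/-6 dB, once calibrated out, leave
        noise-free direction errors at the offset-free level."""
        rng = np.random.default_rng(8)
        offsets = rng.uniform(-6.0, 6.0, size=20)
        config = SimulationConfig(condition="permeable", noise_sd_db=0.0)
        cal = MicCalibration(offsets)
        for true_dir in (-40.0, 5.0, 30.0):
            pos = (4.6, 2.2)
            levels, occ, _ = synthesize_received_levels(
                pos, true_dir, layout_perm, config,
                sensitivity_offsets=offsets)
            fit = localize_pulse(levels, pos, layout_perm, calibration=cal,
                                 occluded_mask=occ)
            assert abs_diff_deg(pulse_direction(fit), true_dir) < 1e-6


class TestDirectivityFit:
    def test_symmetric_pattern_peaks_at_zero(self):
        fit = fit_directivity([50, 60, 70, 60, 50], [-30, -15, 0, 15, 30])
        assert fit.direction_deg == pytest.approx(0.0, abs=1e-6)

    def test_generate_and_refit_recovers_mean(self):
        mu, sigma = 7.3, 20.0
        th = np.linspace(-80, 80, 15)
        lv = 30.0 * np.exp(-(th - mu) ** 2 / (2 * sigma ** 2)) + 40.0
        fit = fit_directivity(lv, th)
        assert fit.direction_deg == pytest.approx(mu, abs=0.1)
        assert fit.width_deg == pytest.approx(sigma, rel=0.01)

    def test_flat_pattern_fails(self):
        with pytest.raises(DirectivityFitError, match="flat"):
            fit_directivity([60.0] * 8, np.linspace(-90, 90, 8))

    def test_too_few_channels_fails(self):
        with pytest.raises(DirectivityFitError, match="channels"):
            fit_directivity([50, 60, 70, 60], [-30, -10, 10, 30])

    def test_narrow_span_fails(self):
        th = np.linspace(-15, 15, 6)
        lv = 60 + 10 * np.exp(-th ** 2 / 800)
        with pytest.raises(DirectivityFitError, match="span"):
            fit_directivity(lv, th)

    def test_wrap_direction_reported_in_range(self):
        th = np.array([150, 165, 180, -165, -150, -135])
        lv = 40 + 25 * np.exp(-(np.array([-25, -10, 5, 20, 35, 50]) ** 2) / (2 * 20.0 ** 2))
        fit = fit_directivity(lv, th)
        assert -180 < fit.direction_deg <= 180

    @given(st.floats(-30, 30))
    def test_global_gain_invariance(self, gain):
        th = np.linspace(-70, 70, 12)
        lv = 35.0 * np.exp(-(th + 12.0) ** 2 / (2 * 22.0 ** 2)) + 48.0
        base = fit_directivity(lv, th).direction_deg
        shifted = fit_directivity(lv + gain, th).direction_deg
        assert abs_diff_deg(shifted, base) < 1e-6


class TestFullReconstruction:
    def test_translation_along_beam_axis(self, layout_perm):
        """Moving the source along its own beam axis barely moves mu."""
        config = SimulationConfig(condition="permeable", noise_sd_db=0.0)
        true_dir = 15.0
        mus = []
        for d in (0.0, 0.5, 1.0):
            pos = (4.4 + d * np.cos(np.radians(true_dir)),
                   1.9 + d * np.sin(np.radians(true_dir)))
            levels, occ, _ = synthesize_received_levels(
                pos, true_dir, layout_perm, config)
            fit = localize_pulse(levels, pos, layout_perm, occluded_mask=occ)
            mus.append(pulse_direction(fit))
        assert max(abs_diff_deg(m, true_dir) for m in mus) < 1.0

    def test_reflective_occlusion_excludes_blocked_channels(self, layout_refl):
        config = SimulationConfig(condition="reflective", noise_sd_db=0.0)
        pos = (4.0, 2.1)  # before wall 1; boards block some mics ahead
        levels, occ, _ = synthesize_received_levels(pos, 10.0, layout_refl, config)
        assert occ.any()
        np.testing.assert_allclose(levels[occ], config.noise_floor_db)
        fit = localize_pulse(levels, pos, layout_refl, occluded_mask=occ,
                             noise_floor_db=config.noise_floor_db)
        assert fit.n_channels_used <= (~occ).sum()
        assert abs_diff_deg(pulse_direction(fit), 10.0) < 3.0
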