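"""Generator properties: determinism, strobe timing, calibrated rates,
speed-count coupling, gaze policies and beam-level synthesis."""

import numpy as np
import pandas as pd
import pytest

from echogaze.gaze import gaze_records, in_wall_rate
from echogaze.kinematics import max_flight_speed, meandering_width, speed_profile
from echogaze.simulate import (BatProfile, GazePolicy, SimulationConfig,
                               StrobeMix, assign_pulse_directions,
                               generate_pulse_schedule, generate_trajectory,
                               simulate_cohort, simulate_flight,
                               synthesize_received_levels, make_bat_profiles)


@pytest.fixture(scope="module")
def base_track():
    config = SimulationConfig(condition="permeable")
    prof = BatProfile("b0", 0.0, 0.0, 0)
    rng = np.random.default_rng(0)
    t, pos, _, _ = generate_trajectory(prof, config, rng, v_max=2.8, delta_d=0.5)
    return config, prof, t, pos


class TestDeterminism:
    def test_same_seed_identical_cohort(self):
        config = SimulationConfig(condition="reflective", n_bats=2)
        a = simulate_cohort(config, np.random.default_rng(7))
        b = simulate_cohort(config, np.random.default_rng(7))
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.positions, fb.positions)
            pd.testing.assert_frame_equal(fa.pulses, fb.pulses)


class TestTrajectories:
    def test_constant_speed_config(self):
        config = SimulationConfig(condition="permeable", constant_speed=3.0)
        prof = BatProfile("b", 0.0, 0.0, 0)
        t, pos, _, _ = generate_trajectory(prof, config,
                                           np.random.default_rng(1),
                                           v_max=3.0, delta_d=0.4)
        prof_speed = speed_profile(t, pos, smoothing_window=1)
        np.testing.assert_allclose(prof_speed.speeds[2:-2], 3.0, rtol=0.02)

    def test_max_speed_measured_matches_drawn(self, base_track):
        config, prof, t, pos = base_track
        layout = config.layout()
        v = max_flight_speed(speed_profile(t, pos), pos, layout)
        assert v == pytest.approx(2.8, rel=0.02)

    def test_track_stays_inside_chamber(self, base_track):
        config, _, _, pos = base_track
        layout = config.layout()
        assert pos[:, 0].min() >= 0 and pos[:, 0].max() <= layout.length_m
        assert pos[:, 1].min() >= 0 and pos[:, 1].max() <= layout.width_m

    def test_speed_meander_negatively_coupled_permeable(self):
        """Faster flights meander less (200 simulated flights)."""
        config = SimulationConfig(condition="permeable")
        prof = BatProfile("b", 0.0, 0.0, 0)
        rng = np.random.default_rng(5)
        vs, ds = [], []
        for _ in range(200):
            t, pos, v, _ = generate_trajectory(prof, config, rng,
                                               flight_number=int(rng.integers(1, 13)))
            vs.append(v)
            ds.append(meandering_width(t, pos))
        assert np.corrcoef(vs, ds)[0, 1] < 0

    def test_infeasible_gap_rejected(self):
        # aisle narrower than wall span + clearance
        cfg = SimulationConfig(condition="permeable",
                               arena_overrides={"aisle_y": (1.25, 1.9)})
        with pytest.raises(ValueError, match="gap|clearance"):
            generate_trajectory(BatProfile("b", 0, 0, 0), cfg,
                                np.random.default_rng(0))


class TestPulseSchedules:
    def test_ipi_rule_by_construction(self, base_track):
        config, prof, t, pos = base_track
        rng = np.random.default_rng(2)
        for _ in range(10):
            sched = generate_pulse_schedule(t, pos, prof, config, rng, 1)
            ipis = np.diff(sched["time_s"]) * 1000
            gid = sched["group_id"].to_numpy()
            within = ipis[gid[1:] == gid[:-1]]
            between = ipis[gid[1:] != gid[:-1]]
            assert (within < 40.0).all()
            assert (between >= 40.0).all()

    def test_total_count_calibration(self, base_track):
        """1000 schedules under the 1st-flight permeable cell: mean total
        within 2% of the configured 52-pulse mean."""
        config, prof, t, pos = base_track
        rng = np.random.default_rng(9)
        totals = [len(generate_pulse_schedule(t, pos, prof, config, rng, 1))
                  for _ in range(1000)]
        assert np.mean(totals) == pytest.approx(52.0, rel=0.02)

    def test_poisson_dispersion(self, base_track):
        config, prof, t, pos = base_track
        rng = np.random.default_rng(10)
        totals = np.array([len(generate_pulse_schedule(t, pos, prof, config, rng, 12))
                           for _ in range(600)])
        iod = totals.var() / totals.mean()
        assert 0.8 < iod < 1.25

    def test_no_multiples_when_share_zero(self, base_track):
        config, prof, t, pos = base_track
        config = SimulationConfig(
            condition="permeable",
            strobe=StrobeMix(multiple_means={("permeable", 1): 1e-9,
                                             ("permeable", 12): 1e-9}))
        rng = np.random.default_rng(3)
        from echogaze.kinematics import group_strobes
        for _ in range(5):
            sched = generate_pulse_schedule(t, pos, prof, config, rng, 1)
            groups = group_strobes(np.diff(sched["time_s"]) * 1000)
            assert all(g.size <= 2 for g in groups)

    def test_zero_rate_gives_empty_schedule(self, base_track):
        _, prof, t, pos = base_track
        config = SimulationConfig(condition="permeable")
        config.emission.cell_means = {("permeable", 1): 1e-9,
                                      ("permeable", 12): 1e-9}
        sched = generate_pulse_schedule(t, pos, prof, config,
                                        np.random.default_rng(0), 1)
        assert len(sched) == 0

    def test_speed_count_coupling_negative(self):
        """Cautious bats: slower flyers emit more pulses across a cohort."""
        config = SimulationConfig(condition="permeable", n_bats=40,
                                  flight_numbers=(1,))
        rng = np.random.default_rng(6)
        flights = simulate_cohort(config, rng)
        v = [f.max_speed_drawn for f in flights]
        n = [len(f.pulses) for f in flights]
        assert np.corrcoef(v, n)[0, 1] < 0


class TestGazeAssignment:
    def test_zero_scan_zero_noise_tracks_flight_direction(self, base_track):
        _, prof, t, pos = base_track
        config = SimulationConfig(
            condition="permeable",
            gaze=GazePolicy(scan_amplitude_deg={1: 0.0, 12: 0.0},
                            in_wall_probs={("permeable", 1): 0.0,
                                           ("permeable", 12): 0.0},
                            noise_sd_deg=0.0))
        rng = np.random.default_rng(4)
        sched = generate_pulse_schedule(t, pos, prof, config, rng, 1)
        out = assign_pulse_directions(t, pos, sched, config, rng, 1)
        np.testing.assert_allclose(out["true_direction_deg"],
                                   out["flight_direction_deg"], atol=1e-9)

    def test_zero_in_wall_probability_zero_rate(self, base_track):
        _, prof, t, pos = base_track
        config = SimulationConfig(
            condition="permeable",
            gaze=GazePolicy(scan_amplitude_deg={1: 0.0, 12: 0.0},
                            in_wall_probs={("permeable", 1): 0.0,
                                           ("permeable", 12): 0.0},
                            noise_sd_deg=0.0))
        rng = np.random.default_rng(4)
        layout = config.layout()
        sched = generate_pulse_schedule(t, pos, prof, config, rng, 1)
        out = assign_pulse_directions(t, pos, sched, config, rng, 1)
        out = out.rename(columns={"true_direction_deg": "direction_deg"})
        recs = gaze_records(out, layout)
        assert in_wall_rate(recs)[0] == 0

    def test_in_wall_ordering_permeable_vs_reflective(self):
        """12th-flight in-wall rates keep the configured ~3:1 ordering."""
        rates = {}
        for cond in ("permeable", "reflective"):
            config = SimulationConfig(condition=cond, n_bats=25,
                                      flight_numbers=(12,))
            rng = np.random.default_rng(11)
            layout = config.layout()
            frames = []
            for f in simulate_cohort(config, rng):
                p = f.pulses.rename(columns={"true_direction_deg": "direction_deg"})
                frames.append(gaze_records(p, layout))
            recs = pd.concat(frames, ignore_index=True)
            rates[cond] = in_wall_rate(recs)[0]
        assert rates["permeable"] > 2 * rates["reflective"]


class TestLevelSynthesis:
    def test_symmetric_mics_equal_levels(self, layout_perm):
        config = SimulationConfig(condition="permeable", noise_sd_db=0.0)
        pos = (6.0, 2.25)  # on the frontal-wall symmetry axis
        levels, _, _ = synthesize_received_levels(pos, 0.0, layout_perm, config)
        mics = layout_perm.mic_positions
        pairs = [(i, j) for i in range(6) for j in range(6)
                 if i < j and np.isclose(mics[i][1] + mics[j][1], 4.5)]
        assert pairs
        for i, j in pairs:
            assert levels[i] == pytest.approx(levels[j], abs=1e-9)

    def test_coincident_mic_flagged_invalid(self):
        from echogaze import default_layout
        layout = default_layout("permeable", extra_mic_positions=[(5.0, 2.0)])
        config = SimulationConfig(condition="permeable", noise_sd_db=0.0)
        levels, _, invalid = synthesize_received_levels((5.0, 2.0), 0.0,
                                                        layout, config)
        assert invalid[-1]
        assert np.isnan(levels[-1])

    def test_cohort_emission_counts_match_cells(self):
        """Cohort-level sanity: means land near the calibrated cells."""
        config = SimulationConfig(condition="reflective")
        rng = np.random.default_rng(21)
        profiles = make_bat_profiles(config, rng)
        tot1 = [len(simulate_flight(p, config, rng, 1).pulses) for p in profiles]
        tot12 = [len(simulate_flight(p, config, rng, 12).pulses) for p in profiles]
        assert np.mean(tot1) == pytest.approx(51.9, rel=0.25)
        assert np.mean(tot12) == pytest.approx(37.0, rel=0.25)
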