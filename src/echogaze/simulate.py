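"""Synthetic flights, pulse schedules, gaze sequences and array levels.

The generator emulates the study conditions: S-shaped flights through a
three-wall slalom in a 9 x 4.5 x 2.5 m chamber sampled at 125 Hz; pulse
schedules composed of strobe groups (within-group IPI strictly below
40 ms, between-group gaps above); per-flight emission counts, strobe
composition and maximum flight speeds whose cell means are calibrated
to the study's reported estimated marginal means for the 1st and 12th
flight in each acoustic condition; gaze policies with wide side-to-side
scanning early and forward-directed sonar late, plus condition- and
flight-dependent in-wall gazing; and 20-channel received levels under a
Gaussian directional beam with spherical spreading, 2.4 dB/m absorption
and per-channel sensitivity offsets.  Every draw goes through one
`numpy.random.Generator`, so a fixed seed reproduces a cohort bit for
bit.

The calibrated defaults are the study conditions, not free dials:
parameter-recovery acceptance checks run the analysis pipeline against
these generator settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from ._angles import bearing_deg, wrap_deg
from .arena import ArenaLayout, PERMEABLE, REFLECTIVE, default_layout

FRAME_RATE_HZ = 125.0

# Cell means the generator is calibrated to (per condition, flight 1/12):
# total pulses per flight, pulses in multiple (>=3) groups, and maximum
# flight speed.  Intermediate flights interpolate log-linearly.
TOTAL_PULSE_MEANS = {(PERMEABLE, 1): 52.0, (PERMEABLE, 12): 29.0,
                     (REFLECTIVE, 1): 51.9, (REFLECTIVE, 12): 37.0}
MULTIPLE_PULSE_MEANS = {(PERMEABLE, 1): 28.8, (PERMEABLE, 12): 8.2,
                        (REFLECTIVE, 1): 38.9, (REFLECTIVE, 12): 18.5}
MAX_SPEED_MEANS = {(PERMEABLE, 1): 2.5, (PERMEABLE, 12): 3.4,
                   (REFLECTIVE, 1): 2.6, (REFLECTIVE, 12): 2.8}
# Relative weights of multiple-pulse emissions across the three course
# sections (section 2 weights chosen so the three sum to the flight total).
SECTION_MULTIPLE_WEIGHTS = {(PERMEABLE, 1): (13.2, 9.3, 6.3),
                            (PERMEABLE, 12): (4.8, 1.9, 1.5),
                            (REFLECTIVE, 1): (13.5, 13.5, 11.9),
                            (REFLECTIVE, 12): (5.5, 9.0, 4.0)}
# Raw in-wall gaze-point rates as reported per condition and flight.
IN_WALL_PROBS = {(PERMEABLE, 1): 0.07, (PERMEABLE, 12): 0.23,
                 (REFLECTIVE, 1): 0.25, (REFLECTIVE, 12): 0.08}


def _interp_cell(table: dict, condition: str, flight: int, log: bool = True) -> float:
    """Cell value with log-linear interpolation over flights 2..11."""
    lo, hi = table[(condition, 1)], table[(condition, 12)]
    f = min(max(flight, 1), 12)
    w = (f - 1) / 11.0
    if log:
        return float(np.exp((1 - w) * np.log(lo) + w * np.log(hi)))
    return float((1 - w) * lo + w * hi)


@dataclass
class EmissionModel:
    """Log-link model of per-flight total pulse counts."""
    cell_means: dict = field(default_factory=lambda: dict(TOTAL_PULSE_MEANS))
    bat_sd: float = 0.12          # SD of the bat random intercept (log scale)
    speed_coupling: float = 0.25  # log-count decrease per m/s of bat speed intercept
    section_time_shares: tuple = (0.42, 0.23, 0.35)


@dataclass
class SpeedModel:
    """Per-flight maximum flight speed (m/s)."""
    cell_means: dict = field(default_factory=lambda: dict(MAX_SPEED_MEANS))
    bat_sd: float = 0.35
    resid_sd: float = 0.30
    min_speed: float = 1.3


@dataclass
class StrobeMix:
    """Pulse-share composition of strobe-group types per cell."""
    multiple_means: dict = field(default_factory=lambda: dict(MULTIPLE_PULSE_MEANS))
    total_means: dict = field(default_factory=lambda: dict(TOTAL_PULSE_MEANS))
    section_weights: dict = field(default_factory=lambda: dict(SECTION_MULTIPLE_WEIGHTS))
    single_share: float = 0.035
    multiple_size_probs: dict = field(default_factory=lambda: {3: 0.6, 4: 0.4})

    def shares(self, condition: str, flight: int) -> tuple[float, float, float]:
        """(single, doublet, multiple) pulse shares for a cell."""
        sm = (_interp_cell(self.multiple_means, condition, flight)
              / _interp_cell(self.total_means, condition, flight))
        sm = min(sm, 1.0 - self.single_share - 0.01)
        return (self.single_share, 1.0 - self.single_share - sm, sm)

    def section_weights_for(self, condition: str, flight: int) -> np.ndarray:
        """Normalised per-section weights of multiple-pulse emissions."""
        key = (condition, 1 if flight <= 6 else 12)
        w = np.asarray(self.section_weights[key], dtype=float)
        return w / w.sum()


@dataclass
class GazePolicy:
    """Scan amplitude and in-wall gaze probability per cell."""
    scan_amplitude_deg: dict = field(default_factory=lambda: {1: 30.0, 12: 8.0})
    in_wall_probs: dict = field(default_factory=lambda: dict(IN_WALL_PROBS))
    noise_sd_deg: float = 3.0

    def amplitude(self, flight: int) -> float:
        w = (min(max(flight, 1), 12) - 1) / 11.0
        return (1 - w) * self.scan_amplitude_deg[1] + w * self.scan_amplitude_deg[12]

    def in_wall_prob(self, condition: str, flight: int) -> float:
        return _interp_cell(self.in_wall_probs, condition, flight, log=False)


@dataclass
class BeamModel:
    """Gaussian directional beam in the dB domain."""
    source_level_db: float = 120.0
    half_width_deg: float = 25.0       # Gaussian sigma of the beam, degrees
    attenuation_depth_db: float = 40.0  # off-axis attenuation asymptote

    def attenuation_db(self, off_axis_deg):
        d = np.asarray(off_axis_deg, dtype=float)
        return self.attenuation_depth_db * (1.0 - np.exp(-d ** 2 / (2 * self.half_width_deg ** 2)))


@dataclass
class PulseShape:
    """CF-FM pulse: initial up sweep, CF2 tone, terminal down sweep."""
    fs_hz: float = 500_000.0
    cf2_hz: float = 69_000.0
    cf_duration_s: float = 0.010
    ifm_start_hz: float = 55_000.0
    ifm_duration_s: float = 0.0015
    tfm_end_hz: float = 50_000.0
    tfm_duration_s: float = 0.0025
    edge_s: float = 0.0003


@dataclass
class SimulationConfig:
    condition: str = PERMEABLE
    n_bats: int = 7
    flight_numbers: tuple = (1, 12)
    emission: EmissionModel = field(default_factory=EmissionModel)
    speed: SpeedModel = field(default_factory=SpeedModel)
    strobe: StrobeMix = field(default_factory=StrobeMix)
    gaze: GazePolicy = field(default_factory=GazePolicy)
    beam: BeamModel = field(default_factory=BeamModel)
    pulse_shape: PulseShape = field(default_factory=PulseShape)
    noise_sd_db: float = 0.5
    noise_floor_db: float = 0.0
    absorption_db_per_m: float = 2.4  # at 65 kHz
    sensitivity_offset_sd_db: float = 0.0
    within_ipi_range_ms: tuple = (25.0, 39.0)
    between_gap_median_ms: float = 80.0
    between_gap_sigma: float = 0.4
    min_between_gap_ms: float = 42.0
    meander_speed_slope: float = -0.2308  # m of delta-d per m/s (permeable)
    meander_noise_sd: float = 0.08
    constant_speed: float | None = None
    z_height_m: float = 1.3
    arena_overrides: dict = field(default_factory=dict)

    def layout(self) -> ArenaLayout:
        return default_layout(self.condition, **self.arena_overrides)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BatProfile:
    """Per-bat random effects, drawn once and fixed across flights.

    ``cautiousness`` couples a slow flight style to a high emission
    rate: the emission intercept contains -speed_coupling times the
    speed intercept plus an independent part.
    """
    bat_id: str
    speed_intercept: float
    emission_intercept: float
    scan_phase: int  # initial side of the side-to-side scan (0 or 1)


@dataclass
class FlightRecord:
    bat_id: str
    condition: str
    flight_number: int
    times: np.ndarray
    positions: np.ndarray  # (n, 3)
    pulses: pd.DataFrame
    max_speed_drawn: float
    meander_drawn: float


def make_bat_profiles(config: SimulationConfig, rng) -> list[BatProfile]:
    em = config.emission
    ind_sd = np.sqrt(max(em.bat_sd ** 2 -
                         (em.speed_coupling * config.speed.bat_sd) ** 2, 1e-8))
    profiles = []
    for i in range(config.n_bats):
        sp = rng.normal(0.0, config.speed.bat_sd)
        emi = -em.speed_coupling * sp + rng.normal(0.0, ind_sd)
        profiles.append(BatProfile(
            bat_id=f"{config.condition[:4]}_bat{i + 1:02d}",
            speed_intercept=sp, emission_intercept=emi,
            scan_phase=int(rng.integers(2))))
    return profiles


# ---------------------------------------------------------------------------
# trajectories


def draw_max_speed(profile: BatProfile, config: SimulationConfig,
                   flight_number: int, rng) -> float:
    mean = _interp_cell(config.speed.cell_means, config.condition, flight_number,
                        log=False)
    v = mean + profile.speed_intercept + rng.normal(0.0, config.speed.resid_sd)
    return max(v, config.speed.min_speed)


def draw_meander(config: SimulationConfig, flight_number: int, v_max: float,
                 rng) -> float:
    """Meandering width delta-d (m); speed-coupled in the permeable condition."""
    if config.condition == PERMEABLE:
        base = 0.8 + config.meander_speed_slope * (v_max - 1.4)
    else:
        w = (min(max(flight_number, 1), 12) - 1) / 11.0
        base = 0.78 - 0.20 * w
    return float(np.clip(base + rng.normal(0.0, config.meander_noise_sd), 0.15, 1.0))


def generate_trajectory(profile: BatProfile, config: SimulationConfig, rng,
                        flight_number: int = 1,
                        v_max: float | None = None,
                        delta_d: float | None = None):
    """Smooth S-curve through the three wall gaps, sampled at 125 Hz.

    Returns ``(times, positions, v_max, delta_d)``.  The lateral path is
    a cubic spline through gap waypoints whose offsets realise the
    requested meandering width; the along-path speed ramps up to
    ``v_max`` just before wall 3 and relaxes towards landing on the
    frontal wall.
    """
    layout = config.layout()
    aisle_lo, aisle_hi = layout.aisle_y
    centre = 0.5 * (aisle_lo + aisle_hi)
    gap_clear = min(w.inner_edge_y - aisle_lo if w.side == "high"
                    else aisle_hi - w.inner_edge_y
                    for w in layout.obstacle_walls)
    if gap_clear < 0.5:
        raise ValueError("wall gap narrower than flight clearance")
    if v_max is None:
        v_max = draw_max_speed(profile, config, flight_number, rng)
    if delta_d is None:
        delta_d = draw_meander(config, flight_number, v_max, rng)

    x0, y0 = layout.start_position
    w1, w2, w3 = (w.x_m for w in layout.obstacle_walls)
    x_end = layout.length_m - 0.1
    amp = delta_d / 2.0
    jit = rng.normal(0.0, 0.02, size=3)
    xs = np.array([x0, 0.5 * (x0 + w1), w1, w2, w3, 0.5 * (w3 + x_end), x_end])
    ys = np.array([y0, y0 - 0.35 * amp, y0 - amp + jit[0], y0 + amp + jit[1],
                   y0 - 0.8 * amp + jit[2], y0, y0])
    path = CubicSpline(xs, np.clip(ys, aisle_lo + 0.2, aisle_hi - 0.2),
                       bc_type="clamped")

    grid = np.linspace(x0, x_end, 2500)
    yg = path(grid)
    ds = np.hypot(np.diff(grid), np.diff(yg))
    s = np.concatenate([[0.0], np.cumsum(ds)])

    if config.constant_speed is not None:
        v = np.full_like(grid, float(config.constant_speed))
    else:
        x_pk, v_launch, v_land = w3 - 0.2, 0.8, 1.0
        ramp = np.clip((grid - x0) / (x_pk - x0), 0.0, 1.0)
        v_up = v_launch + (v_max - v_launch) * np.sin(ramp * np.pi / 2.0)
        fall = np.clip((grid - x_pk) / (x_end - x_pk), 0.0, 1.0)
        v_down = v_land + (v_max - v_land) * np.cos(fall * np.pi / 2.0)
        v = np.where(grid <= x_pk, v_up, v_down)
    seg_v = 0.5 * (v[1:] + v[:-1])
    t = np.concatenate([[0.0], np.cumsum(ds / seg_v)])

    times = np.arange(0.0, t[-1], 1.0 / FRAME_RATE_HZ)
    xt = np.interp(times, t, grid)
    yt = path(xt)
    positions = np.column_stack([xt, yt, np.full_like(xt, config.z_height_m)])
    return times, positions, float(v_max), float(delta_d)


# ---------------------------------------------------------------------------
# pulse schedules


def _section_windows(times, positions, layout):
    x = positions[:, 0]
    bounds = [layout.wall_x[0], layout.wall_x[1]]
    cuts = []
    for b in bounds:
        idx = np.nonzero(x >= b)[0]
        cuts.append(times[idx[0]] if idx.size else times[-1])
    return [(times[0], cuts[0]), (cuts[0], cuts[1]), (cuts[1], times[-1])]


def _partition_multiples(n_pulses: int, size_probs, rng) -> list[int]:
    """Partition ``n_pulses`` (>= 3) into group sizes drawn from
    ``size_probs`` without leaving an unusable remainder of 1-2."""
    ks = np.array(sorted(size_probs))
    ps = np.array([size_probs[k] for k in ks], dtype=float)
    ps /= ps.sum()
    sizes, rem = [], int(n_pulses)
    while rem >= 3:
        k = int(rng.choice(ks, p=ps))
        if rem - k in (1, 2):
            k = rem if rem <= int(ks.max()) + 2 else 3
        sizes.append(min(k, rem))
        rem -= sizes[-1]
    if rem:
        sizes[-1] += rem
    return sizes


def _flight_group_plan(n_total: int, shares, section_weights, time_shares,
                       size_probs, rng):
    """Group sizes per section for exactly ``n_total`` pulses.

    Multiple-group pulses are drawn at flight level (binomial with the
    cell's multiple share) and allocated to sections as whole groups by
    the configured section weights, so no multiples are lost to
    too-small section cells; singles and doublets fill the remaining
    per-section budgets.
    """
    if n_total <= 0:
        return [[] for _ in time_shares]
    s1, sd, sm = shares
    nm = int(rng.binomial(n_total, sm))
    if nm in (1, 2):  # cannot form a >=3 group; demote to doublet/single
        nm = 0
    rest = n_total - nm
    n1 = int(rng.binomial(rest, s1 / max(s1 + sd, 1e-12))) if rest else 0
    nd = rest - n1
    if nd % 2:
        nd -= 1
        n1 += 1
    mult_groups = _partition_multiples(nm, size_probs, rng) if nm else []
    w = np.asarray(section_weights, dtype=float)
    sec_of_mult = rng.choice(len(w), size=len(mult_groups), p=w / w.sum())
    plan = [[] for _ in time_shares]
    mult_pulses_sec = np.zeros(len(w))
    for g, sec in zip(mult_groups, sec_of_mult):
        plan[sec].append(int(g))
        mult_pulses_sec[sec] += g
    q = np.asarray(time_shares, dtype=float)
    budget = np.maximum(q / q.sum() * n_total - mult_pulses_sec, 0.0)
    p_rest = budget / budget.sum() if budget.sum() > 0 else q / q.sum()
    for sec in rng.choice(len(w), size=nd // 2, p=p_rest):
        plan[sec].append(2)
    for sec in rng.choice(len(w), size=n1, p=p_rest):
        plan[sec].append(1)
    for sec_plan in plan:
        rng.shuffle(sec_plan)
    return plan


def generate_pulse_schedule(times, positions, profile: BatProfile,
                            config: SimulationConfig, rng,
                            flight_number: int = 1) -> pd.DataFrame:
    """Strobe-group renewal schedule over one flight.

    The flight total is Poisson with a log-linear cell mean (condition,
    flight number) plus the bat's emission intercept; pulses are split
    over sections by the configured time shares, composed into groups
    with the section's strobe mix, and placed so that within-group IPIs
    stay strictly below 40 ms and between-group gaps strictly above.
    """
    layout = config.layout()
    em = config.emission
    log_mu = (np.log(_interp_cell(em.cell_means, config.condition, flight_number))
              + profile.emission_intercept)
    n_total = int(rng.poisson(np.exp(log_mu)))
    windows = _section_windows(times, positions, layout)
    q = np.asarray(em.section_time_shares, dtype=float)
    q = q / q.sum()
    shares = config.strobe.shares(config.condition, flight_number)
    w = config.strobe.section_weights_for(config.condition, flight_number)
    plan = _flight_group_plan(n_total, shares, w, q,
                              config.strobe.multiple_size_probs, rng)

    lo_ipi, hi_ipi = (v / 1000.0 for v in config.within_ipi_range_ms)
    min_gap = config.min_between_gap_ms / 1000.0
    mu_gap = np.log(config.between_gap_median_ms / 1000.0)

    rows = []
    prev_last = -np.inf
    pid = 0
    for sec, ((a, b), sizes) in enumerate(zip(windows, plan), start=1):
        if not sizes:
            continue
        ipis = [rng.uniform(lo_ipi, hi_ipi, size=k - 1) for k in sizes]
        spans = np.array([ip.sum() for ip in ipis])
        gaps = rng.lognormal(mu_gap, config.between_gap_sigma, size=len(sizes))
        slack = (b - a) - spans.sum()
        if slack > 0 and gaps.sum() > 0:
            gaps *= slack / gaps.sum()
        gaps = np.maximum(gaps, min_gap)
        cursor = a
        for g, (k, ip, gap) in enumerate(zip(sizes, ipis, gaps)):
            start = max(cursor + gap, prev_last + min_gap)
            tpulse = start + np.concatenate([[0.0], np.cumsum(ip)])
            for tau in tpulse:
                rows.append((pid, float(tau), sec, k))
                pid += 1
            prev_last = tpulse[-1]
            cursor = prev_last
    if not rows:
        return pd.DataFrame(columns=["pulse_id", "time_s", "section_planned",
                                     "group_id", "group_size"])
    df = pd.DataFrame(rows, columns=["pulse_id", "time_s", "section_planned",
                                     "group_size"])
    # group ids from the realised gap structure
    gid = np.concatenate([[0], np.cumsum(np.diff(df["time_s"]) >= 0.040)])
    df["group_id"] = gid
    return df[["pulse_id", "time_s", "section_planned", "group_id", "group_size"]]


# ---------------------------------------------------------------------------
# gaze and beam


def track_state_at(times, positions, t_query):
    """Interpolated position and flight direction (deg) at given times."""
    t_query = np.atleast_1d(np.asarray(t_query, dtype=float))
    vel = np.gradient(positions, times, axis=0)
    pos = np.column_stack([np.interp(t_query, times, positions[:, k]) for k in range(3)])
    vx = np.interp(t_query, times, vel[:, 0])
    vy = np.interp(t_query, times, vel[:, 1])
    return pos, bearing_deg(vx, vy)


def assign_pulse_directions(times, positions, pulses: pd.DataFrame,
                            config: SimulationConfig, rng,
                            flight_number: int = 1) -> pd.DataFrame:
    """True beam directions: side-to-side scan alternating per strobe
    group, collapsing towards the flight direction in late flights, with
    occasional rays aimed inside the immediate wall."""
    layout = config.layout()
    out = pulses.copy()
    if out.empty:
        for c in ("x", "y", "z", "flight_direction_deg", "true_direction_deg", "section"):
            out[c] = []
        return out
    pos, fdir = track_state_at(times, positions, out["time_s"].to_numpy())
    amp = config.gaze.amplitude(flight_number)
    p_iw = config.gaze.in_wall_prob(config.condition, flight_number)
    noise = rng.normal(0.0, config.gaze.noise_sd_deg, size=len(out))
    phase = int(rng.integers(2))
    signs = np.where((out["group_id"].to_numpy() + phase) % 2 == 0, 1.0, -1.0)
    true_dir = wrap_deg(fdir + signs * amp + noise)
    sections = np.empty(len(out), dtype=int)
    for i in range(len(out)):
        xy = pos[i, :2]
        sections[i] = layout.section_of(xy)
        if p_iw > 0 and rng.random() < p_iw:
            wall = layout.immediate_wall(xy)
            if wall is not None:
                target_y = rng.uniform(wall.y_lo, wall.y_hi)
                true_dir[i] = bearing_deg(wall.x_m - xy[0], target_y - xy[1])
    out["x"], out["y"], out["z"] = pos[:, 0], pos[:, 1], pos[:, 2]
    out["flight_direction_deg"] = fdir
    out["true_direction_deg"] = true_dir
    out["section"] = sections
    return out


def _occluded_channels(position, layout: ArenaLayout) -> np.ndarray:
    """Channels whose line of sight crosses a reflective board."""
    p = np.asarray(position, dtype=float).ravel()[:2]
    occ = np.zeros(len(layout.mic_positions), dtype=bool)
    if layout.condition != REFLECTIVE:
        return occ
    for i, m in enumerate(layout.mic_positions):
        for wall in layout.obstacle_walls:
            dx = m[0] - p[0]
            if abs(dx) < 1e-12:
                continue
            t = (wall.x_m - p[0]) / dx
            if 0.0 < t < 1.0:
                y_at = p[1] + t * (m[1] - p[1])
                if wall.y_lo <= y_at <= wall.y_hi:
                    occ[i] = True
                    break
    return occ


def synthesize_received_levels(position, true_direction_deg,
                               layout: ArenaLayout,
                               config: SimulationConfig, rng=None,
                               sensitivity_offsets=None,
                               noise_sd_db: float | None = None):
    """Received level (dB) on every array channel for one emission.

    level = SL - beam_attenuation(delta) - 20 log10 r - 2.4 r + offset + noise,
    with reflective boards hard-occluding channels to the noise floor.
    Returns ``(levels, occluded_mask, invalid_mask)``.
    """
    p = np.asarray(position, dtype=float).ravel()[:2]
    r = layout.mic_distances(p)
    invalid = r < 1e-9
    bearings = (_safe_bearings(layout, p, invalid) if invalid.any()
                else layout.mic_bearings(p))
    beam = config.beam
    delta = np.abs(wrap_deg(bearings - true_direction_deg))
    with np.errstate(divide="ignore"):
        levels = (beam.source_level_db - beam.attenuation_db(delta)
                  - 20.0 * np.log10(np.where(invalid, 1.0, r))
                  - config.absorption_db_per_m * r)
    if sensitivity_offsets is not None:
        levels = levels + np.asarray(sensitivity_offsets, dtype=float)
    sd = config.noise_sd_db if noise_sd_db is None else noise_sd_db
    if sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd_db > 0")
        levels = levels + rng.normal(0.0, sd, size=len(levels))
    occluded = _occluded_channels(p, layout)
    levels = np.where(occluded, config.noise_floor_db, levels)
    levels = np.where(invalid, np.nan, levels)
    return levels, occluded, invalid


def _safe_bearings(layout, p, invalid):
    out = np.zeros(len(layout.mic_positions))
    for i, m in enumerate(layout.mic_positions):
        if not invalid[i]:
            out[i] = bearing_deg(m[0] - p[0], m[1] - p[1])
    return out


# ---------------------------------------------------------------------------
# waveform rendering


def pulse_waveform(shape: PulseShape):
    """One CF-FM pulse at unit amplitude.

    Returns ``(waveform, tfm_onset_index)`` where the index marks the
    start of the terminal FM sweep (the emission-time reference used by
    the feature extraction).
    """
    fs = shape.fs_hz
    n_ifm = int(round(shape.ifm_duration_s * fs))
    n_cf = int(round(shape.cf_duration_s * fs))
    n_tfm = int(round(shape.tfm_duration_s * fs))
    f = np.concatenate([
        np.linspace(shape.ifm_start_hz, shape.cf2_hz, n_ifm, endpoint=False),
        np.full(n_cf, shape.cf2_hz),
        np.linspace(shape.cf2_hz, shape.tfm_end_hz, n_tfm),
    ])
    phase = 2.0 * np.pi * np.cumsum(f) / fs
    wave = np.sin(phase)
    n_edge = int(round(shape.edge_s * fs))
    if n_edge:
        ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, n_edge)))
        wave[:n_edge] *= ramp
        wave[-n_edge:] *= ramp[::-1]
    return wave, n_ifm + n_cf


def render_waveform(tfm_onsets_s, levels_db, shape: PulseShape | None = None,
                    duration_s: float | None = None,
                    noise_rms: float = 0.0, rng=None,
                    ref_db: float = 120.0) -> np.ndarray:
    """Mono audio with one CF-FM pulse per onset (fs from the shape).

    ``tfm_onsets_s`` are terminal-FM onset times; the waveform of each
    pulse starts one initial-sweep-plus-CF duration earlier.
    Overlapping pulses are summed.  Levels are dB re ``ref_db`` -> 1.0.
    """
    shape = shape or PulseShape()
    fs = shape.fs_hz
    wave, i_tfm = pulse_waveform(shape)
    onsets = np.atleast_1d(np.asarray(tfm_onsets_s, dtype=float))
    levels = np.broadcast_to(np.asarray(levels_db, dtype=float), onsets.shape)
    if duration_s is None:
        duration_s = (onsets.max() if onsets.size else 0.0) + shape.tfm_duration_s + 0.02
    n = int(round(duration_s * fs))
    audio = np.zeros(n)
    for t0, db in zip(onsets, levels):
        start = int(round(t0 * fs)) - i_tfm
        seg = wave * 10.0 ** ((db - ref_db) / 20.0)
        lo, hi = max(start, 0), min(start + len(seg), n)
        if hi > lo:
            audio[lo:hi] += seg[lo - start: hi - start]
    if noise_rms > 0:
        if rng is None:
            raise ValueError("rng required for noise")
        audio = audio + rng.normal(0.0, noise_rms, size=n)
    return audio


def render_array_waveforms(tfm_onsets_s, arrival_delays_s, levels_db,
                           shape: PulseShape | None = None,
                           duration_s: float | None = None,
                           noise_rms: float = 0.0, rng=None) -> np.ndarray:
    """Per-channel audio: pulses delayed and scaled per channel.

    ``arrival_delays_s`` and ``levels_db`` have shape (n_pulses,
    n_channels); returns (n_channels, n_samples).
    """
    shape = shape or PulseShape()
    delays = np.atleast_2d(np.asarray(arrival_delays_s, dtype=float))
    levels = np.atleast_2d(np.asarray(levels_db, dtype=float))
    onsets = np.atleast_1d(np.asarray(tfm_onsets_s, dtype=float))
    n_ch = delays.shape[1]
    if duration_s is None:
        duration_s = float((onsets[:, None] + delays).max()) + shape.tfm_duration_s + 0.02
    chans = []
    for ch in range(n_ch):
        lv = np.where(np.isfinite(levels[:, ch]), levels[:, ch], -300.0)
        chans.append(render_waveform(onsets + delays[:, ch], lv, shape,
                                     duration_s=duration_s,
                                     noise_rms=noise_rms, rng=rng))
    return np.vstack(chans)


# ---------------------------------------------------------------------------
# cohort assembly


def simulate_flight(profile: BatProfile, config: SimulationConfig, rng,
                    flight_number: int) -> FlightRecord:
    times, positions, v_max, delta_d = generate_trajectory(
        profile, config, rng, flight_number)
    pulses = generate_pulse_schedule(times, positions, profile, config, rng,
                                     flight_number)
    pulses = assign_pulse_directions(times, positions, pulses, config, rng,
                                     flight_number)
    from .kinematics import pulse_table_with_groups
    if len(pulses):
        grp = pulse_table_with_groups(pulses["time_s"].to_numpy(),
                                      pulses["pulse_id"].tolist())
        pulses = pulses.drop(columns=["group_id", "group_size"]).merge(
            grp, on="pulse_id")
    pulses.insert(0, "bat_id", profile.bat_id)
    pulses.insert(1, "condition", config.condition)
    pulses.insert(2, "flight_number", flight_number)
    return FlightRecord(profile.bat_id, config.condition, flight_number,
                        times, positions, pulses, v_max, delta_d)


def simulate_cohort(config: SimulationConfig, rng) -> list[FlightRecord]:
    """All flights of one condition's cohort (n_bats x flight_numbers)."""
    profiles = make_bat_profiles(config, rng)
    return [simulate_flight(p, config, rng, f)
            for p in profiles for f in config.flight_numbers]
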