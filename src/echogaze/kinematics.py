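"""Flight kinematics and strobe-group classification.

Speed is derived from 125-Hz 3D positions by central differences; the
maximum flight speed is restricted to the stretch from flight start to
the first crossing of the third obstacle wall.  The meandering width
(delta-d) is the peak-to-peak lateral amplitude between the first
prominent y-extremum of the S-shaped path and the following extremum of
opposite turning sense.

Strobe groups follow the 40-ms rule: a maximal run of consecutive
pulses whose inter-pulse intervals are all strictly below 40 ms forms
one group; groups of size 1, 2 and >=3 are classed single, doublet and
multiple (triplet or more).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

STROBE_IPI_MS = 40.0

SINGLE = "single"
DOUBLET = "doublet"
MULTIPLE = "multiple"


class IncompleteFlightError(ValueError):
    """Track never crosses the third obstacle wall."""


class UndefinedMeanderError(ValueError):
    """Track has no usable pair of lateral extrema."""


@dataclass
class SpeedProfile:
    times: np.ndarray
    speeds: np.ndarray
    smoothing_window: int


@dataclass(frozen=True)
class StrobeGroup:
    pulse_ids: tuple
    size: int
    group_type: str


def _group_type(size: int) -> str:
    return SINGLE if size == 1 else DOUBLET if size == 2 else MULTIPLE


def speed_profile(times, positions, smoothing_window: int = 5,
                  dt_tolerance: float = 1e-3) -> SpeedProfile:
    """Finite-difference speed magnitudes of a uniformly sampled track.

    Central differences inside the track, one-sided at the endpoints,
    followed by an optional moving-average smoothing (default 5
    samples; pass 1 to disable).
    """
    t = np.asarray(times, dtype=float)
    p = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt.mean()) > dt_tolerance * max(dt.mean(), 1e-9)) or dt.mean() <= 0:
        raise ValueError("non-uniform or non-increasing timestamps")
    vel = np.gradient(p, t, axis=0)
    speeds = np.linalg.norm(vel, axis=1)
    w = int(smoothing_window)
    if w > 1:
        kernel = np.ones(w) / w
        pad = w // 2
        padded = np.pad(speeds, pad, mode="edge")
        speeds = np.convolve(padded, kernel, mode="same")[pad:pad + len(t)]
    return SpeedProfile(times=t, speeds=speeds, smoothing_window=w)


def max_flight_speed(profile: SpeedProfile, positions, layout) -> float:
    """Maximum speed from flight start to the first crossing of wall 3."""
    x = np.atleast_2d(np.asarray(positions, dtype=float))[:, 0]
    wall3_x = layout.obstacle_walls[2].x_m
    crossed = np.nonzero(x >= wall3_x)[0]
    if crossed.size == 0:
        raise IncompleteFlightError("flight never passes the third obstacle wall")
    return float(np.max(profile.speeds[: crossed[0] + 1]))


def meandering_width(times, positions, smoothing_window: int = 5,
                     prominence_m: float = 0.05) -> float:
    """Peak-to-peak lateral amplitude of the first S-turn pair (metres)."""
    y = np.atleast_2d(np.asarray(positions, dtype=float))[:, 1]
    w = int(smoothing_window)
    if w > 1:
        pad = w // 2
        y = np.convolve(np.pad(y, pad, mode="edge"), np.ones(w) / w, mode="same")[pad:pad + len(y)]
    maxima, _ = find_peaks(y, prominence=prominence_m)
    minima, _ = find_peaks(-y, prominence=prominence_m)
    extrema = sorted([(i, +1) for i in maxima] + [(i, -1) for i in minima])
    for k in range(len(extrema) - 1):
        (i, s1), (j, s2) = extrema[k], extrema[k + 1]
        if s1 != s2:
            return float(abs(y[i] - y[j]))
    raise UndefinedMeanderError("no opposite-sense lateral extremum pair found")


def group_strobes(ipis_ms, pulse_ids=None) -> list[StrobeGroup]:
    """Partition a pulse sequence into strobe groups by the 40-ms rule.

    ``ipis_ms`` are the n-1 intervals between n consecutive pulses.  An
    IPI of exactly 40 ms splits groups (strict ``<``).
    """
    ipis = np.asarray(ipis_ms, dtype=float)
    n = len(ipis) + 1
    if pulse_ids is None:
        pulse_ids = list(range(n))
    if len(pulse_ids) != n:
        raise ValueError("pulse_ids must have one more entry than ipis")
    groups, start = [], 0
    for k in range(len(ipis) + 1):
        if k == len(ipis) or not (ipis[k] < STROBE_IPI_MS):
            members = tuple(pulse_ids[start:k + 1])
            groups.append(StrobeGroup(members, len(members), _group_type(len(members))))
            start = k + 1
    return groups


def pulse_table_with_groups(pulse_times_s, pulse_ids=None) -> pd.DataFrame:
    """Per-pulse table of group id / size / type from emission times."""
    t = np.asarray(pulse_times_s, dtype=float)
    ipis = np.diff(t) * 1000.0
    groups = group_strobes(ipis, pulse_ids)
    rows = []
    for gid, g in enumerate(groups):
        for pid in g.pulse_ids:
            rows.append((pid, gid, g.size, g.group_type))
    return pd.DataFrame(rows, columns=["pulse_id", "group_id", "group_size", "group_type"])


def count_by_type(pulses: pd.DataFrame,
                  cohort_keys=("bat_id", "condition", "flight_number"),
                  cohorts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cohort pulse counts by strobe type, plus per-section multiples.

    ``pulses`` needs one row per pulse with ``group_type`` and
    ``section`` columns and the cohort key columns.  Counts are pulse
    counts (a doublet contributes 2); group counts are exported
    alongside.  Identity: total = singles + doublet + multiple pulses.
    Pass ``cohorts`` (a frame of expected key combinations) to get
    all-zero rows for flights without any pulses.
    """
    required = set(cohort_keys) | {"group_type", "section", "group_id"}
    missing = required - set(pulses.columns)
    if missing:
        raise ValueError(f"pulse table missing columns: {sorted(missing)}")
    if pulses[list(required)].isna().any().any():
        raise ValueError("untagged pulses (NaN in required columns)")
    keys = list(cohort_keys)
    out = []
    for cohort, df in pulses.groupby(keys, sort=True):
        row = dict(zip(keys, cohort if isinstance(cohort, tuple) else (cohort,)))
        row["total_pulses"] = len(df)
        for typ in (SINGLE, DOUBLET, MULTIPLE):
            row[f"{typ}_pulses"] = int((df["group_type"] == typ).sum())
            row[f"{typ}_groups"] = df.loc[df["group_type"] == typ, "group_id"].nunique()
        for sec in (1, 2, 3):
            in_sec = df["section"] == sec
            row[f"multiple_pulses_sec{sec}"] = int(
                (in_sec & (df["group_type"] == MULTIPLE)).sum())
            row[f"total_pulses_sec{sec}"] = int(in_sec.sum())
        out.append(row)
    table = pd.DataFrame(out)
    if cohorts is not None:
        keys = list(cohort_keys)
        base = cohorts[keys].drop_duplicates()
        if table.empty:
            table = pd.DataFrame(columns=keys)
        table = base.merge(table, on=keys, how="left")
        count_cols = [c for c in table.columns if c not in keys]
        table[count_cols] = table[count_cols].fillna(0).astype(int)
    return table
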