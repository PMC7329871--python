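"""Acoustic-gaze metrics.

The acoustic gaze angle is the signed minimal angle from the flight
direction to the pulse direction.  The acoustic gaze point is where the
forward ray along the pulse direction crosses the axis line of the
immediate (closest upcoming) obstacle wall; a gaze point whose lateral
coordinate falls inside the wall's span (edges inclusive) is classed
"in wall" -- under the permeable condition such pulses probe the space
behind the chain wall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._angles import abs_diff_deg, signed_diff_deg
from .arena import ArenaLayout, ObstacleWall


class UndefinedRateError(ValueError):
    """No directed pulses available for a rate."""


@dataclass
class GazeRecord:
    pulse_id: int
    gaze_angle_deg: float
    gaze_point: tuple | None
    in_wall: bool
    section: int
    wall_index: int | None


def gaze_angle(pulse_direction_deg, flight_direction_deg):
    """Signed minimal angle (deg) from flight direction to pulse direction."""
    return signed_diff_deg(pulse_direction_deg, flight_direction_deg)


def delta_pulse_direction(directions_deg) -> np.ndarray:
    """Absolute angular change between successive pulse directions.

    ``directions_deg`` may contain NaN for pulses without a usable
    directivity fit; pairs spanning a missing value are skipped.
    """
    d = np.asarray(directions_deg, dtype=float)
    if np.sum(np.isfinite(d)) < 2:
        return np.empty(0)
    out = abs_diff_deg(d[1:], d[:-1])
    return out[np.isfinite(out)]


def gaze_point(position, pulse_direction_deg, wall: ObstacleWall):
    """Forward ray / wall-axis intersection, or ``None``.

    Returns ``None`` when the ray is parallel to the wall axis or
    points away from it.
    """
    p = np.asarray(position, dtype=float).ravel()[:2]
    theta = np.radians(pulse_direction_deg)
    dx, dy = np.cos(theta), np.sin(theta)
    if abs(dx) < 1e-12:
        return None
    t = (wall.x_m - p[0]) / dx
    if t <= 0:
        return None
    return (float(wall.x_m), float(p[1] + t * dy))


def classify_in_wall(point, wall: ObstacleWall) -> bool:
    """True iff the gaze point lies within the wall span, edges inclusive."""
    return wall.y_lo <= point[1] <= wall.y_hi


def gaze_records(pulses: pd.DataFrame, layout: ArenaLayout) -> pd.DataFrame:
    """Per-pulse gaze table from a pulse table with columns
    ``pulse_id, x, y, direction_deg, flight_direction_deg``."""
    rows = []
    for rec in pulses.itertuples(index=False):
        direction = getattr(rec, "direction_deg")
        pos = (rec.x, rec.y)
        section = layout.section_of(pos)
        if not np.isfinite(direction):
            rows.append((rec.pulse_id, np.nan, np.nan, np.nan, False, section, None))
            continue
        ga = gaze_angle(direction, rec.flight_direction_deg)
        wall = layout.immediate_wall(pos)
        gp = gaze_point(pos, direction, wall) if wall is not None else None
        in_wall = bool(gp is not None and classify_in_wall(gp, wall))
        rows.append((rec.pulse_id, ga,
                     gp[0] if gp else np.nan, gp[1] if gp else np.nan,
                     in_wall, section, wall.index if wall else None))
    return pd.DataFrame(rows, columns=[
        "pulse_id", "gaze_angle_deg", "gaze_x", "gaze_y",
        "in_wall", "section", "wall_index"])


def in_wall_rate(records: pd.DataFrame | None = None, *,
                 in_wall_count: int | None = None,
                 total_count: int | None = None):
    """In-wall emission rate as a rounded integer percentage plus counts.

    Either pass a gaze-record table (directed pulses are rows with a
    finite gaze angle) or raw counts.  Returns ``(percent, in_wall,
    total)``; e.g. 46 of 204 -> (23, 46, 204).
    """
    if records is not None:
        directed = records[np.isfinite(records["gaze_angle_deg"])]
        total_count = len(directed)
        in_wall_count = int(directed["in_wall"].sum())
    if not total_count:
        raise UndefinedRateError("no directed pulses")
    return (int(round(100.0 * in_wall_count / total_count)), in_wall_count, total_count)


def section_histograms(records: pd.DataFrame, layout: ArenaLayout,
                       bin_width_m: float = 0.1,
                       aligned_range=(-4.5, 4.5)) -> dict:
    """Wall-aligned gaze-point histograms per section plus their sum.

    Gaze-point y is mapped to the wall-aligned coordinate of the wall
    the pulse was aimed at (0 at the wall's attached edge, increasing
    into the aisle), so the three wall locations line up and the
    per-section histograms can be summed into one integrated histogram.
    """
    edges = np.arange(aligned_range[0], aligned_range[1] + bin_width_m / 2, bin_width_m)
    walls = {w.index: w for w in layout.obstacle_walls}
    hists = {}
    for sec in (1, 2, 3):
        sub = records[(records["section"] == sec) & np.isfinite(records["gaze_y"])]
        if len(sub):
            aligned = np.concatenate([
                np.atleast_1d(walls[int(w)].aligned_y(y))
                for y, w in zip(sub["gaze_y"], sub["wall_index"]) if w is not None
            ]) if len(sub) else np.empty(0)
        else:
            aligned = np.empty(0)
        hists[sec], _ = np.histogram(aligned, bins=edges)
    hists["integrated"] = hists[1] + hists[2] + hists[3]
    hists["bin_edges"] = edges
    return hists
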