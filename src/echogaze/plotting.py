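"""Quick-look figures: flight paths with pulse directions, and EMM plots."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_flight(record, layout, ax=None, ray_length_m: float = 1.0):
    """Aerial view of one flight: path, obstacle walls, pulse-direction rays."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ax.plot(record.positions[:, 0], record.positions[:, 1], "r-", lw=1.2,
            label="flight path")
    for wall in layout.obstacle_walls:
        ax.plot([wall.x_m, wall.x_m], [wall.y_lo, wall.y_hi],
                color="0.4", lw=5, solid_capstyle="butt")
    for y in layout.aisle_y:
        ax.axhline(y, color="0.8", lw=0.8, ls=":")
    p = record.pulses
    col = "direction_deg" if "direction_deg" in p.columns else "true_direction_deg"
    if len(p):
        th = np.radians(p[col].to_numpy(dtype=float))
        ok = np.isfinite(th)
        ax.quiver(p["x"][ok], p["y"][ok],
                  ray_length_m * np.cos(th[ok]), ray_length_m * np.sin(th[ok]),
                  angles="xy", scale_units="xy", scale=1, width=0.002,
                  color="tab:blue", alpha=0.6, label="pulse direction")
    ax.set_xlim(0, layout.length_m)
    ax.set_ylim(0, layout.width_m)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_title(f"{record.bat_id}  flight {record.flight_number} "
                 f"({record.condition})")
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_emmeans(results, groupby, ax=None, **emm_kwargs):
    """Estimated marginal means with 95% CIs from a mixed-model fit."""
    mm = results.marginal_means(groupby, **emm_kwargs)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    labels = mm.drop(columns=["emmean", "se_link", "ci_lower", "ci_upper"])
    ticklabels = [", ".join(str(v) for v in row) for row in labels.to_numpy()]
    x = np.arange(len(mm))
    yerr = np.vstack([mm["emmean"] - mm["ci_lower"],
                      mm["ci_upper"] - mm["emmean"]])
    ax.errorbar(x, mm["emmean"], yerr=yerr, fmt="o", capsize=4)
    ax.set_xticks(x)
    ax.set_xticklabels(ticklabels, rotation=30, ha="right")
    ax.set_ylabel(results.model.endog_name)
    return ax


def plot_section_histograms(hists, ax=None):
    """Wall-aligned gaze-point histograms (per section + integrated)."""
    edges = hists["bin_edges"]
    centres = 0.5 * (edges[:-1] + edges[1:])
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    for sec in (1, 2, 3):
        ax.step(centres, hists[sec], where="mid", alpha=0.5,
                label=f"section {sec}")
    ax.step(centres, hists["integrated"], where="mid", color="k",
            label="integrated")
    ax.axvspan(0.0, 0.48, color="0.85", label="wall span")
    ax.set_xlabel("wall-aligned gaze-point position (m)")
    ax.set_ylabel("pulses")
    ax.legend(fontsize=8)
    return ax
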