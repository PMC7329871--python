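"""Horizontal pulse-direction reconstruction from 20-channel array levels.

Per pulse: arrival times at each microphone follow from the bat's
position and the speed of sound; raw received levels are corrected for
spherical spreading (20 log10 r re 1 m), atmospheric absorption
(2.4 dB/m at 65 kHz) and per-channel sensitivity offsets; a Gaussian
directivity pattern with a free baseline,

    level(theta) = b + A exp(-(theta - mu)^2 / (2 sigma^2)),

is least-squares fitted to the corrected levels over microphone bearing
(dB domain, bearings unwrapped around the best-level channel), and the
pulse direction is the fitted peak direction mu.  The free baseline
makes the estimate invariant to global gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from ._angles import signed_diff_deg, wrap_deg


class DirectivityFitError(ValueError):
    """Directivity fit failed (too few channels, flat pattern, no fit)."""


class CalibrationError(ValueError):
    """Sensitivity calibration incomplete."""


@dataclass
class PropagationModel:
    absorption_db_per_m: float = 2.4   # at 65 kHz
    speed_of_sound_m_s: float = 344.0  # dry air at the 22 C chamber temperature
    reference_distance_m: float = 1.0

    def loss_db(self, r_m):
        r = np.asarray(r_m, dtype=float)
        if np.any(r <= 0):
            raise ValueError("path length must be positive")
        spread = 20.0 * np.log10(r / self.reference_distance_m)
        return spread + self.absorption_db_per_m * r


@dataclass
class MicCalibration:
    """Per-channel sensitivity offsets from a reference-tone pre-measurement.

    Reference protocol: loudspeaker 1 m in front of each microphone,
    3-ms tone bursts at 107 dB SPL / 65 kHz.
    """

    sensitivity_offset_db: np.ndarray
    reference_level_db: float = 107.0
    reference_frequency_hz: float = 65_000.0
    reference_distance_m: float = 1.0

    @classmethod
    def flat(cls, n_channels: int) -> "MicCalibration":
        return cls(np.zeros(n_channels))


@dataclass
class DirectivityFit:
    amplitude_db: float       # fitted peak level b + A
    direction_deg: float      # mu, wrapped to (-180, 180]
    width_deg: float          # sigma
    baseline_db: float
    rms_residual_db: float
    n_channels_used: int
    used_mask: np.ndarray = field(repr=False, default=None)


def estimate_arrival_times(emission_time_s, position, layout,
                           model: PropagationModel | None = None) -> np.ndarray:
    """Expected pulse arrival time at each array channel."""
    model = model or PropagationModel()
    r = layout.mic_distances(position)
    return emission_time_s + r / model.speed_of_sound_m_s


def correct_received_level(raw_level_db, r_m, channel=None,
                           calibration: MicCalibration | None = None,
                           model: PropagationModel | None = None):
    """Loss- and sensitivity-corrected level at the source.

    corrected = raw + 20 log10(r / 1 m) + 2.4 dB/m * r - offset_ch
    """
    model = model or PropagationModel()
    corrected = np.asarray(raw_level_db, dtype=float) + model.loss_db(r_m)
    if calibration is not None:
        offsets = calibration.sensitivity_offset_db
        corrected = corrected - (offsets[channel] if channel is not None else offsets)
    return corrected if corrected.ndim else float(corrected)


def calibrate_sensitivity(responses_db, reference_level_db: float = 107.0) -> MicCalibration:
    """Offsets making corrected reference-tone responses equal across channels.

    Offsets are relative to the median channel response (the median
    channel gets offset 0), so a single hot channel is attributed its
    full excess.  ``responses_db`` may contain NaN only for channels
    that were never measured, which is an error.
    """
    r = np.asarray(responses_db, dtype=float)
    if np.any(~np.isfinite(r)):
        raise CalibrationError("missing channel recording")
    offsets = r - np.median(r)
    return MicCalibration(offsets, reference_level_db=reference_level_db)


def _gauss_baseline(theta, baseline, amp, mu, sigma):
    return baseline + amp * np.exp(-((theta - mu) ** 2) / (2.0 * sigma ** 2))


def fit_directivity(corrected_levels_db, bearings_deg,
                    min_channels: int = 5,
                    min_span_deg: float = 40.0,
                    noise_floor_db: float | None = None,
                    min_amplitude_db: float = 3.0,
                    valid_mask=None) -> DirectivityFit:
    """Gaussian directivity fit over microphone bearing.

    Channels flagged invalid (occluded, NaN level, or below
    ``noise_floor_db`` + 6 dB) are excluded.  Bearings are unwrapped
    around the best-level channel so the fit never straddles the
    +/-180 deg seam.  Raises :class:`DirectivityFitError` on too few
    channels, too little bearing span, a flat pattern, a non-converged
    fit, or a width beyond 180 deg.
    """
    levels = np.asarray(corrected_levels_db, dtype=float)
    bearings = np.asarray(bearings_deg, dtype=float)
    mask = np.isfinite(levels) & np.isfinite(bearings)
    if valid_mask is not None:
        mask &= np.asarray(valid_mask, dtype=bool)
    if noise_floor_db is not None:
        mask &= levels > noise_floor_db + 6.0
    if mask.sum() < min_channels:
        raise DirectivityFitError(f"only {int(mask.sum())} valid channels")
    lv, th = levels[mask], bearings[mask]
    best = np.argmax(lv)
    rel = signed_diff_deg(th, th[best])
    if rel.max() - rel.min() < min_span_deg:
        raise DirectivityFitError("bearing span too small")
    dyn = lv.max() - lv.min()
    if dyn < min_amplitude_db:
        raise DirectivityFitError("flat level pattern")
    p0 = (lv.min(), dyn, 0.0, 30.0)
    bounds = ([-np.inf, 0.0, -180.0, 1.0], [np.inf, np.inf, 180.0, 360.0])
    try:
        popt, _ = curve_fit(_gauss_baseline, rel, lv, p0=p0, bounds=bounds, maxfev=5000)
    except RuntimeError as err:
        raise DirectivityFitError(f"fit did not converge: {err}") from err
    baseline, amp, mu_rel, sigma = popt
    if sigma > 180.0:
        raise DirectivityFitError(f"width {sigma:.0f} deg exceeds 180 deg")
    if amp < min_amplitude_db:
        raise DirectivityFitError("fitted amplitude below dynamic-range minimum")
    resid = lv - _gauss_baseline(rel, *popt)
    full_mask = np.zeros_like(mask)
    full_mask[np.nonzero(mask)[0]] = True
    return DirectivityFit(
        amplitude_db=float(baseline + amp),
        direction_deg=wrap_deg(th[best] + mu_rel),
        width_deg=float(sigma),
        baseline_db=float(baseline),
        rms_residual_db=float(np.sqrt(np.mean(resid ** 2))),
        n_channels_used=int(mask.sum()),
        used_mask=full_mask,
    )


def pulse_direction(fit: DirectivityFit) -> float:
    """Horizontal pulse direction: peak of the fitted directivity pattern."""
    if fit is None:
        raise DirectivityFitError("no successful fit")
    return wrap_deg(fit.direction_deg)


def localize_pulse(raw_levels_db, position, layout,
                   calibration: MicCalibration | None = None,
                   model: PropagationModel | None = None,
                   occluded_mask=None, **fit_kwargs) -> DirectivityFit:
    """Correction + fit convenience wrapper for one pulse."""
    model = model or PropagationModel()
    r = layout.mic_distances(position)
    bearings = layout.mic_bearings(position)
    corrected = correct_received_level(raw_levels_db, r, calibration=calibration, model=model)
    valid = None if occluded_mask is None else ~np.asarray(occluded_mask, dtype=bool)
    return fit_directivity(corrected, bearings, valid_mask=valid, **fit_kwargs)
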