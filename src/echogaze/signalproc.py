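"""Pulse detection, terminal-FM feature extraction and inter-pulse intervals.

Spectrograms use the study's analysis parameters: Hanning window of
1,024 samples of which 512 are zero-padding (so 512 real samples),
98% overlap, at fs = 500 kHz.  Pulses are contiguous supra-threshold
energy regions; the terminal downward FM sweep of the second harmonic
(tFM2) is the last region of the pulse whose peak frequency drops below
the CF2 plateau within 25 dB of the maximum-energy portion, and its
first frame defines the emission time.  IPIs are intervals between the
tFM2 onsets of successive calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann


class EmptySpectrogramError(ValueError):
    """Audio shorter than one analysis window."""


class ExtractionError(ValueError):
    """tFM2 could not be isolated for a pulse."""


@dataclass
class SpectrogramParams:
    n_window: int = 1024       # FFT length, power of two
    n_zero_padded: int = 512   # zero-filled points inside the window
    overlap: float = 0.98
    fs_hz: float = 500_000.0

    def __post_init__(self):
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be < 100%")
        if self.n_window & (self.n_window - 1):
            raise ValueError("n_window must be a power of two")

    @property
    def n_effective(self) -> int:
        return self.n_window - self.n_zero_padded

    @property
    def hop(self) -> int:
        return max(int(round(self.n_effective * (1.0 - self.overlap))), 1)

    @property
    def hop_s(self) -> float:
        return self.hop / self.fs_hz


@dataclass
class Spectrogram:
    times: np.ndarray
    freqs: np.ndarray
    power_db: np.ndarray  # (n_freq, n_frames), dB re spectrogram maximum
    params: SpectrogramParams
    ref_power: float = 1.0  # absolute power at the 0 dB reference


@dataclass
class PulseEvent:
    emission_time_s: float     # tFM2 onset
    tfm2_onset_s: float
    peak_level_db: float
    support_s: tuple
    per_channel_levels: np.ndarray | None = None
    position_at_emission: tuple | None = None
    direction_deg: float = float("nan")
    group_id: int | None = None
    group_size: int | None = None


def compute_spectrogram(audio, params: SpectrogramParams | None = None) -> Spectrogram:
    params = params or SpectrogramParams()
    x = np.asarray(audio, dtype=float)
    if len(x) < params.n_effective:
        raise EmptySpectrogramError("audio shorter than one analysis window")
    win = hann(params.n_effective, sym=False)
    stft = ShortTimeFFT(win, hop=params.hop, fs=params.fs_hz,
                        mfft=params.n_window, scale_to="magnitude")
    mag = np.abs(stft.stft(x)).astype(np.float32)
    power = mag ** 2
    ref = power.max()
    floor_db = -140.0
    if ref <= 0:
        db = np.full(power.shape, floor_db, dtype=np.float32)
    else:
        with np.errstate(divide="ignore"):
            db = 10.0 * np.log10(power / ref, where=power > 0,
                                 out=np.full(power.shape, -np.inf, dtype=np.float32))
        db = np.maximum(db, floor_db)
    times = stft.t(len(x))
    return Spectrogram(times=times, freqs=stft.f, power_db=db, params=params,
                       ref_power=float(ref))


def detect_pulses(spec: Spectrogram, threshold_db: float = -45.0,
                  merge_gap_ms: float = 2.0,
                  min_duration_ms: float = 1.0,
                  band_hz: tuple = (20_000.0, 150_000.0)) -> list[tuple]:
    """Contiguous supra-threshold energy regions, merged across gaps
    shorter than ``merge_gap_ms``.  Returns (t_start, t_end) pairs
    ordered by onset; empty list on silence."""
    if spec.power_db.size == 0:
        raise ValueError("empty spectrogram")
    if spec.ref_power <= 0:
        return []  # digital silence
    in_band = (spec.freqs >= band_hz[0]) & (spec.freqs <= band_hz[1])
    frame_energy = (10.0 ** (spec.power_db[in_band] / 10.0)).sum(axis=0)
    ref = frame_energy.max()
    if ref <= 0:
        return []
    frame_db = 10.0 * np.log10(np.maximum(frame_energy / ref, 1e-30))
    active = frame_db > threshold_db
    if not active.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], active.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2] - 1
    merge_frames = int(round(merge_gap_ms / 1000.0 / spec.params.hop_s))
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] <= merge_frames:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_frames = min_duration_ms / 1000.0 / spec.params.hop_s
    return [(float(spec.times[s]), float(spec.times[e]))
            for s, e in merged if (e - s) >= min_frames]


def extract_tfm2(spec: Spectrogram, support: tuple,
                 band_db: float = 25.0,
                 cf_drop_hz: float = 1500.0) -> tuple[float, float]:
    """tFM2 onset time and peak level for one detected pulse.

    Within the support, frames whose peak frequency has dropped below
    the CF2 plateau by more than ``cf_drop_hz`` and whose level lies
    within ``band_db`` of the maximum-energy portion belong to FM
    sweeps; the *last* such contiguous run is the terminal sweep, and
    its first frame is the onset.  The returned level is invariant to
    global amplitude scaling in the onset (the level itself is the
    absolute spectrogram peak within the support, dB re file max).
    """
    t0, t1 = support
    idx = np.nonzero((spec.times >= t0 - 1e-12) & (spec.times <= t1 + 1e-12))[0]
    if idx.size == 0:
        raise ExtractionError("empty support")
    sub = spec.power_db[:, idx]
    frame_peak_db = sub.max(axis=0)
    peak_freqs = spec.freqs[np.argmax(sub, axis=0)]
    max_db = frame_peak_db.max()
    strong = frame_peak_db >= max_db - band_db
    # CF2 plateau frequency: dominant frequency of the strongest frames
    cf_hz = float(np.median(peak_freqs[frame_peak_db >= max_db - 6.0]))
    swept = strong & (peak_freqs < cf_hz - cf_drop_hz)
    if not swept.any():
        raise ExtractionError("no FM sweep within 25 dB of the energy maximum")
    edges = np.flatnonzero(np.diff(np.concatenate([[0], swept.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2] - 1
    # terminal sweep = last contiguous run of swept frames
    s = starts[-1]
    onset = float(spec.times[idx[s]])
    return onset, float(max_db)


def compute_ipis(tfm2_onsets_s) -> np.ndarray:
    """Inter-pulse intervals (ms) between successive tFM2 onsets."""
    t = np.asarray(tfm2_onsets_s, dtype=float)
    if len(t) < 2:
        return np.empty(0)
    d = np.diff(t)
    if np.any(d <= 0):
        raise ValueError("pulse onsets must be strictly increasing")
    return d * 1000.0


def detect_and_extract(audio, params: SpectrogramParams | None = None,
                       threshold_db: float = -45.0) -> list[PulseEvent]:
    """Detection + tFM2 extraction for a mono recording."""
    spec = compute_spectrogram(audio, params)
    events = []
    for support in detect_pulses(spec, threshold_db=threshold_db):
        try:
            onset, level = extract_tfm2(spec, support)
        except ExtractionError:
            continue
        events.append(PulseEvent(emission_time_s=onset, tfm2_onset_s=onset,
                                 peak_level_db=level, support_s=support))
    return events
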