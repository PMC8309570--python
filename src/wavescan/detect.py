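"""Wave-train detection and measurement.

A wave train is a time- and frequency-localized increase of spectral power,
operationalized as a strict local maximum of the smoothed wavelet
spectrogram. Each detected maximum is characterized by four attributes:

* central frequency f_central (the frequency coordinate of the maximum),
* maximal power psd_max,
* duration at half-maximum, expressed in periods (duration_s * f_central),
* bandwidth at half-maximum (Hz).

The two widths are measured on one-dimensional slices through the maximum
(the time slice at f_central and the frequency slice at t_peak), with linear
interpolation at the half-maximum crossings. A maximum whose slice runs into
the record edge before crossing half-maximum is rejected with code ``EDGE``;
one whose slice rises above psd_max again before crossing (an overlapping,
engulfed train) is rejected with code ``ENGULFED``. Trains shorter than 1/10
of the signal period at their central frequency are discarded.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter

from .preprocess import SignalRecord
from .tfr import MorletParams, Spectrogram, adaptive_smooth, cwt_spectrogram

EVENT_COLUMNS = ["subject_id", "group", "arm", "muscle", "t_peak_s",
                 "f_central_hz", "psd_max", "duration_s", "duration_periods",
                 "bandwidth_hz", "rejected_code"]


@dataclass(frozen=True)
class WaveTrain:
    t_peak: float
    f_central: float
    psd_max: float
    duration_s: float
    duration_periods: float
    bandwidth: float
    subject_id: str = "anon"
    group: str = "NA"
    arm: str = "NA"
    muscle: str = "NA"
    rejected_code: str | None = None


@dataclass(frozen=True)
class ParameterBox:
    """Closed-interval bounds in the four-parameter wave-train space."""

    min_freq: float = 0.0
    max_freq: float = math.inf
    min_psd: float = 0.0
    max_psd: float = math.inf
    min_durat: float = 0.0
    max_durat: float = math.inf
    min_bandwidth: float = 0.0
    max_bandwidth: float = math.inf

    def __post_init__(self):
        for lo, hi, name in [(self.min_freq, self.max_freq, "freq"),
                             (self.min_psd, self.max_psd, "psd"),
                             (self.min_durat, self.max_durat, "durat"),
                             (self.min_bandwidth, self.max_bandwidth, "bandwidth")]:
            if lo > hi:
                raise ValueError(f"min_{name} > max_{name}")

    def contains(self, ev: WaveTrain) -> bool:
        return (self.min_freq <= ev.f_central <= self.max_freq
                and self.min_psd <= ev.psd_max <= self.max_psd
                and self.min_durat <= ev.duration_periods <= self.max_durat
                and self.min_bandwidth <= ev.bandwidth <= self.max_bandwidth)

    def intersect(self, other: "ParameterBox") -> "ParameterBox":
        """Intersection; a dimension with disjoint intervals becomes the
        empty selection (inf, inf)."""
        bounds = []
        for lo_a, hi_a, lo_b, hi_b in [
                (self.min_freq, self.max_freq, other.min_freq, other.max_freq),
                (self.min_psd, self.max_psd, other.min_psd, other.max_psd),
                (self.min_durat, self.max_durat, other.min_durat, other.max_durat),
                (self.min_bandwidth, self.max_bandwidth,
                 other.min_bandwidth, other.max_bandwidth)]:
            lo, hi = max(lo_a, lo_b), min(hi_a, hi_b)
            if lo > hi:
                lo = hi = math.inf
            bounds.extend((lo, hi))
        return ParameterBox(*bounds)


@dataclass(frozen=True)
class DetectionConfig:
    fmin: float = 0.1
    fmax: float = 50.0
    fstep: float = 0.1
    params: MorletParams = field(default_factory=MorletParams)
    edge_pad_s: float = 1.0
    min_duration_periods: float = 0.1


@dataclass(frozen=True)
class WaveTrainSet:
    events: tuple
    rejected: tuple
    duration_s: float
    valid_duration_s: float
    subject_id: str = "anon"
    group: str = "NA"
    arm: str = "NA"
    muscle: str = "NA"


def find_local_maxima(sg: Spectrogram) -> np.ndarray:
    """Grid points strictly greater than all 8 neighbors, inside the valid
    cone; plateau cells (ties with a neighbor) are not peaks."""
    if not sg.smoothed:
        raise ValueError("local maxima are detected on the smoothed spectrogram")
    psd = sg.psd
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neighbor_max = maximum_filter(psd, footprint=footprint, mode="constant",
                                  cval=-np.inf)
    peaks = (psd > neighbor_max) & sg.valid_mask
    # rows at the grid's frequency edges lack a full neighborhood
    peaks[0, :] = False
    peaks[-1, :] = False
    return np.argwhere(peaks)


def _halfmax_width(vals: np.ndarray, j: int, half: float, pmax: float):
    """Half-max width (in samples, interpolated) of the region around j.

    Returns (width, code): code is None on success, 'EDGE' when the slice
    reaches the array end while still above half-maximum, 'ENGULFED' when it
    rises above pmax before crossing.
    """
    n = vals.size
    # leftward
    left_seg = vals[:j]
    below = left_seg < half
    if not below.any():
        return np.nan, "EDGE"
    idx = int(np.flatnonzero(below)[-1])            # first sample below, going left
    if idx + 1 < j and np.max(left_seg[idx + 1:]) > pmax:
        return np.nan, "ENGULFED"
    frac = (vals[idx + 1] - half) / (vals[idx + 1] - vals[idx])
    left_x = (idx + 1) - frac
    # rightward
    right_seg = vals[j + 1:]
    below = right_seg < half
    if not below.any():
        return np.nan, "EDGE"
    idx2 = j + 1 + int(np.flatnonzero(below)[0])    # first sample below, going right
    if idx2 > j + 1 and np.max(vals[j + 1:idx2]) > pmax:
        return np.nan, "ENGULFED"
    frac = (vals[idx2 - 1] - half) / (vals[idx2 - 1] - vals[idx2])
    right_x = (idx2 - 1) + frac
    return right_x - left_x, None


def measure_wavetrain(sg: Spectrogram, peak) -> WaveTrain:
    """Measure the four attributes at a grid peak; rejections are returned
    as WaveTrain values with a ``rejected_code``, never raised."""
    i, j = int(peak[0]), int(peak[1])
    pmax = float(sg.psd[i, j])
    half = 0.5 * pmax
    f_central = float(sg.freqs[i])
    t_peak = float(sg.times[j])
    dt = 1.0 / sg.fs

    meta = dict(subject_id=sg.subject_id, group=sg.group, arm=sg.arm,
                muscle=sg.muscle)
    w_t, code = _halfmax_width(sg.psd[i, :], j, half, pmax)
    if code is None:
        w_f, code = _halfmax_width(sg.psd[:, j], i, half, pmax)
    else:
        w_f = np.nan
    if code is not None:
        return WaveTrain(t_peak, f_central, pmax, np.nan, np.nan, np.nan,
                         rejected_code=code, **meta)
    duration_s = w_t * dt
    bandwidth = w_f * sg.fstep
    return WaveTrain(t_peak, f_central, pmax, duration_s,
                     duration_s * f_central, bandwidth, **meta)


def filter_short(events: Iterable[WaveTrain],
                 min_periods: float = 0.1) -> list[WaveTrain]:
    """Drop trains shorter than 1/10 of the signal period at f_central.

    The rule is "less than": a duration of exactly ``min_periods`` is kept.
    """
    return [e for e in events if e.duration_periods >= min_periods]


def detect_wavetrains(rec: SignalRecord,
                      config: DetectionConfig = DetectionConfig()) -> WaveTrainSet:
    """Full per-record chain: spectrogram -> smoothing -> maxima ->
    measurement -> short-train filter; events sorted by peak time."""
    sg = cwt_spectrogram(rec, fmin=config.fmin, fmax=config.fmax,
                         fstep=config.fstep, params=config.params,
                         edge_pad_s=config.edge_pad_s)
    sg = adaptive_smooth(sg)
    measured = [measure_wavetrain(sg, pk) for pk in find_local_maxima(sg)]
    accepted = filter_short([e for e in measured if e.rejected_code is None],
                            config.min_duration_periods)
    accepted.sort(key=lambda e: e.t_peak)
    rejected = tuple(e for e in measured if e.rejected_code is not None)
    return WaveTrainSet(events=tuple(accepted), rejected=rejected,
                        duration_s=sg.duration_s,
                        valid_duration_s=sg.valid_duration_s,
                        subject_id=sg.subject_id, group=sg.group,
                        arm=sg.arm, muscle=sg.muscle)


def select_box(events: Iterable[WaveTrain], box: ParameterBox) -> list[WaveTrain]:
    """Keep the events inside the closed parameter box."""
    return [e for e in events if box.contains(e)]


def rate_per_second(events, record_duration: float) -> float:
    """Events per second over the valid (non-masked) record duration."""
    if record_duration <= 0:
        raise ValueError("record duration must be positive")
    n = events if isinstance(events, (int, np.integer)) else len(list(events))
    return n / record_duration


def events_to_frame(sets: Iterable[WaveTrainSet] | WaveTrainSet,
                    include_rejected: bool = False) -> pd.DataFrame:
    """Event table with the interchange column order."""
    if isinstance(sets, WaveTrainSet):
        sets = [sets]
    rows = []
    for ws in sets:
        evs = list(ws.events) + (list(ws.rejected) if include_rejected else [])
        for e in evs:
            rows.append((e.subject_id, e.group, e.arm, e.muscle, e.t_peak,
                         e.f_central, e.psd_max, e.duration_s,
                         e.duration_periods, e.bandwidth,
                         e.rejected_code or ""))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
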