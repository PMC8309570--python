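"""Self-contained verification studies.

Each function generates its own inputs from a seed, runs one slice of the
pipeline, and returns the measured quantities. They back the package's
reproduction script and the acceptance-style tests, and double as worked
examples of the API.

Study conditions (sample sizes, rates, amplitudes, noise) are fixed here as
the package's reference conditions; see docs/methods.md for the rationale
behind each choice.
"""
from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .detect import (DetectionConfig, detect_wavetrains, events_to_frame,
                     find_local_maxima, measure_wavetrain)
from .diagrams import auc_diagram_2d, auc_diagram_3d, best_cell, refine
from .preprocess import SignalRecord
from .stats import bonferroni_alpha, roc_auc, welch_group_compare
from .synth import BandRate, BurstSpec, CohortSpec, _add_burst, synth_cohort
from .tfr import adaptive_smooth, cwt_spectrogram, wavelet_widths

__all__ = ["expected_halfmax_widths", "tone_recovery_study",
           "burst_attribute_study", "cohort_discrimination_study",
           "multiscale_null_study", "welch_alpha_study",
           "slice_consistency_study", "auc_u_identity_study"]


def expected_halfmax_widths(f0: float, duration_periods: float,
                            fb: float = 1.0, fc: float = 1.0):
    """Closed-form prediction of the measured half-max widths of an isolated
    Gaussian burst: the burst envelope, the wavelet envelope and the
    smoothing kernel are all Gaussian, so their convolution is Gaussian with
    summed variances (squaring the modulus halves the variance).

    Returns (duration_s, bandwidth_hz) at half maximum.
    """
    sigma_t = (fc / f0) * math.sqrt(fb / 2.0)
    sigma_f = 1.0 / (2.0 * math.pi * sigma_t)
    s = duration_periods / (2.0 * f0 * math.sqrt(math.log(2.0)))
    s_f = 1.0 / (2.0 * math.pi * s)
    fwhm = 2.0 * math.sqrt(2.0 * math.log(2.0))
    dur = fwhm * math.sqrt((s * s + sigma_t * sigma_t) / 2.0
                           + (sigma_t / 2.0) ** 2)
    bw = fwhm * math.sqrt((s_f * s_f + sigma_f * sigma_f) / 2.0
                          + (sigma_f / 2.0) ** 2)
    return dur, bw


def tone_recovery_study(fs: float = 125.0, duration_s: float = 90.0):
    """Spectrogram argmax error for 90 s pure tones across the 1-50 Hz grid."""
    tones = [1.3, 2.7, 5.1, 7.9, 10.0, 15.2, 20.3, 25.7, 31.1, 37.9, 43.6,
             49.3]
    t = np.arange(int(duration_s * fs)) / fs
    errs = []
    for f0 in tones:
        sg = cwt_spectrogram(np.cos(2 * np.pi * f0 * t), fs=fs)
        prof = np.nan_to_num(
            np.nanmean(np.where(sg.valid_mask, sg.psd, np.nan), axis=1))
        errs.append(abs(float(sg.freqs[np.argmax(prof)]) - f0))
    return {"n_tones": len(tones), "max_abs_err_hz": max(errs)}


def burst_attribute_study(seed: int, n_bursts: int = 100, fs: float = 125.0):
    """Attribute recovery for isolated noisy Gaussian bursts.

    One 12 s record per burst: baseline 10 uV, white noise sigma = 2 uV,
    burst amplitude 8 uV (SNR 4), f0 ~ U(3, 12) Hz covering the parkinsonian
    (3-8 Hz) and physiological (8-12 Hz) tremor bands, duration ~ U(2, 4)
    periods. Errors are reported against the convolution-of-Gaussians
    prediction; medians summarize the 100 bursts.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    n = int(12 * fs)
    err_f, err_d, err_b = [], [], []
    for _ in range(n_bursts):
        f0 = float(rng.uniform(3.0, 12.0))
        d = float(rng.uniform(2.0, 4.0))
        x = 10.0 + rng.normal(0.0, 2.0, n)
        _add_burst(x, BurstSpec(f0=f0, amplitude=8.0, duration_periods=d,
                                onset=6.0,
                                phase=float(rng.uniform(0, 2 * np.pi))),
                   fs, "gaussian")
        np.maximum(x, 0.0, out=x)
        sg = adaptive_smooth(cwt_spectrogram(x, fs=fs, fmin=0.5, fmax=50.0,
                                             fstep=0.1))
        best = None
        for pk in find_local_maxima(sg):
            e = measure_wavetrain(sg, pk)
            if (e.rejected_code is None and abs(e.t_peak - 6.0) < 1.0
                    and abs(e.f_central - f0) < 3.0
                    and (best is None or e.psd_max > best.psd_max)):
                best = e
        if best is None:
            err_f.append(np.inf)
            err_d.append(np.inf)
            err_b.append(np.inf)
            continue
        dur, bw = expected_halfmax_widths(f0, d)
        err_f.append(abs(best.f_central - f0))
        err_d.append(abs(best.duration_s - dur) / dur)
        err_b.append(abs(best.bandwidth - bw) / bw)
    return {"n_bursts": n_bursts,
            "f_central_median_abs_err_hz": float(np.median(err_f)),
            "duration_median_rel_err": float(np.median(err_d)),
            "bandwidth_median_rel_err": float(np.median(err_b))}


def discrimination_cohort(seed: int) -> CohortSpec:
    """The worked-example emulation cohort: 10 controls vs 12 patients,
    patients with a 3x wave-train rate in 8-20 Hz, high-amplitude
    ~1-period bursts over a shared broadband background."""
    return CohortSpec(
        n_controls=10, n_patients=12, seed=seed,
        control_rates=(BandRate(1.0, 45.0, 1.0), BandRate(8.0, 20.0, 0.3)),
        patient_rates=(BandRate(1.0, 45.0, 1.0), BandRate(8.0, 20.0, 0.9)),
        amplitude_median=20.0, duration_median_periods=1.0)


def cohort_discrimination_study(seed: int):
    """Full pipeline on the discrimination cohort: detection, the Frequency
    2D AUC diagram, and the automated refinement loop."""
    coh = synth_cohort(discrimination_cohort(seed))
    sets = [detect_wavetrains(rec) for rec in coh.records]
    events = events_to_frame(sets)
    roster = pd.DataFrame([{"subject_id": s.subject_id, "group": s.group,
                            "valid_duration_s": s.valid_duration_s}
                           for s in sets])
    d = auc_diagram_2d(events, roster, "frequency")
    cell = best_cell(d)
    red = np.nan_to_num(d.auc, nan=0.0)
    i, j = np.unravel_index(np.argmax(red), red.shape)
    state = refine(events, roster)
    min_dur = (events[events.rejected_code == ""].duration_periods.min()
               if len(events) else np.nan)
    return {
        "events": events, "roster": roster,
        "best_cell": cell,
        "best_red_cell": (float(d.lower_bounds[i]), float(d.upper_bounds[j]),
                          float(d.auc[i, j])),
        "auc_8_20": float(d.auc[np.flatnonzero(d.lower_bounds == 8.0)[0],
                                np.flatnonzero(d.upper_bounds == 20.0)[0]]),
        "refined_box": state.box,
        "stop_reason": state.stop_reason,
        "min_emitted_duration_periods": float(min_dur),
    }


def null_event_cohort(rng, n_patients: int = 12, n_controls: int = 10,
                      rate: float = 1.0, duration_s: float = 90.0,
                      frange=(1.0, 10.0)):
    """Event-level null cohort: identical Poisson rate and iid uniform
    frequencies in both groups."""
    rows, roster = [], []
    for group, n in (("patient", n_patients), ("control", n_controls)):
        for i in range(n):
            sid = f"{group}{i:02d}"
            k = rng.poisson(rate * duration_s)
            f = rng.uniform(frange[0], frange[1], k)
            rows.append(pd.DataFrame({
                "subject_id": sid, "group": group, "arm": "right",
                "muscle": "extensor", "t_peak_s": 0.0, "f_central_hz": f,
                "psd_max": 50.0, "duration_s": 0.2, "duration_periods": 1.0,
                "bandwidth_hz": 2.0, "rejected_code": ""}))
            roster.append({"subject_id": sid, "group": group,
                           "valid_duration_s": duration_s})
    empty = pd.DataFrame(columns=rows[0].columns) if rows else None
    events = pd.concat(rows, ignore_index=True) if rows else empty
    return events, pd.DataFrame(roster)


def multiscale_null_study(seed: int, n_sim: int = 200,
                          resolutions=range(1, 13), alpha0: float = 0.05):
    """Fraction of null cohorts with any significance-masked-in cell in the
    3D diagram (family-wise type-I rate of the whole multiscale scan)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    flagged = 0
    for _ in range(n_sim):
        events, roster = null_event_cohort(rng)
        d3 = auc_diagram_3d(events, roster, "frequency", prange=(1.0, 10.0),
                            resolutions=resolutions, alpha0=alpha0)
        if any(s.significant.any() for s in d3.slices):
            flagged += 1
    return {"n_sim": n_sim, "flag_fraction": flagged / n_sim,
            "bound": alpha0 + 1.96 * math.sqrt(alpha0 * (1 - alpha0) / n_sim)}


def welch_alpha_study(seed: int):
    """Bonferroni-corrected level over the Welch comparison's 250 bins
    (10 s Hann windows, 7/8 overlap, 0-25 Hz), computed from an actual run."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    fs = 125.0
    recs = [SignalRecord(10.0 + rng.normal(0, 1.0, int(90 * fs)), fs,
                         stage="decimated_envelope") for _ in range(6)]
    out = welch_group_compare(recs[:3], recs[3:])
    return {"n_bins": int(out.n_bins),
            "alpha_corrected": float(out.alpha_corrected)}


def auc_u_identity_study(seed: int, n_draws: int = 1000):
    """Max |AUC * n1 n2 - U| over random tied rate vectors, U computed by
    the independent scipy implementation."""
    from scipy.stats import mannwhitneyu
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    worst = 0.0
    for _ in range(n_draws):
        n1 = int(rng.integers(5, 16))
        n2 = int(rng.integers(5, 16))
        a = rng.integers(0, 8, n1).astype(float)
        b = rng.integers(0, 8, n2).astype(float)
        u = mannwhitneyu(a, b, alternative="two-sided").statistic
        worst = max(worst, abs(roc_auc(a, b) * n1 * n2 - u))
    return {"n_draws": n_draws, "max_abs_diff": worst}


def slice_consistency_study(seed: int, resolutions=(1, 5, 9, 15)):
    """Max |3D slice - independently built 2D diagram| over the stack."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    events, roster = null_event_cohort(rng, rate=1.5)
    d3 = auc_diagram_3d(events, roster, "frequency", prange=(1.0, 10.0),
                        resolutions=resolutions)
    worst = 0.0
    n_cells = 0
    for s in d3.slices:
        edges = np.linspace(1.0, 10.0, s.resolution + 1)
        d2 = auc_diagram_2d(events, roster, "frequency",
                            lower_bounds=edges[:-1], upper_bounds=edges[1:],
                            min_width=(9.0 / s.resolution) * (1 - 1e-9),
                            compute_p=True)
        if not np.array_equal(s.diagram.auc, d2.auc, equal_nan=True):
            diff = np.abs(np.nan_to_num(s.diagram.auc) - np.nan_to_num(d2.auc))
            worst = max(worst, float(diff.max()))
        if not np.array_equal(s.diagram.p, d2.p, equal_nan=True):
            diff = np.abs(np.nan_to_num(s.diagram.p) - np.nan_to_num(d2.p))
            worst = max(worst, float(diff.max()))
        n_cells += int(s.diagram.defined.sum())
    return {"n_cells": n_cells, "max_abs_diff": worst}
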