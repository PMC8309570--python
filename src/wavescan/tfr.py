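"""Complex Morlet spectrograms and frequency-adaptive Gaussian smoothing.

The analyzing wavelet is

    psi(x) = (pi * Fb)^(-1/2) * exp(2i pi Fc x) * exp(-x^2 / Fb)

with bandwidth parameter Fb = 1 and center-frequency parameter Fc = 1 by
default. The scale-to-frequency map is f = Fc / a, so with Fc = 1 the scale
at analysis frequency f is simply 1/f seconds. The Gaussian envelope of the
scaled wavelet has time SD

    sigma_t(f) = (Fc / f) * sqrt(Fb / 2),     sigma_f(f) = 1 / (2 pi sigma_t)

so sigma_t * sigma_f = 1/(2 pi) at every frequency.

Power calibration
-----------------
Coefficients are normalized so that a stationary sinusoid of amplitude A uV
reads a peak power of A^2 / 2 at its own frequency, *independent of the
analysis frequency*. A per-Hz density normalization necessarily carries a
1/f trend across analysis frequencies, which shifts the ridge maximum of a
pure tone by about f / (4 pi^2 Fb Fc^2) — over 1 Hz at 50 Hz — so the flat
amplitude calibration is used throughout and
:func:`equivalent_noise_bandwidth` gives the exact factor for converting a
reading into a uV^2/Hz density (divide by ENBW(f)).

Smoothing
---------
Spectrograms are smoothed with a two-dimensional Gaussian whose SDs adapt to
the wavelet's own resolution at each frequency: half the wavelet time and
frequency widths (a wider kernel would distort the spectrogram shape). The
frequency direction uses explicit per-row kernels truncated at +-3 SD; the
time direction applies the exact Gaussian transfer function in the Fourier
domain, both with mirrored boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq
from scipy.signal import fftconvolve
from scipy.signal import hilbert as _hilbert

from .preprocess import SignalRecord


@dataclass(frozen=True)
class MorletParams:
    fb: float = 1.0   # bandwidth parameter (dimensionless)
    fc: float = 1.0   # center frequency parameter (dimensionless)

    def __post_init__(self):
        if self.fb <= 0 or self.fc <= 0:
            raise ValueError("Fb and Fc must be positive")


def morlet(x, p: MorletParams = MorletParams()) -> np.ndarray:
    """Complex Morlet mother wavelet evaluated at dimensionless time x."""
    x = np.asarray(x, dtype=float)
    return (np.pi * p.fb) ** -0.5 * np.exp(2j * np.pi * p.fc * x) * np.exp(-x * x / p.fb)


def wavelet_widths(f, p: MorletParams = MorletParams()):
    """(sigma_t [s], sigma_f [Hz]) of the scaled wavelet at frequency f."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    sigma_t = (p.fc / f) * np.sqrt(p.fb / 2.0)
    sigma_f = 1.0 / (2.0 * np.pi * sigma_t)
    return sigma_t, sigma_f


def equivalent_noise_bandwidth(f, p: MorletParams = MorletParams()):
    """ENBW (Hz) of the wavelet's power response at analysis frequency f.

    Dividing a calibrated power reading by this converts it into a uV^2/Hz
    spectral density.
    """
    f = np.asarray(f, dtype=float)
    return f / (p.fc * np.sqrt(2.0 * np.pi * p.fb))


def calibrate(amplitude: float = 1.0) -> float:
    """Peak power reading of a stationary sinusoid of the given amplitude."""
    return 0.5 * amplitude * amplitude


@dataclass(frozen=True)
class Spectrogram:
    """Time-frequency power matrix (frequency x time) with axis vectors.

    ``valid_mask`` is False inside the cone of influence (within
    max(edge_pad_s, 3 sigma_t(f)) of either record edge, per row);
    ``valid_duration_s`` is the scalar record duration used for rate
    normalization (record length minus the edge padding on both sides).
    """

    psd: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    params: MorletParams
    smoothed: bool
    valid_mask: np.ndarray
    duration_s: float
    valid_duration_s: float
    subject_id: str = "anon"
    group: str = "NA"
    arm: str = "NA"
    muscle: str = "NA"

    def __post_init__(self):
        if self.psd.shape != (self.freqs.size, self.times.size):
            raise ValueError("psd shape inconsistent with axis vectors")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def fstep(self) -> float:
        return float(self.freqs[1] - self.freqs[0]) if self.freqs.size > 1 else 0.0


def cwt_spectrogram(rec, fs: float | None = None, fmin: float = 0.1,
                    fmax: float = 50.0, fstep: float = 0.1,
                    params: MorletParams = MorletParams(),
                    edge_pad_s: float = 1.0,
                    support_sigmas: float = 4.0) -> Spectrogram:
    """Morlet power spectrogram of an envelope record on a uniform grid.

    Each row is the correlation of the signal with the scaled, conjugated
    wavelet at scale a = Fc/f, calibrated so a tone of amplitude A peaks at
    A^2/2 (see module docstring).
    """
    if isinstance(rec, SignalRecord):
        x = rec.samples
        fs = rec.fs
        meta = dict(subject_id=rec.subject_id, group=rec.group,
                    arm=rec.arm, muscle=rec.muscle)
    else:
        x = np.asarray(rec, dtype=float)
        if fs is None:
            raise ValueError("fs is required for a bare sample array")
        meta = {}
    if x.size == 0:
        raise ValueError("empty signal")
    if fmax >= fs / 2.0:
        raise ValueError(f"fmax={fmax} Hz must be below Nyquist {fs / 2.0} Hz")
    if fmin <= 0 or fstep <= 0 or fmax < fmin:
        raise ValueError("need 0 < fmin <= fmax and fstep > 0")

    nf = int(np.floor((fmax - fmin) / fstep + 1e-9)) + 1
    freqs = fmin + fstep * np.arange(nf)
    n = x.size
    # correlate the analytic signal with the complex wavelet: the real
    # signal's negative-frequency component otherwise aliases into the
    # passband near Nyquist (a 2 f0 beat folded to fs - 2 f0) and tilts the
    # ridge of high-frequency tones
    xa = _hilbert(x)
    psd = np.empty((nf, n))
    mask = np.zeros((nf, n), dtype=bool)
    sigma_t, _ = wavelet_widths(freqs, params)
    for i, f in enumerate(freqs):
        a = params.fc / f
        half = int(np.ceil(support_sigmas * sigma_t[i] * fs))
        m = np.arange(-half, half + 1)
        psi = morlet(m / (a * fs), params)
        # correlation with the conjugated wavelet, flat amplitude calibration
        c = fftconvolve(xa, np.conj(psi[::-1]), mode="same") * (1.0 / (fs * a))
        psd[i] = 0.5 * np.abs(c) ** 2
        edge = int(np.ceil(max(edge_pad_s, 3.0 * sigma_t[i]) * fs))
        if 2 * edge < n:
            mask[i, edge:n - edge] = True

    duration = n / fs
    return Spectrogram(psd=psd, freqs=freqs, times=np.arange(n) / fs, fs=fs,
                       params=params, smoothed=False, valid_mask=mask,
                       duration_s=duration,
                       valid_duration_s=max(duration - 2.0 * edge_pad_s, 0.0),
                       **meta)


def adaptive_smooth(sg: Spectrogram, truncate: float = 3.0) -> Spectrogram:
    """Frequency-adaptive 2D Gaussian smoothing.

    At grid frequency f the kernel SDs are 0.5 * sigma_t(f) in time and
    0.5 * sigma_f(f) in frequency; every kernel sums to one, so a constant
    spectrogram is left unchanged and total power in a locally flat region is
    preserved. Nonnegativity is preserved (the result is clipped at zero to
    remove FFT round-off).
    """
    if sg.smoothed:
        raise ValueError("spectrogram is already smoothed")
    psd = sg.psd
    nf, nt = psd.shape
    fstep = sg.fstep
    if nf > 1 and not np.allclose(np.diff(sg.freqs), fstep):
        raise ValueError("adaptive smoothing requires a uniform frequency grid")
    sigma_t, sigma_f = wavelet_widths(sg.freqs, sg.params)
    s_f_bins = 0.5 * sigma_f / fstep if nf > 1 else np.zeros(nf)
    s_t_bins = 0.5 * sigma_t * sg.fs

    # frequency direction: per-row truncated Gaussian weights, mirrored edges,
    # assembled into one banded weight matrix so the pass is a single matmul
    half_f = np.ceil(truncate * s_f_bins).astype(int)
    pad_f = min(int(half_f.max()), nf - 1) if nf > 1 else 0
    padded = np.pad(psd, ((pad_f, pad_f), (0, 0)), mode="reflect") if pad_f else psd
    weights = np.zeros((nf, nf + 2 * pad_f))
    for i in range(nf):
        hw = min(half_f[i], pad_f)
        if hw == 0 or s_f_bins[i] < 1e-12:
            weights[i, i + pad_f] = 1.0
            continue
        offs = np.arange(-hw, hw + 1)
        w = np.exp(-0.5 * (offs / s_f_bins[i]) ** 2)
        weights[i, i + pad_f - hw:i + pad_f + hw + 1] = w / w.sum()
    tmp = weights @ padded

    # time direction: exact Gaussian transfer per row, mirrored padding
    pad_t = min(int(np.ceil(truncate * s_t_bins.max())), nt - 1)
    xp = np.pad(tmp, ((0, 0), (pad_t, pad_t)), mode="reflect") if pad_t else tmp
    nfft = next_fast_len(xp.shape[1])
    spec = rfft(xp, nfft, axis=1)
    nu = rfftfreq(nfft, d=1.0)
    spec *= np.exp(-2.0 * np.pi ** 2 * np.outer(s_t_bins ** 2, nu ** 2))
    out = irfft(spec, nfft, axis=1)[:, pad_t:pad_t + nt]
    np.maximum(out, 0.0, out=out)

    return replace(sg, psd=out, smoothed=True)
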