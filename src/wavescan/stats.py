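"""Group statistics: ROC/AUC, Mann-Whitney testing, multiscale Bonferroni
correction, correlations, and the Welch-spectrum baseline comparison.

Orientation convention: patients are the positive class everywhere, so
AUC > 0.5 means the per-subject wave-train rate is higher in patients.

The corrected significance level for a range-scan diagram of resolution R is
the Sidak-form

    alpha_B = 1 - (1 - alpha_0)^(1/C),   C = R (R + 1) / 2,

C being the number of cells in the diagram's upper triangle (diagonal
included).
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .preprocess import SignalRecord

EXACT_MAX_N = 12   # per-group threshold for the exact Mann-Whitney null


def _midrank_u(a: np.ndarray, b: np.ndarray) -> float:
    """Midrank Mann-Whitney U for the first sample (ties get half credit)."""
    n1 = a.size
    ranks = _stats.rankdata(np.concatenate([a, b]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def roc_auc(a, b) -> float:
    """Area under the ROC curve for rates ``a`` (patients, positive class)
    against ``b`` (controls): the fraction of pairs with a_i > b_j, ties
    counting 1/2. Equal to midrank U / (n_a n_b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    return _midrank_u(a, b) / (a.size * b.size)


@lru_cache(maxsize=None)
def _u_counts(m: int, n: int):
    """Number of rank arrangements of m-vs-n samples for each U = 0..m*n."""
    if m == 0 or n == 0:
        return np.ones(1)
    # c(u; m, n) = c(u - n; m-1, n) + c(u; m, n-1)
    with_last = _u_counts(m - 1, n)
    without = _u_counts(m, n - 1)
    out = np.zeros(m * n + 1)
    out[n:n + with_last.size] += with_last
    out[:without.size] += without
    return out


def _exact_two_sided_p(u: float, n1: int, n2: int) -> float:
    counts = _u_counts(n1, n2)
    total = counts.sum()
    u_lo = int(round(min(u, n1 * n2 - u)))
    p = 2.0 * counts[:u_lo + 1].sum() / total   # null is symmetric about n1 n2 / 2
    return min(1.0, p)


def mann_whitney_p(a, b):
    """(midrank U, two-sided p) for a group difference in location.

    Exact null distribution when both groups have <= 12 observations and
    there are no ties (the study's group sizes); otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    u = _midrank_u(a, b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        return u, _exact_two_sided_p(u, n1, n2)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t ** 3 - t).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    d = u - mu
    d -= 0.5 * np.sign(d)       # continuity correction
    z = d / np.sqrt(var)
    return u, min(1.0, 2.0 * _stats.norm.sf(abs(z)))


def correction_count(r: int) -> int:
    """Cells in the upper triangle (diagonal included) at resolution R."""
    if r < 1:
        raise ValueError("resolution must be >= 1")
    return r * (r + 1) // 2


def bonferroni_alpha(alpha0: float, c: int) -> float:
    """Sidak-form corrected level 1 - (1 - alpha0)^(1/C)."""
    if not 0 < alpha0 < 1:
        raise ValueError("alpha0 must be in (0, 1)")
    if c < 1:
        raise ValueError("C must be >= 1")
    return 1.0 - (1.0 - alpha0) ** (1.0 / c)


def correlate(x, y) -> dict:
    """Pearson and Spearman correlation with their two-sided p-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    pr = _stats.pearsonr(x, y)
    sp = _stats.spearmanr(x, y)
    return {"pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
            "spearman_rho": float(sp.statistic), "spearman_p": float(sp.pvalue)}


# ---------------------------------------------------------------------------
# vectorized per-cell helpers used by the diagram builders

def auc_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise midrank AUC of a (n1, m) against b (n2, m)."""
    n1 = a.shape[0]
    n2 = b.shape[0]
    ranks = _stats.rankdata(np.vstack([a, b]), axis=0)
    u = ranks[:n1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n2)


def mwu_p_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise two-sided Mann-Whitney p, matching :func:`mann_whitney_p`
    column by column (exact table for tie-free columns at small n)."""
    n1, m = a.shape
    n2 = b.shape[0]
    n = n1 + n2
    pooled = np.vstack([a, b])
    ranks = _stats.rankdata(pooled, axis=0)
    u = ranks[:n1].sum(axis=0) - n1 * (n1 + 1) / 2.0

    srt = np.sort(pooled, axis=0)
    tied = srt[1:] == srt[:-1]
    # tie correction per column: sum(t^3 - t) over tie groups
    tie_term = np.zeros(m)
    any_ties = tied.any(axis=0)
    for col in np.flatnonzero(any_ties):
        _, t = np.unique(pooled[:, col], return_counts=True)
        tie_term[col] = (t ** 3 - t).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    d = u - n1 * n2 / 2.0
    d = d - 0.5 * np.sign(d)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, d / np.sqrt(var), 0.0)
    p = np.minimum(1.0, 2.0 * _stats.norm.sf(np.abs(z)))
    p[var <= 0] = 1.0

    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N and not any_ties.all():
        counts = _u_counts(n1, n2)
        cdf = np.cumsum(counts) / counts.sum()
        cols = np.flatnonzero(~any_ties)
        u_lo = np.round(np.minimum(u[cols], n1 * n2 - u[cols])).astype(int)
        p[cols] = np.minimum(1.0, 2.0 * cdf[u_lo])
    return p


# ---------------------------------------------------------------------------
# Welch-spectrum baseline comparison

@dataclass(frozen=True)
class WelchComparison:
    freqs: np.ndarray
    psd_a: np.ndarray            # (n_subjects_a, n_bins), patients
    psd_b: np.ndarray
    p: np.ndarray
    alpha0: float
    alpha_corrected: float
    mask_uncorrected: np.ndarray
    mask_corrected: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.freqs.size


def welch_psd(rec: SignalRecord, window_s: float = 10.0, overlap: float = 7 / 8):
    """Per-subject Welch PSD of the envelope (Hann window)."""
    nperseg = int(round(window_s * rec.fs))
    noverlap = int(round(nperseg * overlap))
    return _signal.welch(rec.samples, fs=rec.fs, window="hann",
                         nperseg=nperseg, noverlap=noverlap)


def welch_group_compare(group_a, group_b, window_s: float = 10.0,
                        overlap: float = 7 / 8, fmax: float = 25.0,
                        alpha0: float = 0.05) -> WelchComparison:
    """Per-frequency-bin Mann-Whitney comparison of Welch envelope spectra.

    Bins with 0 < f <= fmax are compared (with a 10 s window this is 250
    bins up to 25 Hz); the corrected mask uses the Sidak-form level with
    C equal to the number of compared bins.
    """

    def stack(recs):
        spectra = []
        freqs = None
        for rec in recs:
            f, p = welch_psd(rec, window_s, overlap)
            freqs = f if freqs is None else freqs
            spectra.append(p)
        return freqs, np.asarray(spectra)

    freqs, psd_a = stack(group_a)
    _, psd_b = stack(group_b)
    keep = (freqs > 0) & (freqs <= fmax + 1e-9)
    freqs = freqs[keep]
    psd_a = psd_a[:, keep]
    psd_b = psd_b[:, keep]
    p = mwu_p_matrix(psd_a, psd_b)
    alpha_b = bonferroni_alpha(alpha0, freqs.size)
    return WelchComparison(freqs=freqs, psd_a=psd_a, psd_b=psd_b, p=p,
                           alpha0=alpha0, alpha_corrected=alpha_b,
                           mask_uncorrected=p <= alpha0,
                           mask_corrected=p <= alpha_b)
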