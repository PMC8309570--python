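# Methods

`wavescan` analyzes surface-EMG recordings as a superposition of *wave
trains*: increases of power spectral density localized in time and
frequency. Instead of classifying individual trains, the method counts them
per subject inside ranges of four train attributes and compares the counts
between groups with rank statistics. This note documents the model, the
numerical choices, and what the synthetic studies do and do not show.

## Preprocessing

Raw EMG (500 Hz in the reference protocol) is conditioned in a fixed order:
zero-phase IIR notches at 50/100/150/200 Hz (Q = 35 per pass, chosen so the
squared forward-backward response is narrower than 1 Hz at 50 Hz; the
acquisition literature gives no Q), a 60–240 Hz fourth-order Butterworth
band-pass applied forward and backward, the Hilbert-transform envelope, and
decimation by 4 (to 125 Hz) behind an 8th-order zero-phase anti-alias
low-pass at 0.8× the target Nyquist. Aliasing protection is standard
practice rather than part of the original acquisition protocol. The decimated envelope is
clipped at zero (an envelope is nonnegative; the anti-alias filter can
undershoot). The first and last second of each record are flagged as edge
transients and excluded from detection and from the rate denominator.

## Time–frequency representation

The analyzing wavelet is the complex Morlet
`psi(x) = (pi Fb)^(-1/2) exp(2i pi Fc x) exp(-x^2/Fb)` with `Fb = Fc = 1`;
the scale at analysis frequency `f` is `a = Fc/f`. Its Gaussian envelope has
`sigma_t(f) = (Fc/f) sqrt(Fb/2)` and `sigma_f = 1/(2 pi sigma_t)`. The
default grid is 0.1–50 Hz in 0.1 Hz steps.

Coefficients are computed by FFT correlation of the **analytic signal**
with the conjugated wavelet (support ±4 sigma). Correlating the real signal
instead leaves its negative-frequency component, whose 2·f0 beat aliases to
`fs − 2 f0` and measurably tilts the ridge of tones near the top of the
grid.

**Calibration.** Power is scaled so a stationary sinusoid of amplitude A µV
reads a peak of A²/2 at every analysis frequency. A per-Hz density
normalization necessarily multiplies the response by a 1/f trend, which
moves the ridge maximum of a pure tone by about `f/(4 pi^2 Fb Fc^2)` — over
1 Hz at 50 Hz — so the flat calibration is used and
`equivalent_noise_bandwidth(f)` converts readings into µV²/Hz densities
when needed. Consequently all absolute power thresholds (e.g. "PSD ≥ 30")
are configuration values in this package's units, not portable constants.

**Adaptive smoothing.** The spectrogram is smoothed with a 2D Gaussian
whose SDs are half the wavelet's own widths at each row's frequency — wide
enough to suppress computation artifacts, narrow enough not to distort the
train shapes ("half the wavelet width" is read as half the SD in each
dimension; the width of a Gaussian window could equally mean FWHM or full
support, and SD is the choice used here). The frequency direction uses per-row kernels truncated at ±3 SD
(assembled into one banded matrix), the time direction the exact Gaussian
transfer function in the Fourier domain; both mirror the boundaries, and
every kernel sums to one, so constant fields are preserved exactly.

A known artifact of any frequency-adaptive smoother is scale-space drift:
because the kernel widens with frequency, a ridge maximum is displaced by
roughly `k k' ≈ 0.013 f` Hz (k = 0.5 sigma_f). Together with the
constant-Q skew of the response this biases measured central frequencies by
about +0.02·f — e.g. +0.3 Hz at 15 Hz — which is documented rather than
corrected: the counting statistics downstream are rank-based and the bias
is identical across subjects, so group comparisons are unaffected.

## Wave-train detection and attributes

Wave trains are strict 8-neighbor local maxima of the smoothed spectrogram
inside the cone of influence (3 sigma_t(f), at least 1 s, from each edge).
Plateaus are not peaks: exact ties have measure zero after smoothing except
in degenerate inputs. Each maximum is measured on two one-dimensional
slices through the peak — the time slice at the central frequency and the
frequency slice at the peak time — as the width of the contiguous region
above half the maximum, with linear interpolation at the crossings:
duration (s and periods = s × f_central) and bandwidth (Hz). A slice that
reaches the record edge still above half-maximum yields rejection code
`EDGE`; one that rises above the peak's own maximum before crossing
(an overlapping train engulfing the peak) yields `ENGULFED` — rejecting
avoids double-counting overlapping trains and unbounded widths measured
across a neighbor's ridge. Trains shorter than 1/10 period at their central
frequency are dropped (durations of exactly 0.1 periods are kept; the rule
says "less than"). In practice the wavelet-plus-smoothing time width alone
measures ≈1.4 periods at half maximum, so this filter almost never binds
for genuine maxima.

For an isolated Gaussian burst every stage is a convolution of Gaussians,
giving the closed-form prediction used throughout the tests
(`studies.expected_halfmax_widths`): with burst amplitude-envelope SD
`s = d/(2 f0 sqrt(ln 2))`,

    FWHM_t = 2 sqrt(2 ln 2) * sqrt((s^2 + sigma_t^2)/2 + (sigma_t/2)^2)

and the analogous expression in frequency with `s_f = 1/(2 pi s)`. Noisy
isolated bursts in the tremor bands (3–12 Hz) are recovered with median
central-frequency error ≈0.15–0.19 Hz and median width errors ≈6 % /
8 % against this prediction.

## Group statistics

Per-subject rates are counts divided by the edge-trimmed record duration
(a single scalar; the per-frequency cone only suppresses edge detections,
symmetrically in both groups). Groups are compared with the area under the
ROC curve, patients as the positive class — `AUC = [#(a>b) + 0.5#(a=b)] /
(n_a n_b)`, identical to the midrank Mann–Whitney U divided by `n_a n_b` —
so AUC > 0.5 means more wave trains in patients. Two-sided p-values use the
exact U null distribution (in-package dynamic-programming recursion,
cross-checked against scipy) when both groups have ≤ 12 tie-free
observations, else the tie- and continuity-corrected normal approximation.

A 2D AUC diagram scans one attribute over all (lower, upper) closed ranges
on a grid (defaults: frequency 1–50 Hz step 1; PSD 0–1000 step 10;
duration 0–10 periods step 0.1; bandwidth 0–50 Hz step 0.1), the other
three attributes fixed by the current constraint box; cells with lower >
upper are undefined (triangular support, diagonal included). The 3D
diagram stacks equal-bin scans over resolutions R = 1..23 (23 is the
reference plateau resolution) and masks cells by the Šidák-form corrected
level `alpha_B = 1 − (1 − alpha_0)^(1/C)`, `C = R(R+1)/2`, the number of
cells at that resolution. The masked stack is exported as data (isosurface
input), not rendered surfaces.

**Refinement.** `refine` formalizes the analyst's exploratory loop: per
iteration all four diagrams are rebuilt under the current box (each
parameter's own diagram is constrained only by the *other* three), the cell
with the largest |AUC − 0.5| is taken (ties: widest range, then smallest
lower bound), and that parameter's bounds are replaced. It stops when the
candidate does not improve the current whole-box score by more than
eps = 0.01 (`no_change`), when it is worse by more than delta = 0.05
(`degraded`, restriction not applied), or at max_iter. eps and delta are
this package's quantification of otherwise qualitative stopping criteria. The
argmax rule is a stand-in for a judgement an analyst makes by eye among
several competing red and blue areas; a different branch is
explored by re-running with a different initial box.

The Welch baseline compares per-subject envelope spectra (Hann window,
10 s, 7/8 overlap) bin by bin with the same test; with 0.1 Hz bins up to
25 Hz that is 250 comparisons and a corrected level of 0.0002.

## Synthetic data

Because the clinical recordings are available only on request, all studies
run on surrogates with known truth. A burst is `A · G(t) · cos(2π f0 t +
φ)` with Gaussian G whose squared-envelope FWHM equals `d/f0` seconds
(Hann optional); onsets are homogeneous Poisson per frequency band,
overlaps allowed; background is additive white Gaussian noise on a positive
baseline, the whole envelope clipped at zero. Between-subject heterogeneity
is modelled by independent unit-mean gamma multipliers per band (CV 0.3 —
without it, 90 s Poisson counts separate 10-vs-12 groups almost perfectly,
unlike any real cohort). Raw-domain surrogates multiply the same modulation
onto a unit-envelope 60–240 Hz noise carrier plus optional 50 Hz mains; the
preprocessed envelope tracks the modulation up to the carrier's
multiplicative Rayleigh noise (correlation ≈0.85–0.90 at high modulation
depth, ≈0.7 at the default depth — an intrinsic ceiling, since the carrier
envelope noise occupies the same 1–45 Hz band as the modulation). All
randomness derives from one integer seed via `SeedSequence` spawn keys.

Reference study conditions: 90 s records, 10 controls vs 12 patients,
shared broadband background trains (1 /s over 1–45 Hz), patient excess in
8–20 Hz (0.9 vs 0.3 /s), lognormal amplitudes and durations; the
discrimination study uses high-amplitude (~20 µV median over 1.5 µV noise),
~1-period bursts. Null calibration studies use event-level cohorts
(Poisson counts, iid attributes, identical distributions in both groups),
since the scan statistics are pure functions of the event table; the
multiscale type-I study uses resolutions 1..12 at 200 replicates.

### What the surrogates reveal (and do not)

Two findings matter for interpreting results on such surrogates:

* **Count saturation.** The method counts *all* smoothed local maxima, and
  a white-ish noise floor contributes a scale-invariant ≈0.15 maxima per
  (Hz·s) regardless of its amplitude. Strong genuine trains absorb or
  engulf nearby floor maxima (≈1–1.5 per train), so unconstrained counts
  respond only weakly — sometimes inversely — to the injected train rate,
  and suppression shows up as *blue* regularities: fewer broadband,
  moderate-bandwidth trains in the group with the stronger band-limited
  activity. A PSD
  floor constraint (typically the refinement's own second step) removes the
  floor counts and restores discrimination (AUC 0.92–1.0 in the reference
  study). Automated argmax refinement may therefore follow the suppression
  regularity rather than the injected band; recovering a specific band can
  require starting the loop from that red area by hand.

* **Multiscale multiplicity.** Each resolution level of the 3D diagram is
  Šidák-controlled at alpha_0 over its own cells, but the stack applies no
  correction *across* resolutions; empirically the family-wise type-I rate
  of a 1..12-level stack on null cohorts is ≈0.08–0.14 at alpha_0 = 0.05,
  damped below the naive 12×0.05 by the strong nesting correlation but not
  to alpha_0. This is inherent to the procedure; scale-space/RFT-style
  corrections are an extension point, not implemented.

Passing tests on these surrogates show the machinery is faithful and
calibrated; they cannot show that real EMG noise floors, inter-subject
variability or disease effects match the generator's assumptions (no
characterization of real background EMG envelope spectra was available, so
the white-noise background is an explicit assumption).

## Numerical notes

Float comparisons in diagram grids use a 1e-9 tolerance so closed-interval
membership is robust to decimal grids. Detection is deterministic given a
record; diagrams and refinement are pure functions of the event table.
Problem sizes in the bundled studies (12 s single-burst records, 90 s
cohort records, 200 null replicates, resolutions 1..12) are the package's
reference conditions and keep a full verification run around two minutes
on one core.
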