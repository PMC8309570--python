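# wavescan

Wave-train electrical-activity analysis of surface-EMG envelopes, with 2D
and 3D AUC range-scan diagrams for group comparison — developed around the
problem of quantifying tremor-related muscle activity in early-stage
Parkinson's disease, where conventional envelope spectra show no group
difference on the clinically unaffected side.

The package treats a biomedical signal as a combination of **wave trains**:
increases of power spectral density localized in time and frequency,
detected as local maxima of an adaptively smoothed complex-Morlet wavelet
spectrogram of the signal envelope,

    psi(x) = (pi Fb)^(-1/2) exp(2i pi Fc x) exp(-x^2 / Fb),  Fb = Fc = 1.

Each train is characterized by four attributes: central frequency f, maximal
power, duration in periods (half-max temporal width × f), and bandwidth
(half-max spectral width). For any attribute range [low, up], per-subject
train rates are compared between groups by the area under the ROC curve,
AUC = U/(n₁n₂) with the midrank Mann–Whitney U and patients as the positive
class. A **2D AUC diagram** tabulates this AUC for every (low, up) cell of a
grid; a **3D AUC diagram** stacks equal-bin diagrams over resolutions R,
keeping only cells significant at the Šidák-form corrected level

    alpha_B = 1 − (1 − alpha_0)^(1/C),   C = R(R+1)/2.

An iterative refinement loop (`refine`) alternates between the four
diagrams, restricting one attribute range per step, until the best
attainable |AUC − 0.5| stops improving. Because the clinical recordings are
not public, a first-class synthetic module generates cohorts of envelope or
raw-EMG records with known ground-truth trains for every study.

See `docs/methods.md` for the model details, numerical choices, and the
limitations of the synthetic studies.

## Worked example

```python
import pandas as pd
import wavescan as ws
from wavescan.detect import events_to_frame

spec = ws.CohortSpec(n_controls=4, n_patients=4, duration_s=60.0, seed=42,
                     amplitude_median=20.0, duration_median_periods=1.0)
cohort = ws.synth_cohort(spec)                      # patients: 3x rate in 8-20 Hz
sets = [ws.detect_wavetrains(rec) for rec in cohort.records]
events = events_to_frame(sets)
roster = pd.DataFrame([{"subject_id": s.subject_id, "group": s.group,
                        "valid_duration_s": s.valid_duration_s} for s in sets])
print(f"{len(events)} wave trains in {len(roster)} subjects")

box = ws.ParameterBox(min_psd=30.0)                 # drop the noise-floor trains
diagram = ws.auc_diagram_2d(events, roster, "frequency", constraints=box)
cell = ws.best_cell(diagram)
print(f"best frequency cell [{cell.lower:.0f}, {cell.upper:.0f}] Hz, "
      f"AUC = {cell.auc:.3f}")

rates = events[(events.f_central_hz.between(8, 20)) & (events.psd_max >= 30)] \
    .groupby("subject_id").size() / 58.0
pat = [rates.get(s, 0.0) for s in roster[roster.group == "patient"].subject_id]
ctl = [rates.get(s, 0.0) for s in roster[roster.group == "control"].subject_id]
u, p = ws.mann_whitney_p(pat, ctl)
print(f"8-20 Hz, PSD>=30: AUC = {ws.roc_auc(pat, ctl):.3f}, U = {u:.0f}, p = {p:.4f}")
print(f"corrected alpha over 250 Welch bins: {ws.bonferroni_alpha(0.05, 250):.6f}")
```

prints

```
1661 wave trains in 8 subjects
best frequency cell [1, 50] Hz, AUC = 1.000
8-20 Hz, PSD>=30: AUC = 1.000, U = 16, p = 0.0286
corrected alpha over 250 Welch bins: 0.000205
```

Reading the output: detection counts *every* local maximum, including the
noise floor's, so the interesting structure appears once a power constraint
is applied. With only 4 subjects per group the injected 8–20 Hz excess
separates the groups perfectly (AUC = 1), and many frequency cells tie at
AUC = 1 — `best_cell` then prefers the widest range, here the full 1–50 Hz.
The exact Mann–Whitney p for the 8–20 Hz, PSD ≥ 30 selection is 0.0286 (U =
16, all four patients above all four controls), and the Šidák-corrected
level for the 250-bin Welch comparison reproduces the familiar 0.0002.

The same pipeline is available from the shell:

```sh
wavescan --seed 7 simulate --out cohort/ --n-controls 10 --n-patients 12
wavescan detect --manifest cohort/manifest.csv --out events.csv
wavescan diagram2d --events events.csv --roster events.roster.csv \
         --parameter frequency --out freq.csv --png freq.png
wavescan refine  --events events.csv --roster events.roster.csv --out refine.jsonl
wavescan diagram3d --events events.csv --roster events.roster.csv \
         --parameter frequency --range 1 10 --out freq3d.csv
```

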