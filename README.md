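# egmkit

Organization indices for multichannel atrial fibrillation (AF) electrograms.

Whether AF terminates acutely during catheter ablation may be predictable
from how *organized* the fibrillatory electrical activity is before
ablation. `egmkit` computes three per-patient organization indices from
long (≈60 s) multichannel unipolar electrogram recordings sampled at 1 kHz
— such as 64-electrode basket-catheter exports — and evaluates how well
each index separates terminating ("Term") from non-terminating ("NonTerm")
patients. It is written for cardiac-electrophysiology researchers who have
a cohort of recordings plus termination labels, and ships a synthetic
electrogram generator so the entire pipeline is testable without clinical
data.

## The indices

For each electrode, the power spectral density P(f) is a Welch periodogram
(4 s Hamming windows, 50% overlap, per-segment mean removal) restricted to
0–20 Hz, and DF is the frequency of its maximum.

* **ADF (average dominant frequency)** — the mean DF over all electrodes;
  a surrogate for the global activation rate (Hz).

* **SPI (spectral power index)** — with threshold fraction α ∈ (0, 1) and
  half-width Δf:

      R     = { f ∈ [0, 20] Hz : P(f) > α·P_DF }
      SPI   = Σ_{f ∈ R, |f−DF| ≤ Δf} P(f)  /  Σ_{f ∈ R} P(f)

  Organized electrograms are sharp periodic deflection trains whose power
  sits partly in harmonics of the activation rate *outside* the DF window,
  giving a low SPI; disorganized signals have one broad peak and SPI ≈ 1.
  (α, Δf) are chosen by a cohort-level grid search maximizing the ROC AUC.

* **EQI (electrogram quality index)** — after a 2.5–30 Hz Butterworth
  band-pass and 55–65 Hz band-stop (all zero-phase, 4th order), the cycle
  period T is estimated from the first non-zero-lag autocorrelation peak,
  the derivative dv/dt is cut into consecutive intervals of width T, and
  each interval i scores

      Q_i = (β − mean(γ_j)) / β

  where β is the interval's dv/dt maximum and γ_j the other positive local
  maxima. A single clean activation peak gives Q_i = 1; two equal peaks
  give Q_i = 0. The channel EQI is the mean Q_i (~300 intervals at 60 s),
  the patient EQI the mean over channels.

Cohort evaluation uses trapezoidal ROC AUC (equal to the pairwise
concordance probability), class-stratified percentile bootstrap CIs
(10 000 replicates), leave-5-out sensitivity analysis (5 000 iterations),
per-group outlier removal (3 SD or 1.5 IQR), Welch t / Wilcoxon rank-sum
group tests, and a single-covariate logistic adjustment check.

## Worked example

```python
import numpy as np
from egmkit import (CohortSimParams, simulate_cohort_recordings,
                    compute_patient_indices, roc_auc, bootstrap_auc_ci)

# 17 organized + 25 disorganized synthetic patients, 16 channels x 60 s
cohort = simulate_cohort_recordings(CohortSimParams(n_channels=16, seed=0))
rows = [compute_patient_indices(rec, label=lab) for _, lab, rec in cohort]
labels = [r.label for r in rows]

eqi = [r.eqi for r in rows]
auc = roc_auc(eqi, labels, "higher_is_term").auc
lo, hi = bootstrap_auc_ci(eqi, labels, "higher_is_term", n_boot=1000, seed=0)
print(f"EQI AUC = {auc:.2f} [{lo:.2f}, {hi:.2f}]")
print(f"mean EQI Term    = {np.mean([r.eqi for r in rows if r.label == 'Term']):.3f}")
print(f"mean EQI NonTerm = {np.mean([r.eqi for r in rows if r.label == 'NonTerm']):.3f}")
```

prints

```
EQI AUC = 1.00 [1.00, 1.00]
mean EQI Term    = 0.893
mean EQI NonTerm = 0.614
```

— the organized (Term) group's clean single-deflection cycles score high
Q_i in nearly every interval, the fractionated disorganized group scores
low, and at these synthetic effect sizes the groups separate completely.
Clinical effect sizes are far smaller; the synthetic cohort checks
direction and machinery, not magnitude.

The same analysis from the shell:

```bash
egmkit simulate --out cohort/ --seed 0
egmkit compute-indices --manifest cohort/manifest.csv --fs 1000 --out results.csv
egmkit grid-search --manifest cohort/manifest.csv --fs 1000 --aggregator mean --out grid.csv
egmkit evaluate --results results.csv --index eqi --n-boot 10000 --seed 0
```

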