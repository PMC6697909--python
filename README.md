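# crackletrack

Acoustic analysis of **fine crackles** — the short, high-pitched
discontinuous lung sounds heard in interstitial lung disease (ILD) — aimed
at a clinical question: can the crackles recorded at the posterior lung
bases tell apart patients **with honeycombing** on high-resolution CT (the
hallmark of established fibrosis / the UIP pattern) from ILD patients
**without** it?

The package implements the full measurement-to-inference chain for
single-channel lung-sound recordings (16-bit PCM WAV, 44.1 kHz, paced
breathing: nominally eight breaths of 2 s inspiration + 2 s expiration,
two posterior-base sites), plus a synthetic-data module so that every
stage is testable without clinical recordings.

## What it computes

**Per crackle** (time-expanded waveform, CORSA conventions): deflections
are excursions between consecutive baseline crossings after the onset;

- **IDW** — initial deflection width (ms),
- **2CD** — two-cycle duration, onset to the end of deflection 4 (ms),
- **LDW** — largest deflection width among deflections 1–4 (ms),
- **A2/A1, A3/A1** — amplitude ratios of the first deflection peaks;
- a **fine crackle** is defined by 2CD < 10 ms.

**Per patient:** the average number of fine crackles per inspiratory
phase (both sites pooled); the onset-timing tercile (early/mid/late third
of the inspiratory phase, from the mean first-crackle relative onset);
the percentile frequencies **F50/F95/F99** of the band-limited
(100–2000 Hz) inspiratory power spectrum — Fq is the frequency below
which q% of total signal power is accumulated; and per-patient medians of
the waveform parameters.

**Cohort inference:** median [IQR] summaries with Mann–Whitney U,
chi-squared contrasts, Gwet's AC1 inter-rater agreement, univariate →
multivariate logistic regression with unit-scaled odds ratios
(OR per 5 crackles, per 100 Hz of F99), correlated-variable pruning
(keeping F99 for the frequency cluster), and ROC analysis with the
upper-left-corner cutoff: the threshold minimizing
√((1−sens)² + (1−spec)²).

Crackle detection correlates the envelope-normalized signal with a bank
of damped-sinusoid templates `s(t) = A sin(2π f₀ t) e^(−t/τ)` spanning the
crackle morphology range and thresholds the normalized correlation
magnitude — see `docs/methods.md` for the design rationale and the
validated operating range.

## Worked example

```python
import numpy as np
from crackletrack import (CrackleSpec, protocol_phases, synth_breath,
                          bandpass, detect_crackles, measure_waveform,
                          roc_analysis)
from crackletrack.synthetic_data import CohortSpec, synth_cohort

# one paced breath with three fine crackles, measured back from the audio
phases = protocol_phases(n_breaths=1, t_insp_s=2.0, t_exp_s=2.0)
crackles = [CrackleSpec(onset_s=t, f0=400.0, tau_s=0.005)
            for t in (0.5, 1.0, 1.5)]
rec, truth = synth_breath(44100.0, phases, crackles, snr_db=20.0, seed=0)
seg = bandpass(rec).samples[:88200]
for onset in detect_crackles(seg, 44100.0):
    ev = measure_waveform(seg, 44100.0, onset)
    print(f"onset {onset*1e3:7.2f} ms  2CD {ev.tcd_ms:.2f} ms  "
          f"IDW {ev.idw_ms:.2f} ms  A2/A1 {ev.a2_a1:.2f}  fine={ev.is_fine}")

# cohort-level discrimination of honeycombing by crackle count
cohort = synth_cohort(CohortSpec(seed=1))
r = roc_analysis(cohort["count_per_insp"],
                 (cohort["group"] == "honeycombing").astype(int))
print(f"count/inspiration: AUC {r.auc:.3f}, cutoff {r.cutoff:.1f} "
      f"(sens {100*r.cutoff_sens:.1f}%, spec {100*r.cutoff_spec:.1f}%)")
```

prints

```
onset  500.05 ms  2CD 4.97 ms  IDW 1.18 ms  A2/A1 0.93  fine=True
onset 1000.00 ms  2CD 4.95 ms  IDW 1.20 ms  A2/A1 0.96  fine=True
onset 1500.02 ms  2CD 4.92 ms  IDW 1.17 ms  A2/A1 0.86  fine=True
count/inspiration: AUC 0.871, cutoff 15.0 (sens 83.3%, spec 80.9%)
```

The three inserted 400 Hz crackles (true 2CD = 5.0 ms, IDW = 1.25 ms) are
recovered at their onsets to within fractions of a millisecond and
classified fine; the 24-vs-47 synthetic cohort — calibrated to the
published group medians and IQRs — separates on the crackle count with
AUC ≈ 0.87 at a cutoff of ≈15 crackles per inspiratory phase.

## Command-line pipeline

```
crackletrack synthesize --seed 1 --out run/synth
crackletrack extract    --audio-dir run/synth --out run/extract
crackletrack analyze    --features run/extract/features.csv --out run/analyze
crackletrack report     --results run/analyze/results.json --out run/report
```

Each stage is deterministic given the config + seed (`--config c.yaml`
overrides defaults; `manifest.json` carries SHA-256 checksums).

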