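# acmkit

Ambulatory circadian monitoring (ACM) analysis for sleep medicine and
chronobiology: from raw wrist-temperature and tilt-accelerometer logs to
non-parametric circadian parameters, the integrated TAP variable, and a
one-decision screening rule for sleep disordered breathing (SDB) status
and CPAP treatment effect.

## Who this is for

Sleep researchers and chronobiologists who record free-living subjects for
a week with two cheap wearables — a wrist skin-temperature (WT) logger
sampling every 10 min and an arm tilt accelerometer sampling every 30 s —
and want reproducible circadian phenotyping plus a simple screening
classifier, without polysomnography.

## The analysis

All channels are averaged onto a common 10-minute grid. Motor activity is
the rate of change of the tilt angle (°/min); body position is the angle
between the device X axis and the horizontal plane (°). WT (inverted),
activity and position are each normalized to [0, 1] per subject and
averaged into TAP, so TAP ≈ 1 means active upright wake and TAP ≈ 0 means
warm, still, horizontal sleep.

For any channel the non-parametric circadian suite is computed:

- **IS** (interdaily stability): `IS = [N·Σ_b (x̄_b − x̄)²] / [p·Σ_i (x_i − x̄)²]`
  over `p` time-of-day bins and `N` samples — 1 iff every day is identical.
- **IV** (intradaily variability): `IV = [N·Σ (x_i − x_{i−1})²] / [(N−1)·Σ (x_i − x̄)²]`,
  with differences never straddling missing bins — near 0 for smooth
  rhythms, near 2 for white noise, up to 4 for strict alternation.
- **M10 / L5** and their timings **TM10 / TL5**: means of the 10 consecutive
  hours of highest and 5 consecutive hours of lowest values of the mean
  daily waveform, searched circularly across midnight.
- **RA** (relative amplitude): `(M10 − L5)/(M10 + L5)`.
- **CFI** (circadian function index): `(IS + (2 − min(IV, 2))/2 + RA)/3 ∈ [0, 1]`.

Screening is a C4.5-style decision stump: one variable, one cut-off chosen
by Shannon information gain, evaluated by sensitivity / specificity /
PPV / NPV / agreement rate and the ROC AUC, under a best-of-100 random
66% train / 34% test protocol, with candidate variables compared by a
paired Wilcoxon signed-rank test across split iterations.

A seeded simulator generates week-long multichannel recordings for
healthy, mild (AHI < 15), moderate (15–30), severe (> 30) and post-CPAP
phenotypes, with jittered nightly sleep windows, Poisson nocturnal arousal
bursts at an AHI-proportional rate, and an inverse circadian WT profile —
so the whole pipeline is testable without clinical data.

## Worked example

```python
import numpy as np
from acmkit import generate_subject, phenotype, summarize
from acmkit.pipeline import PipelineConfig, process_recording

rec = generate_subject(phenotype("severe"), days=7, seed=1)
channels = process_recording(rec, PipelineConfig())
s = summarize(channels["activity"])
print(f"IS={s.IS:.2f} IV={s.IV:.2f} RA={s.RA:.2f} CFI={s.CFI:.2f} "
      f"L5={s.L5:.1f} deg/min at {s.TL5:%H:%M}")
```

prints

```
IS=0.72 IV=0.51 RA=0.59 CFI=0.69 L5=11.2 deg/min at 01:00
```

— a fragmented activity rhythm (elevated IV), substantial nocturnal
movement (L5 ≈ 11 °/min starting at 01:00) and a correspondingly
reduced circadian function index, the signature of severe untreated SDB.
A healthy subject under the same analysis (seed 1) shows IS = 0.82,
L5 = 3.5 °/min and CFI = 0.85.

The same pipeline runs from the shell:

```sh
acmkit simulate --config config.yaml --outdir device_csvs   # device-dialect CSVs
acmkit analyze  --config config.yaml                        # summaries, tables, waveforms, screening
acmkit report   <run_dir>                                   # plain-text digest
```

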