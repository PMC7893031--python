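# cardiomea

Analysis of hiPSC-cardiomyocyte (hiPSC-CM) function and morphology under
**hypoxia–reoxygenation**, built around multi-electrode array (MEA) field
potentials. The package targets in-vitro ischemia–reperfusion experiments:
a cardiomyocyte sheet on an 8×8 MEA (200 µm pitch, corner positions absent,
60 electrodes) is recorded intermittently through a normoxic baseline,
24 h of hypoxia and 24 h of reoxygenation, and its electrophysiology,
morphology and gene expression are quantified.

Because such recordings are rarely public, the package ships a seeded,
ground-truth-annotated **simulator** for every data modality it analyzes —
MEA traces, two-channel fluorescence images, and qPCR Ct tables — so the
entire pipeline is testable by parameter recovery at desk scale.

## What is computed

**Beating frequency.** Beats are detected per electrode (10–2000 Hz
band-pass, threshold of 6 robust SDs, 250 ms refractory floor) and the rate
per 1-min segment is normalized to the electrode's own baseline:

> f̃ₑ(t) = fₑ(t) / median{ fₑ(s) : s ∈ baseline window [−20 h, 0) }

Normalized rates are averaged per electrode within analysis periods
(baseline, 7–15 h hypoxia, 15–24 h hypoxia, 0–6 h and 6–24 h
reoxygenation), then summarized across electrodes as mean ± SD.

**Field-potential landmarks.** Per beat, P1 (sharp first peak), P2 (the
opposite-signed second peak) and the low "flat peak" of repolarization are
located with sub-sample refinement. Depolarization time = t(P2) − t(P1);
field potential duration FPD = t(flat) − t(P1). Both are normalized per
sample to the mean of its own baseline values (fold changes).

**Conduction.** Beats are matched across electrodes within a 50 ms
coincidence window; activation time per electrode is its P1 time. The
conduction statistic is the pooled mean ± SD of |Δt| over all grid-adjacent
(x or y) electrode pairs and all beats of a timepoint, plus activation
heatmaps on a fixed colour scale.

**Morphometry.** Nuclei are segmented with a global two-class Otsu
threshold, distance-transform watershed declumping, equivalent-diameter
gates (50–250 px) and a border filter; areas are reported in µm². Sarcomere
coverage = 100 × (sarcomere-positive area) / (total cell area).

**Statistics / qPCR.** Two-sided Mann–Whitney U and Wilcoxon signed-rank
tests with exact small-sample p values by full enumeration, and comparative
Ct quantification (fold = 2^−ΔΔCt, ΔCt against the mean of the GAPDH /
TBP / EEF1A1 housekeeping panel, calibrated to the control group).

## Worked example

Recover the SLC2A1 (glucose transporter 1) induction after 24 h hypoxia
from a synthetic Ct table:

```bash
python analysis/06_qpcr_expression.py --seed 1
```

```
  group  n      mean       sd
control  6  1.020933 0.207102
hypoxia  5 50.348049 5.163790

programmed folds: {'control': 1.0, 'hypoxia': 48.22}
Mann-Whitney U control vs hypoxia: U=0, p=0.004329 (exact) -- the glucose-transporter
induction under hypoxia is recovered and significant.
```

The generator programmed a true 48.22-fold induction; the ΔΔCt pipeline
recovers a 50.3 ± 5.2 group mean from 5 hypoxia vs 6 control samples
(3 technical replicates each), and the exact Mann–Whitney p of 0.0043 is
the smallest achievable two-sided value for these group sizes, U = 0 being
complete separation.

The other drivers follow the same pattern — each simulates its modality,
runs the full analysis chain and prints recovered vs programmed values:

```bash
python analysis/01_simulate_recording.py   # demo HDF5 recording + pO2 curve
python analysis/02_beat_rate_periods.py    # normalized beat-rate period means
python analysis/03_landmark_folds.py       # depolarization / FPD fold changes
python analysis/04_conduction_lags.py      # adjacent-pair lags + heatmaps
python analysis/05_morphometry.py          # nucleus areas + sarcomere coverage
```

A `cardiomea` CLI (`simulate`, `features`, `conduction`, `morphometry`,
`stats`, `run`) wraps the same library functions for file-based workflows;
`cardiomea run --out-dir out --seed 1` executes all stages and writes a
digest manifest.

## Layout

```
src/cardiomea/    library: simulator, I/O, features, conduction, imaging,
                  stats, qPCR, scenarios, pipeline, CLI
analysis/         numbered narrative drivers writing results/
tests/            pytest suite incl. parameter-recovery acceptance tests
docs/methods.md   models, parameters, numerical choices, limitations
```
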