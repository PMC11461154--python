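# deltasync

Band-limited EEG phase-synchrony analysis for expert/novice cohort designs:
Hilbert-phase phase-locking values (PSV) over fronto-parietal electrode
pairs, a coupled-oscillator cohort simulator, and per-pair split-plot
repeated-measures ANOVA with Greenhouse–Geisser, Bonferroni and
Benjamini–Hochberg control.

## Who this is for

Cognitive-neuroscience groups studying inter-regional functional
connectivity during long naturalistic stimuli (math demonstrations, music,
film) who need a tested, reproducible reimplementation of the classic
Hilbert phase-locking pipeline — and, because such EEG datasets are rarely
public, a statistically faithful synthetic cohort to validate every stage
against.

## The statistic

For two channels with band-limited instantaneous Hilbert phases
φ_a(t), φ_b(t), the phase-locking value over a window W is the mean
resultant length of the phase difference

    PSV = | (1/|W|) Σ_{t ∈ W} exp(i·(φ_a(t) − φ_b(t))) | ∈ [0, 1]

1 means rigid locking at any fixed lag; independent phases give
≈ √π/2·N^(−1/2) for N samples. Two stimulus segmentations are built in:

* **whole_stimuli** — 5-s windows, 50 % overlap, skipping the first 2 s and
  last 1 s of each epoch (a 54-s epoch yields 19 windows over 2–53 s);
* **first_two_seconds** — 0.5-s windows, 50 % overlap, over 250–2000 ms.

Window PSVs are averaged per epoch, epochs per condition, so each
participant contributes one PSV per condition × electrode pair. The default
region of interest is the 12 fronto-parietal electrodes F3, Fz, F4, FCz,
Cz, CP3, CP4, P1, Pz, P2, PPO1, PPO2 → 66 pairs.

Inference per pair is a mixed (split-plot) RM-ANOVA — between-participant
Group (expert/novice), within-participant Posture (sitting/standing) and
Stimulus (symbolic/geometric) — with Greenhouse–Geisser-adjusted p-values,
Bonferroni-protected level contrasts, and BH-FDR across the 66-pair family.

## Worked example

```python
import deltasync as ds

cohort = ds.CohortConfig(n_per_group=8, seed=7)      # 2 × 8 participants
cfg = ds.PipelineConfig(cohort=cohort, seed=7,
                        bands=("delta", "theta", "alpha"))
result = ds.run_pipeline(cfg)

cz = result.psv_table.query(
    "band=='delta' & scheme=='whole_stimuli' & pair_a=='Cz' & pair_b=='Pz'")
print(cz.groupby("group").psv.mean())
print(ds.format_report(result.reports[("delta", "whole_stimuli")],
                       "delta / whole_stimuli"))
```

prints (seed 7; report truncated to its first rows):

```
group
expert    0.449712
novice    0.315612
Name: psv, dtype: float64

delta / whole_stimuli
=====================
CP3-PPO1     group   F(1,14)=10.59  pGG=0.0058  pFDR=0.0476  expert > novice  experts 0.49 (0.09)  novices 0.37 (0.05)  baseline pGG=0.58
Cz-CP3       group   F(1,14)=12.29  pGG=0.0035  pFDR=0.0452  expert > novice  experts 0.48 (0.09)  novices 0.34 (0.07)  baseline pGG=0.52
Cz-Pz        group   F(1,14)=11.72  pGG=0.0041  pFDR=0.0452  expert > novice  experts 0.45 (0.09)  novices 0.32 (0.06)  baseline pGG=0.05
FCz-CP3      group   F(1,14)=32.11  pGG=0.0001  pFDR=0.0038  expert > novice  experts 0.50 (0.04)  novices 0.37 (0.05)  baseline pGG=0.54
```

Math experts show stronger delta-band fronto-parietal synchrony than
novices (cohort means ≈ 0.45 vs 0.32 on Cz–Pz in this small run), the
reported pairs were not different at rest baseline, and the theta/alpha
reports are (essentially) empty — the spatial and spectral pattern the
simulator is calibrated to produce. Each report row gives the split-plot
F for that electrode pair, its Greenhouse–Geisser-adjusted p, the BH-FDR
adjusted p across the 66-pair family, the Bonferroni-protected group
contrast, and group means with standard deviations.

A shell interface wraps the same stages:

```bash
deltasync simulate --config cohort.yaml --seed 7 --out data/   # EDF + CSV + YAML
deltasync run --config pipeline.yaml --out results/
deltasync report --psv results/psv_table.csv --band delta --scheme whole_stimuli
```

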