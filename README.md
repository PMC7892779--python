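# erpstats

Statistical machinery for event-related-potential (ERP) studies on
single-trial EEG: spatio-temporal cluster-based permutation tests,
JZS default-prior Bayes factors, and a data-grounded effect-injection power
simulation — driven by a synthetic multi-subject epoch generator, so the
whole pipeline is testable without access to raw recordings.

## What is in the box

| module | purpose |
| --- | --- |
| `erpstats.montage` | 61-electrode stand-in layout, the six scalp regions (anterior/posterior splits), spatial adjacency graph |
| `erpstats.synth` | synthetic single-trial epoch generator: spatially correlated 1/f + alpha background, injectable ERP-like components (SAN / P600 / P2 presets), the study's 8-condition RSVP design |
| `erpstats.preprocess` | mastoid re-referencing, zero-phase 20 Hz low-pass, baseline correction, Perrin-style spherical-spline channel interpolation, window averaging |
| `erpstats.cluster` | pointwise repeated-measures ANOVA / paired-t maps, spatio-temporal clustering, max-cluster-sum permutation null (default 1,000 permutations), corrected p-values |
| `erpstats.bayes` | JZS t-test Bayes factor (adaptive quadrature) and repeated-measures ANOVA Bayes factor (Monte-Carlo over g-priors; cross-checked against the reference R package) |
| `erpstats.power` | effect-injection simulation: pseudo-condition trial partitioning, data-derived sigma, detection-rate grids over effect size × sample size |
| `erpstats.pipeline` | end-to-end orchestration of the analysis roster + BF suite + power grids, YAML config, deterministic JSON reports |
| `erpstats.brainvision` | optional reader for BrainVision (.vhdr/.vmrk/.eeg) recordings with a TSV event table |

Amplitudes are microvolts everywhere.  Epoch tensors are indexed
`(subject, condition, trial, electrode, time)`.

## CLI

```sh
# write a synthetic epoch set (HDF5)
erpstats simulate --preset demo --seed 1 --out scratch/epochs.h5

# run the evoked comparisons + Bayes-factor suite
erpstats analyze --preset demo --seed 1 --permutations 500 --out scratch/run1

# render the report
erpstats report --report scratch/run1/report.json

# effect-injection power grid
erpstats power --preset demo --component power_san --repetitions 20 --out scratch/power
```

`analyze` and `power` also accept `--config config.yaml`; every field of
`erpstats.pipeline.AnalysisConfig` can be set there (see
`AnalysisConfig.to_dict()` for the schema).  All commands are fully
deterministic given `--seed`.

## Reproducibility notes

- One master seed drives every random stream (noise generation, component
  amplitudes, permutations, trial partitioning, Monte-Carlo integration);
  per-stage substreams are derived with `numpy.random.SeedSequence`.
- The default full-size design (37 subjects × 8 conditions × 48 trials ×
  61 electrodes at 500 Hz) produces a ~9 GB tensor; use the `demo` preset
  or a custom `StudyDesign` for desk-scale work.
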