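# eegdays

Cross-day EEG source tracking: a reusable pipeline that takes multiday,
multichannel EEG recordings of trial-based emotion experiments and asks
which cortical sources — and which of their band-power responses to the
rated emotional conditions — recur from day to day and from subject to
subject. Because suitable public recordings of this kind are scarce, the
package ships a first-class synthetic study generator with full ground
truth (planted dipolar sources, day-to-day presence/absence, calibrated
emotion effects, artifacts), which every stage is validated against.

## Pipeline

1. **`eegdays.synth`** — multiday study generator. Analytic three-shell
   spherical head model (Legendre-series lead fields), a packaged 30-channel
   10–20 montage, dipolar sources with 1/f background plus band-limited
   oscillatory peaks, per-session Bernoulli source presence, blink/EMG
   artifacts, diffuse cortical background, and 5-point valence/arousal
   ratings drawn per emotion quadrant. Planted effects are multiplicative
   band-power changes calibrated by bisection to a requested standardized
   effect size `d`. Deterministic given `(seed, subject, session)`.
2. **`eegdays.preprocess`** — zero-phase Butterworth band-pass (1–50 Hz)
   and artifact subspace reconstruction: principal axes and per-axis
   `mean + 5·SD` RMS thresholds from the cleanest calibration windows;
   sliding half-second windows whose offending axes are shrunk back to
   threshold, raised-cosine overlap-add.
3. **`eegdays.decompose`** — extended-infomax ICA (square, seeded,
   kurtosis-sign switching, annealed natural-gradient updates) and
   automated screening: dipolarity > 85 %, within-brain dipole, and
   blink/EMG spectral-profile rules.
4. **`eegdays.dipoles`** — single equivalent-dipole fits of IC scalp maps:
   linear least-squares moment at each location, coarse-grid seeding plus
   simplex refinement, residual variance / dipolarity, within-brain flag.
   A brute-force grid oracle (`grid_search_rv`) is kept for verification.
5. **`eegdays.tracking`** — per-subject k-means clustering of screened ICs
   on standardized (PSD, scalp map, dipole location) features, 3-SD outlier
   relocation, reproducibility (% of sessions a cluster appears in), greedy
   cross-subject matching, and inter-subject commonality at an N-of-8-days
   criterion.
6. **`eegdays.bandpower`** — STFT (2-s Hamming window, 50 % overlap, dB),
   five-band grouping (delta 1–3, theta 4–7, alpha 8–13, beta 14–30,
   gamma 31–50 Hz), and per-trial z-normalization against the trial's own
   preceding rest phase.
7. **`eegdays.stats`** — rating dichotomization at the scale midpoint,
   imbalanced-subject exclusion, pooled-variance unpaired t-tests,
   label-permutation tests (n = 20 000 by default, add-one estimator),
   rating regression, and the cross-subject tendency-commonality table.
8. **`eegdays.workbench`** — EDF + sidecar-TSV session I/O, an HDF5 session
   container, TOML configuration with per-stage seed derivation, report
   schemas, pipeline orchestration with a checksummed run manifest, and the
   CLI.

## CLI

```sh
eegdays simulate --seed 1 --out runs/demo        # EDF + events + ground truth
eegdays all      --seed 1 --out runs/demo        # full pipeline + reports
eegdays all --config my.toml                     # override any stage default
```

Subcommands: `simulate`, `preprocess`, `decompose`, `cluster`, `power`,
`stats`, `all`; each accepts `--config`, `--seed`, `--out`, `--log-level`.
`runs/<out>` receives cluster reports (JSON), the commonality table (TSV),
per-subject statistics (JSON), long-format band-power tables (TSV), and a
manifest whose checksums reproduce exactly on re-run.

## Notes

- Coordinates are package-internal head-frame millimetres on the spherical
  model; no atlas registration is attempted.
- Everything is deterministic from the configuration: one global seed
  derives all stage seeds (`RunConfig.stage_seed`, SHA-256 based).
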