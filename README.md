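# scalerp

Unmixing **fixed-time** and **scaled-time** components in continuous scalp
EEG with a convolutional GLM.

Conventional event-related averaging assumes every neural response occupies a
fixed wall-clock window around an event. `scalerp` additionally models a
single response that is *stretched or compressed* to span the variable
interval between two events (e.g. cue → response): the design matrix combines
fixed-lag stick-function blocks with one shared scaled-time basis whose
temporal support is resampled per trial with an area-averaging box kernel.
Estimation is penalized least squares with a first-derivative (smoothness)
Tikhonov penalty and cross-validated regularization weight.

The package also ships the validation machinery around the estimator:

- `scalerp.simulate` — synthetic continuous EEG with exact per-component
  ground truth (cue transient + response transient + one scaled template,
  AR(1) or white noise, seeded).
- `scalerp.design` — design-matrix construction, box-kernel resampling
  (`resize_box`), moving-window peak-to-peak artifact flagging,
  response-time-based trial exclusion, and row bookkeeping for masked samples.
- `scalerp.solver` — the penalized solver, k-fold cross-validation of the
  penalty weight on a target channel, and full vs fixed-only model comparison.
- `scalerp.epochs` — conventional ERP epoching, baselining, threshold
  rejection, condition averages, and ragged variable-duration interval epochs.
- `scalerp.metrics` — VIF collinearity profiles, fixed-only / scaled-only
  dataset reconstruction, and the scaling index (post-stretch coefficient of
  determination between condition means).
- `scalerp.stats` — spatiotemporal cluster-based permutation test with a
  participant sign-flip null, paired t with Cohen's d, PCA latency analysis
  (PC2 as a latency index), and one-way repeated-measures ANOVA with
  partial/generalized eta squared.
- `scalerp.io` / `scalerp.cli` — native interchange (`.npy` matrix + JSON
  sidecar, BIDS-style events TSV), run configuration snapshots, and the CLI.

## Command-line usage

```bash
# simulate a ground-truth dataset (150 trials, 3 interval conditions)
scalerp simulate --seed 7 --out sim/

# fit the GLM with cross-validated regularization
scalerp fit --recording sim/recording --events sim/events.tsv --cv --out fit/

# collinearity diagnostics, scaling index, model comparison
scalerp vif            --recording sim/recording --events sim/events.tsv --out vif/
scalerp scaling-index  --recording sim/recording --events sim/events.tsv --out si/
scalerp compare-models --recording sim/recording --events sim/events.tsv --out cmp/

# group-level statistics on saved waveform arrays (.npy)
scalerp cluster-test --waveforms waves.npy --electrodes Fz,FCz,Cz --out cl/
scalerp pca-latency  --waveforms bins.npy --out pca/
```

Every command accepts `--config <json>` (a `RunConfig` snapshot; defaults
match the production-task analysis: 200 Hz, (−200, 800) ms cue and
(−800, 200) ms response windows, 330 scaled points, 9-value lambda grid,
10-fold CV) and writes its exact config snapshot and a run log next to its
outputs.

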