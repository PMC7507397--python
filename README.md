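# dyadsync

Simulation and analysis of dyadic cooperative-task behavior and two-brain
optical (fNIRS-style) recordings.

The package implements, end to end on synthetic data:

1. **Task simulator** (`dyadsync.task_model`) — a two-player keystroke task
   where a dyad wins a trial when the absolute response-time difference
   (RTD) stays within the trial threshold `T = (RT1 + RT2) / 8`.  Three
   strategy modes (delayed / immediate / no-strategy) with calibrated group
   structure, plus the behavioral metrics: winning ratio (WR), mean RTD,
   mean threshold, and the cooperation coefficient
   `CC = mean threshold − mean RTD`.
2. **Signal synthesis** (`dyadsync.signal_synthesis`) — a forward generator
   for two-participant, 22-channel, 10 Hz optical recordings over the
   rest/task/rest/task/rest block design: physiological noise (1/f drift,
   quasi-periodic cardiac / respiratory / Mayer components, white noise), a
   strategy-dependent shared narrowband oscillation on designated channels
   during task blocks (optionally lagged between partners), motion
   artifacts, and the modified Beer–Lambert forward model down to raw
   intensity.  Ground truth is retained for oracle-style testing.
3. **Preprocessing** (`dyadsync.preprocessing`) — channel quality screening
   (mean/SD < 2 marks a channel missing), optical-density conversion,
   moving-window motion-artifact detection with cubic-spline correction,
   and the Beer–Lambert inversion to HbO/HbR.  No band-pass filtering.
4. **Wavelet coherence** (`dyadsync.coherence`) — Morlet continuous wavelet
   transform, smoothed squared wavelet coherence, cone-of-influence
   handling, band-averaged (3.2–12.8 s period) coherence per timeline
   segment, and the synchronization contrast
   `IBS = mean task coherence − mean rest-interval coherence` (raw and
   Fisher-Z).
5. **Granger causality** (`dyadsync.causality`) — bivariate time-domain
   VAR causality in both directions with BIC order selection,
   block-boundary-respecting lags, and cohort-level one-sample / paired
   tests.
6. **Statistics** (`dyadsync.stats`) — one-tailed/two-tailed t tests,
   one-way ANOVA with partial eta squared and Tukey HSD,
   Benjamini–Hochberg FDR, Pearson correlation.
7. **Pipeline + CLI** (`dyadsync.pipeline`, `dyadsync.cli`) — a seeded,
   config-driven end-to-end run producing behavior tables, per-channel
   synchronization tables, group statistics, and the directional analysis
   at the FDR-flagged channel.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (Monte-Carlo
calibration and power checks; a few minutes of CPU).  The naive reference
implementations (loop-based wavelet coherence, literal BH step-up, normal
equation Granger regression) live in `tests/_reference.py`.

## CLI

```bash
dyadsync full-run --config config.yaml --seed 1 --out results/run1
```

Stage-by-stage commands: `simulate-behavior`, `simulate-signals`,
`preprocess`, `ibs`, `gca`, `stats` — each takes `--config`, `--out`, and
(where relevant) `--seed`.  Recordings are written either as a documented
wide-TSV dialect or as SNIRF (one file per participant); event tables are
BIDS-style `events.tsv`.  Exit codes: 0 ok, 1 validation/config error,
2 runtime error.

A YAML config mirrors the defaults (all keys optional, unknown keys
rejected):

```yaml
master_seed: 1
task:
  group_sizes: {delayed: 17, immediate: 16, none: 10}
coupling:
  coupled_channels: [19]
  strength_by_strategy: {delayed: 1.5, immediate: 0.0, none: 0.5}
band: {period_lo: 3.2, period_hi: 12.8}
stats: {fdr_q: 0.05}
```

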