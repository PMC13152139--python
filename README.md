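# ecogonset

Sensorimotor ECoG band-power onset-latency analysis: a tested pipeline that
takes continuous multichannel recordings from trial alignment through
adaptive-threshold neural-onset detection to region-level (M1 vs S1) group
statistics, driven by a synthetic-data generator with known ground truth.

## What it does

1. **synth** — generates ECoG-like recordings: 1/f background, optional
   50 Hz line noise, a continuous 8–30 Hz rhythm whose amplitude drops
   around movement, and a broadband 60–100 Hz component whose amplitude
   rises, with programmable per-channel onset lags, per-trial reaction-time
   jitter, bad channels, and dataglove traces. Ground truth (true movement
   times, true per-channel onsets) is returned alongside.
2. **preprocess** — variance-based bad-channel screening, common-average
   referencing, zero-phase equalizing filters (0.15–134 Hz band-pass,
   50 Hz notch), epoching to [−1, 2] s around per-trial markers, and
   manual + amplitude-based trial rejection.
3. **align** — per-trial movement markers: MOM (derivative-of-Gaussian
   deflection detection on glove traces) for executed movement, GSM
   (slope-segment matching on the mean high-frequency band response) when
   no movement trace exists.
4. **spectral** — Morlet wavelet power (width 7, gwidth 3, 1 Hz bins) and
   band averaging for alpha (8–12), beta (13–30), LFB (8–30) and HFB
   (60–100 Hz), with per-participant band overrides. Wavelet edge samples
   are invalidated (NaN) and excluded from every downstream statistic.
5. **select** — per-channel one-sided paired t-tests of post- vs
   pre-marker band power (direction per band, no multiple-comparison
   correction), signed-r² maps against the task design, and the analysis
   filter (significant ∧ hand region ∧ M1/S1).
6. **onset** — the core: 0.5 s trial smoothing, trial-mean z-scoring with
   baseline correction, two-phase adaptive threshold optimization
   (start ±0.4, step 0.1, window [−0.5, 0.5] s) and first-crossing onset
   detection, plus the permissive (phase-1-only) variant.
7. **groupstats** — per-participant/finger region means, two-within-factor
   repeated-measures ANOVA (region × finger, participant as grouping
   factor; mixed-model route behind a flag) with Tukey-adjusted marginal
   contrasts, per-participant Welch tests with Bonferroni correction,
   earliest-quartile percentages and earliest-channel summaries.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (end-to-end onset
recovery over a 50-seed synthetic cohort, threshold-optimizer oracle
equivalence, GSM alignment recovery, significance-stage calibration,
deterministic micro-fixtures, and threshold-variant robustness); it takes a
few minutes. Everything else runs in seconds.

## CLI

Each stage is a subcommand; files (HDF5 for signals/power, CSV for events
and tables) are the interface between stages:

```sh
ecogonset synth --config cfg.yaml --out-dir run/
ecogonset align mom --glove run/glove.h5 --events run/events.csv --out run/events_mom.csv
ecogonset preprocess --recording run/recording.h5 --events run/events_mom.csv \
    --band 0.15:134 --notch-hz 50 --window -1:2 --out run/trials.h5
ecogonset spectral --trials run/trials.h5 --bands alpha,beta,lfb,hfb \
    --overrides bands.yaml --out-dir run/
ecogonset select --power run/power_hfb.h5 --pre -1:-0.5 --post 0:0.5 --out run/stats_hfb.csv
ecogonset onset --power run/power_hfb.h5 --stats run/stats_hfb.csv \
    --mode full --window -0.5:0.5 --start 0.4 --step 0.1 --out run/onsets_hfb.csv
ecogonset groupstats --onsets cohort_onsets.csv --band hfb --out-dir results/
```

For GSM alignment, epoch on the cue first (`marker_time_s = cue_time_s`),
compute HFB power, then `ecogonset align gsm --power ... --events ... --out ...`.

`bands.yaml` maps band names to edges, e.g. `hfb: [30, 100]` for a
participant with a wider gamma response.

## Python API sketch

```python
from ecogonset import pipeline
from ecogonset.data import DEFAULT_BANDS

cfg = pipeline.make_participant_config(seed=0, region_lag_s=0.1)
res = pipeline.run_participant(cfg, band=DEFAULT_BANDS["hfb"])
print(res.onsets.groupby(["finger", "region"])["onset_s"].mean())
```
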