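# neurodyad

Frontal alpha-asymmetry analysis of infant EEG recorded during a structured
mother–infant multisensory interaction, together with a synthetic session
generator that makes the whole chain testable end to end without any
recorded data.

The paradigm is 4 scripted maternal actions of 10 s each (15-s pauses),
cycled 2 trials × 2 runs (2-min inter-run break), so every action has 4
iterations. The analysis chain is:

1. **Preprocess** — 60 Hz notch, order-1 Butterworth 0.3–40 Hz bandpass
   (both zero-phase), bad-channel detection (flat or extreme), neighbor-mean
   interpolation (≤35 bad channels, more excludes the segment), average
   re-reference, segmentation into 10-s action epochs, masking of samples
   exceeding 120 µV (±100 ms guard).
2. **Envelope** — order-4 Butterworth 6–9 Hz (infant alpha), 7-channel
   cluster means around the left/right frontal sites, Hilbert envelopes, and
   alpha-band global field power (per-sample SD across channels).
3. **Align** — per action, the 4 iterations are aligned by normalized
   cross-correlation of the (smoothed) alpha GFP (±2000 ms search); the
   response window [2000 ms + lag, 7000 ms + lag) is averaged per side, then
   across iterations (≥2 required).
4. **FAS** — frontal asymmetry score `(L − R) / (L + R)` on the mean
   envelope amplitudes, per action; action 1 is the baseline and is
   subtracted from actions 2–4 (3 values per infant).
5. **Behavior** — 3-domain behavioral codes (1/2/3; sensitivity 0 when
   drowsy) averaged over iterations with inconsolable iterations dropped;
   dyad classifications (irritability, bondedness, depression screen).
6. **Stats** — pooled Pearson trends across actions, group × action OLS
   interaction tests (effect size = signed √ partial R²), and descriptive
   grand-average correlations over the 4 action-level cohort means.

The synthetic generator injects Hann-windowed alpha bursts with a controlled
left/right amplitude asymmetry (the injected value equals the noise-free
FAS), per-iteration onset jitter, blink-like >120 µV artifacts, flat/railed
channels, and behavioral codes from an ordered-categorical model with a
controllable per-action trend — all reproducible from a single seed.

## CLI

```sh
# one synthetic session (EEG as HDF5 + events/WECS/metadata CSV + truth JSON)
neurodyad simulate --config sim.yaml --out session/ --seed 1

# per-action FAS from a recording + event schedule
neurodyad fas --recording session/recording.h5 --events session/events.csv --out fasout/

# behavioral aggregation / statistics from tables
neurodyad behavior --wecs wecs.csv --meta meta.csv --out behav/
neurodyad stats --fas fas.csv --wecs wecs_aggregated.csv --meta metadata.csv --out stats/

# simulate a cohort and run everything
neurodyad run-all --out cohort/ --seed 1 --n-infants 10 --irritable-fraction 0.5
```

A YAML config may set simulation parameters under `sim:`, analysis
thresholds under `analysis:` (all default to the protocol values: 120 µV,
35 electrodes, 2000 ms delay, 5000 ms window, 6–9 Hz, order-1 0.3–40 Hz,
60 Hz notch), and a `montage:` path. CLI flags override the config; every
run writes its resolved config and a per-stage exclusion report.

## Notes

- Sign convention: positive FAS = left-lateralized alpha envelope. The
  common inverse-activity interpretation of alpha is *not* applied.
- Monte-Carlo validation suites (ground-truth recovery, statistical
  calibration) run on a reduced 48-channel / 250 Hz configuration for
  runtime; all analysis thresholds are identical to the full-size setup.
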