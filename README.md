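# somnapose

Posture-based sleep monitoring from ambulatory accelerometry.

`somnapose` turns a night of four-channel acceleration data — a triaxial
sensor on the sternum (vertical, antero-posterior, medio-lateral axes) and a
single-axis sensor on the right thigh (antero-posterior), in units of g,
sampled at 64 Hz — into objective indicators of sleep duration and sleep
quality:

1. **Gravity/dynamic separation** — per-channel median and SD in 5-s
   windows; the median is the gravity estimate, and the mean magnitude of
   the median-subtracted samples is the dynamic-activity score.
2. **Posture tree** — a two-split hierarchy on window medians: lying when
   the vertical-axis gravity magnitude is below 0.66 g, otherwise sitting
   when the thigh axis exceeds 0.5 g, else standing/walking. Thresholds can
   be refit from a labeled calibration recording by 10-fold
   cross-validation (`fit_thresholds`, `somnapose calibrate`).
3. **Orientation segmentation** — during lying, the torso rotation angle
   (0° ventral, +90° right, ±180° dorsal, −90° left) is tracked per window
   and segmented adaptively: a boundary is set only when the angle leaves
   the sliding circular mean of the recent trace by more than 30°, so
   jitter around a fixed category boundary never splits a segment.
4. **Night indices** — time supine (≥ 50-s lying runs), total sleep time
   (supine with activity < 0.15 g), still-position latency (first ≥ 3-min
   still run), rises, posture changes per hour, mean posture duration,
   postures > 15 min, per-posture time fractions, and turning-based sleep
   efficiency, all restricted to the 20:00–10:00 night window.
5. **Simulator** — scenario-driven synthetic calibration protocols and full
   nights with analytically derived ground truth (gravity projection per
   posture, smooth turn transitions, deterministic movement bursts,
   seeded sensor noise), used for end-to-end recovery testing.

## CLI

```bash
# synthesize a night (recording.csv, ground_truth.json, scenario.yaml)
somnapose simulate --seed 7 --out-dir night/

# full night summary (all indices, thresholds embedded for provenance)
somnapose summarize night/recording.csv --out summary.json

# per-window features + postures and the supine segment table
somnapose classify night/recording.csv --out-dir out/

# refit tree thresholds from a labeled calibration recording
somnapose calibrate protocol.csv labels.csv --folds 10 --seed 1
```

Recordings are CSV channel tables: `#`-prefixed `key=value` metadata lines
(`subject_id`, `start_time`, `sampling_rate`), a header row naming
`sternum_vertical,sternum_ap,sternum_lat,thigh_ap`, then one sample per
row in g. Readers validate finiteness, range (|value| ≤ 16 g), and channel
presence, and never rescale silently (`unit="ms2"` converts explicitly).

## Notes

- Activity is computed on median-subtracted (dynamic) values; raw values
  would read ≈ 1 g at rest and would make the 0.15 g stillness threshold
  meaningless.
- The lying rule uses the *magnitude* of the vertical gravity median, which
  is correct for either mounting polarity of the sternum sensor; a signed
  convention can be pinned via `Thresholds(vertical_sign=...)`.
- Windows tile the recording (step = window) by default; a sliding variant
  is available via `step_s`.
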