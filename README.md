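# sitpress

Detection of compensatory trunk/shoulder motions during seated reaching
from seat-pressure-map streams.

A pressure mattress on the seat records 32×32 sensor grids at 50 Hz.
From each window of frames, ten features are computed — mean and peak
sensor value, mean/SD of the medial-lateral and anterior-posterior
centre of pressure, and mean/SD of the left/right and front/back
half-grid load ratios.  An RBF-kernel SVM classifies windows into four
motion classes (NC noncompensation, TR trunk rotation, TLF trunk
lean-forward, SE shoulder elevation), evaluated offline with
leave-one-subject-out (LOSO) cross-validation and deployed online with
a sliding-window streaming detector that emits debounced compensation
events as newline-delimited JSON.

Because no recorded patient data ships with this package, a synthetic
seated-pressure simulator generates labelled trials with per-class
pressure signatures, per-subject variability, task-dependent reach
cycles and sensor noise.  Every downstream stage is developed and
benchmarked against it.  The simulator's compensation signatures (and
in particular the shoulder-elevation signature) are modelling
assumptions, not measurements.

## Modules

| module               | role |
|----------------------|------|
| `sitpress.io`        | plain-text trial dialect, frame/trial types, manifests |
| `sitpress.simulate`  | synthetic cohort generator (config: `src/sitpress/defaults.yaml`) |
| `sitpress.features`  | the ten window-level features |
| `sitpress.classify`  | min-max normalisation, RBF-SVM + inner 5-fold grid search, LOSO, confusion-matrix metrics |
| `sitpress.online`    | sliding-window streaming detector, event debouncing, feedback emission |
| `sitpress.cli`       | `sitpress` command-line workbench |

## CLI

```sh
sitpress simulate --subjects 4 --reps 3 --seed 0 --out-dir data/
sitpress extract  --manifest data/manifest.csv --out features.csv
sitpress train    --features features.csv --out model.joblib
sitpress loso     --features features.csv --out-dir reports/
sitpress detect   --model model.joblib --trial data/S01_back_and_forth_TLF_006.txt \
                  --out events.jsonl --trace trace.csv
sitpress benchmark --subjects 4 --reps 3 --holdout 1 --seed 0 --out-dir bench/
```

`detect` and `benchmark` accept `--window/--stride/--smooth/--debounce`
(defaults 50/10/5/3 frames) and an optional `--sink`
(file path or `tcp://host:port`) for live event delivery.  Event schema,
one JSON object per line:

```json
{"comp_class": "TLF", "onset_time": 4.18, "offset_time": 7.90, "peak_confidence": 1.0}
```

## Trial file format

Plain text, diff-able and lossless: a `key: value` metadata header
(`subject_id`, `task`, `label`, `sample_rate`, `affected_side`),
followed by one block per frame — 32 lines of 32 whitespace-separated
decimal values — separated by blank lines.  This dialect is a documented
stand-in; it is not the vendor export format of any particular pressure
measurement system.  Row 0 is the anterior (front) edge of the seat,
column 0 the sitter's left.  Timestamps are reconstructed as
`index / sample_rate`.

## Notes

- Frames from left-affected subjects are column-mirrored before feature
  extraction so that medial/lateral features are pose-invariant when
  pooling subjects; disable with `--no-mirror` / `mirror=False`.
- The hyperparameter search uses a powers-of-two grid over
  C ∈ [2⁻³, 2⁷] and gamma ∈ [2⁻⁷, 2³] (exponent step 2 by default) with
  an inner stratified 5-fold cross-validation maximising macro-F1.
- Streaming models should be trained on window-level features
  (`features.window_feature_table`) so the training distribution matches
  the windows scored online; trial-level features are for offline LOSO.
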