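# qsarlab

A QSAR model life-cycle toolkit: build, validate, predict, retrain and
version PLS-based structure–activity models from SDF training series,
with applicability-domain reliability categories and a confidential
coefficient-only model export.

## Features

- **SDF in, SDF/CSV out** — V2000 SDFiles with an embedded activity data
  field (default name `activity`) are the only training input; prediction
  output is CSV or SDF with the predicted value, AD category and 95% CI
  half-width written into each record.
- **In-house multivariate engine** — NIPALS PCA and PLS1 (regression and
  discriminant modes), per-dimensionality r²/q²/SDEC/SDEP,
  leave-one-out cross-validation (vectorized over folds), automatic
  class-cutoff estimation balancing sensitivity and specificity.
- **FFD variable selection** — a two-level design with dummy variables
  estimates each descriptor's effect on cross-validated error; variables
  that demonstrably hurt are pruned, and the reduction is kept only if q²
  does not decrease.
- **Applicability domain** — six training-derived criteria, each
  thresholded at its 95th percentile; the violation count (0–6) is the
  reliability category, mapped to an empirical 95% CI half-width.
  *Note: the six-criterion scheme is a documented reconstruction at the
  granularity of the published ADAN approach (six criteria, categories
  0–6, 95th-percentile thresholds); the original formulas were not
  published in the source this package follows.*
- **Versioned model store** — one directory tree per tag; version 0 is
  the development sandbox, publication copies it to the next sequential
  number; versions are listable, removable, exportable and reimportable,
  and removed numbers are never reused so historical predictions stay
  reproducible bit-for-bit.
- **Confidential mode** — a model can be exported as a plain-text file
  holding only scalar header values and one `(mean, scale, coefficient)`
  record per retained descriptor variable: nothing in the file derives
  from, or scales with, individual training compounds. Predictions from
  the confidential file equal the full model's to 1e-10.
- **Stage overrides** — the four workflow stages (`normalize`,
  `extract`, `build`, `predict`) can be replaced per model tag while the
  rest of the machinery (versioning, AD, services) is inherited
  unchanged; external SDF-in/SDF-out tools can be wrapped as overrides.
- **CLI + HTTP service** — one executable with `build`, `predict`,
  `manage` and `serve` subcommands; `serve` exposes published models as
  a JSON-over-HTTP endpoint (stdlib only).

## Quick start

```bash
# build a sandbox model (version 0) from an SDF with an "activity" field
qsarlab build -e MYTAG -v 0 -f training.sdf --root ./models

# publish it as version 1
qsarlab manage -e MYTAG --publish --root ./models

# predict a query file (CSV or SDF output, by suffix)
qsarlab predict -e MYTAG -v 1 -f query.sdf -o predictions.csv --root ./models

# list versions / export / confidential export
qsarlab manage -e MYTAG --list --root ./models
qsarlab manage -e MYTAG --export 1 -o mytag-v1.zip --root ./models
qsarlab manage -e MYTAG --export-confidential 1 -o mytag-conf.txt --root ./models

# serve published models over HTTP
qsarlab serve --port 8220 --root ./models
# GET  /models            -> published version metadata
# POST /predict           -> {"tag": ..., "version": ..., "sdf": "<text>"}
```

Per-model settings live in a flat `key=value` config file (scaling mode,
embedded SDF fields used as extra variables, FFD on/off, qualitative
label mapping, …):

```bash
qsarlab build -e MYTAG -v 0 -f training.sdf --config model.cfg
```

From Python:

```python
from qsarlab import build_workflow, predict_workflow, publish

report = build_workflow("./models", "MYTAG", "training.sdf")
print(report.quality_table())
publish("./models", "MYTAG")
results = predict_workflow("./models", "MYTAG", 1, "query.sdf")
```

## Tests

```bash
python -m pytest -q tests/
```

The suite is self-contained: the `qsarlab.synth` module generates toy
SDF molecule sets (valence-legal random trees with activities computed
from the built-in descriptors) and latent-structure matrices, so no
external data or binaries are needed. `tests/test_acceptance.py` holds
one test per acceptance criterion (oracle equivalences, ground-truth
simulations, life-cycle round trips).

## Notes

- Descriptors: a built-in 2D block (element/bond/ring counts, H-bond
  donors/acceptors, molecular weight, first Zagreb index, Wiener index)
  keeps the package self-contained; external descriptor engines can be
  plugged in via the `extract` stage override, keyed by
  `descriptor_set_id`.
- Normalization: largest-covalent-fragment keep + explicit-H removal +
  canonical structure key. Ionization adjustment and 2D→3D conversion
  are not implemented natively; wrap licensed tools as `normalize`
  stage overrides.
- V3000 SDFiles are rejected; V2000 only.
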