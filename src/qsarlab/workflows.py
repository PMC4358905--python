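"""Build / predict / retrain workflows and the stage-override registry.

Both workflows share the same normalize and extract stage
implementations, so a query compound is guaranteed to be processed
exactly as the training series was.  Any of the four named stages
(normalize, extract, build, predict) can be overridden per tag while the
remaining stages keep their built-in behavior; a model built or
predicted through an override is marked "custom" in its metadata.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from . import adan as adan_mod
from . import chem_io, descriptors, store
from .chem_io import NormalizationSettings, TrainingSeries
from .ffd import FFDResult, ffd_select
from .mva import PLSModel, build_pls_model, transform_scores

__all__ = [
    "BuildConfig",
    "BuildReport",
    "PredictionResult",
    "register_stage",
    "unregister_stage",
    "resolve_stage",
    "registered_stages",
    "build_workflow",
    "predict_workflow",
    "retrain",
    "external_sdf_stage",
]

STAGES = ("normalize", "extract", "build", "predict")
VARIANCE_EPS = 1e-12


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class BuildConfig:
    activity_field: str = "activity"
    activity_type: str = "quantitative"  # or "qualitative"
    label_map: dict = dc_field(default_factory=lambda: {"0": 0, "1": 1})
    strip_salts: bool = True
    remove_hs: bool = True
    descriptor_set_id: str = descriptors.BUILTIN_SET_ID
    embedded_fields: list = dc_field(default_factory=list)
    scaling: str = "autoscale"
    A_max: Optional[int] = None
    ffd_enabled: bool = False
    ffd_threshold: float = 2.0
    ffd_dummies: Optional[int] = None
    ffd_runs: Optional[int] = None
    detect_training_copy: bool = True
    k_nn: int = 5
    seed: int = 0

    _BOOL = {"strip_salts", "remove_hs", "ffd_enabled", "detect_training_copy"}
    _INT = {"A_max", "ffd_dummies", "ffd_runs", "k_nn", "seed"}
    _FLOAT = {"ffd_threshold"}

    def normalization(self) -> NormalizationSettings:
        return NormalizationSettings(strip_salts=self.strip_salts, remove_hs=self.remove_hs)

    def to_text(self) -> str:
        lines = []
        for key in ("activity_field", "activity_type", "strip_salts", "remove_hs",
                    "descriptor_set_id", "scaling", "A_max", "ffd_enabled",
                    "ffd_threshold", "ffd_dummies", "ffd_runs",
                    "detect_training_copy", "k_nn", "seed"):
            val = getattr(self, key)
            lines.append(f"{key}={'' if val is None else val}")
        lines.append("embedded_fields=" + ",".join(self.embedded_fields))
        lines.append("label_map=" + ",".join(f"{k}:{v}" for k, v in self.label_map.items()))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "BuildConfig":
        cfg = cls()
        known = set(cfg.__dataclass_fields__) - {"label_map", "embedded_fields"}
        for ln, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {ln}: expected key=value, got {line!r}")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key == "embedded_fields":
                cfg.embedded_fields = [f for f in raw.split(",") if f]
            elif key == "label_map":
                if raw:
                    cfg.label_map = {
                        k: int(v) for k, v in (pair.split(":") for pair in raw.split(","))
                    }
            elif key in known:
                if raw == "":
                    setattr(cfg, key, None)
                elif key in cls._BOOL:
                    if raw not in ("True", "False", "true", "false", "1", "0"):
                        raise ValueError(f"config line {ln}: bad boolean {raw!r}")
                    setattr(cfg, key, raw in ("True", "true", "1"))
                elif key in cls._INT:
                    setattr(cfg, key, int(raw))
                elif key in cls._FLOAT:
                    setattr(cfg, key, float(raw))
                else:
                    setattr(cfg, key, raw)
            else:
                raise ValueError(f"config line {ln}: unknown key {key!r}")
        return cfg

    @classmethod
    def from_file(cls, path) -> "BuildConfig":
        return cls.from_text(Path(path).read_text())


# ---------------------------------------------------------------------------
# stage registry
# ---------------------------------------------------------------------------

_REGISTRY: dict = {}


def register_stage(tag: str, stage_name: str, operation: Callable) -> None:
    """Replace one named stage of a tag's workflows with ``operation``.

    The replacement must honor the built-in stage's signature:
    normalize(record, settings) -> record;
    extract(series, config) -> (DescriptorMatrix, y);
    build(X, y, config) -> PLSModel;
    predict(bundle, X_aligned) -> array of predictions.
    """
    if stage_name not in STAGES:
        raise ValueError(f"unknown stage {stage_name!r}; valid stages: {STAGES}")
    _REGISTRY[(tag, stage_name)] = operation


def unregister_stage(tag: str, stage_name: Optional[str] = None) -> None:
    if stage_name is None:
        for key in [k for k in _REGISTRY if k[0] == tag]:
            del _REGISTRY[key]
        return
    _REGISTRY.pop((tag, stage_name), None)


def resolve_stage(tag: str, stage_name: str) -> Callable:
    if stage_name not in STAGES:
        raise ValueError(f"unknown stage {stage_name!r}; valid stages: {STAGES}")
    builtin = {
        "normalize": _builtin_normalize,
        "extract": _builtin_extract,
        "build": _builtin_build,
        "predict": _builtin_predict,
    }[stage_name]
    return _REGISTRY.get((tag, stage_name), builtin)


def registered_stages(tag: str) -> list:
    return sorted(s for (t, s) in _REGISTRY if t == tag)


def _builtin_normalize(record, settings):
    return chem_io.normalize(record, settings)


def _builtin_extract(series, config: BuildConfig):
    return descriptors.extract(
        series,
        embedded_fields=config.embedded_fields,
        descriptor_set_id=config.descriptor_set_id,
    )


def _builtin_build(X, y, config: BuildConfig) -> PLSModel:
    mode = "discriminant" if config.activity_type == "qualitative" else "regression"
    return build_pls_model(X, y, mode=mode, scaling=config.scaling, A_max=config.A_max)


def _builtin_predict(bundle, X_aligned) -> np.ndarray:
    if isinstance(bundle, store.ConfidentialModel):
        return bundle.predict(X_aligned)
    return bundle.pls.predict(X_aligned)


def external_sdf_stage(command: list) -> Callable:
    """Wrap an external SDF-in/SDF-out tool as a normalize-stage override.

    The command is run once per record with the input SDF on a temp file
    and must write the transformed record to the output path appended to
    the argument list.  A missing executable raises immediately; there is
    no silent fallback to the built-in stage.
    """
    import shutil as _shutil
    import subprocess
    import tempfile

    exe = command[0]
    if _shutil.which(exe) is None:
        raise FileNotFoundError(
            f"external tool {exe!r} not found; install it or remove the stage override"
        )

    def _stage(record, settings):
        with tempfile.TemporaryDirectory() as td:
            src = Path(td) / "in.sdf"
            dst = Path(td) / "out.sdf"
            chem_io.write_sdf([record], src)
            subprocess.run([*command, str(src), str(dst)], check=True)
            series = chem_io.read_sdf(dst, require_activity=False)
            out = series.records[0]
            out.structure_key = chem_io.normalize(out).structure_key
            return out

    return _stage


# ---------------------------------------------------------------------------
# reports and results
# ---------------------------------------------------------------------------

@dataclass
class BuildReport:
    tag: str
    n: int
    A_max: int
    A_opt: int
    r2: np.ndarray
    q2: np.ndarray
    sdec: np.ndarray
    sdep: np.ndarray
    recalculated: np.ndarray
    loo_pred: np.ndarray
    var_names: list
    cutoff: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    ffd: Optional[FFDResult] = None
    warnings: list = dc_field(default_factory=list)
    version_path: Optional[Path] = None

    def quality_table(self) -> str:
        rows = ["  A      r2      q2    SDEC    SDEP"]
        for a in range(self.A_max):
            star = " *" if a + 1 == self.A_opt else ""
            rows.append(
                f"{a + 1:3d}  {self.r2[a]:6.3f}  {self.q2[a]:6.3f}  "
                f"{self.sdec[a]:6.3f}  {self.sdep[a]:6.3f}{star}"
            )
        if self.cutoff is not None:
            rows.append(
                f"cutoff={self.cutoff:.4f}  sensitivity={self.sensitivity:.3f}  "
                f"specificity={self.specificity:.3f}"
            )
        return "\n".join(rows)


@dataclass
class PredictionResult:
    compound_id: str
    y_pred: float
    is_training_copy: bool = False
    experimental_value: Optional[float] = None
    adan_category: object = None  # int, "NA" for confidential models, or None
    ci95: object = None           # float, or "NA"
    score: Optional[float] = None
    record: object = None

    def to_dict(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "y_pred": self.y_pred,
            "is_training_copy": self.is_training_copy,
            "experimental_value": self.experimental_value,
            "adan_category": self.adan_category,
            "ci95": self.ci95,
        }


# ---------------------------------------------------------------------------
# workflows
# ---------------------------------------------------------------------------

def _normalize_series(tag: str, series: TrainingSeries, config: BuildConfig) -> TrainingSeries:
    stage = resolve_stage(tag, "normalize")
    settings = config.normalization()
    series.records = [stage(rec, settings) for rec in series.records]
    return series


def build_workflow(root, tag: str, sdf_path, config: Optional[BuildConfig] = None) -> BuildReport:
    """Run normalize -> extract -> build, validate, and persist sandbox
    version 0 under ``root``/``tag``."""
    config = copy.deepcopy(config) if config is not None else BuildConfig()
    series = chem_io.read_sdf(
        sdf_path,
        activity_field=config.activity_field,
        activity_type=config.activity_type,
        label_map=config.label_map,
    )
    n = len(series)
    if n < 5:
        raise ValueError(f"training series too small (n={n}, need >= 5)")
    y_all = np.asarray(series.activities, dtype=float)
    if config.activity_type == "qualitative" and len(np.unique(y_all)) < 2:
        raise ValueError("qualitative training series contains a single class")

    warnings: list = []
    series = _normalize_series(tag, series, config)
    keys = [rec.structure_key for rec in series.records]
    seen: dict = {}
    for i, key in enumerate(keys):
        if key in seen:
            warnings.append(f"duplicate structure: records {seen[key] + 1} and {i + 1}")
        else:
            seen[key] = i

    matrix, y = resolve_stage(tag, "extract")(series, config)

    # near-constant variables would break autoscaling
    variances = matrix.values.var(axis=0)
    var_mask = variances >= VARIANCE_EPS
    if not var_mask.any():
        raise ValueError("all descriptor variables are constant across the training series")
    if not var_mask.all():
        dropped = [v for v, keep in zip(matrix.var_names, var_mask) if not keep]
        warnings.append(f"dropped near-constant variables: {', '.join(dropped)}")
    var_names = [v for v, keep in zip(matrix.var_names, var_mask) if keep]
    X = matrix.values[:, var_mask]

    build_stage = resolve_stage(tag, "build")
    model: PLSModel = build_stage(X, y, config)

    ffd_result = None
    if config.ffd_enabled and X.shape[1] >= 4:
        ffd_result = ffd_select(
            X, y, model.A_opt,
            d=config.ffd_dummies, R=config.ffd_runs,
            threshold_factor=config.ffd_threshold,
            seed=config.seed, scaling=config.scaling,
        )
        warnings.extend(ffd_result.warnings)
        if ffd_result.applied:
            var_names = [v for v, keep in zip(var_names, ffd_result.mask) if keep]
            X = X[:, ffd_result.mask]
            model = build_stage(X, y, config)

    adan_state = None
    if n >= 10:
        Xs = model.scaling.apply(X)
        adan_state = adan_mod.fit_adan(model, Xs, y, k_nn=min(config.k_nn, n - 1))
    else:
        warnings.append("training series too small for ADAN (n < 10); no AD state stored")

    if np.all(model.q2 <= 0):
        warnings.append("no predictive model: q2 <= 0 at every dimensionality")

    custom = registered_stages(tag)
    bundle = store.ModelBundle(
        pls=model,
        var_names=var_names,
        descriptor_set_id=matrix.descriptor_set_id,
        embedded_fields=config.embedded_fields,
        structure_keys=keys,
        activities=list(map(float, y)),
        activity_raw=[rec.activity_raw for rec in series.records],
        activity_type=config.activity_type,
        adan_state=adan_state,
        label_map=config.label_map,
        custom_stages=custom,
    )
    vdir = store.save_version(
        root, tag, bundle,
        training_sdf_text=Path(sdf_path).read_text(),
        config_text=config.to_text(),
    )

    Xs = model.scaling.apply(X)
    recalculated = Xs @ model.B[:, model.A_opt - 1] + model.y_mean
    return BuildReport(
        tag=tag,
        n=n,
        A_max=model.A_max,
        A_opt=model.A_opt,
        r2=model.r2,
        q2=model.q2,
        sdec=model.sdec,
        sdep=model.sdep,
        recalculated=recalculated,
        loo_pred=model.loo_pred,
        var_names=var_names,
        cutoff=model.cutoff,
        sensitivity=model.sensitivity,
        specificity=model.specificity,
        ffd=ffd_result,
        warnings=warnings,
        version_path=vdir,
    )


def predict_workflow(root, tag: str, version: int, sdf_path) -> list:
    """Predict an SDF query file with a stored model version.

    Query structures pass through the same normalize/extract stages as the
    training series.  Training copies (matching structure key) report the
    stored experimental value; confidential versions report category "NA"
    and the exported global CI.
    """
    meta, bundle = store.load_version(root, tag, version)
    config = BuildConfig.from_text(
        (store.version_dir(root, tag, version) / "config.txt").read_text()
    ) if not meta.confidential else BuildConfig()

    series = chem_io.read_sdf(sdf_path, require_activity=False)
    series = _normalize_series(tag, series, config)
    matrix, _ = resolve_stage(tag, "extract")(series, config)

    confidential = isinstance(bundle, store.ConfidentialModel)
    var_names = bundle.var_names
    set_id = bundle.descriptor_set_id
    X = descriptors.align_to_model(matrix, var_names, set_id)

    predict_stage = resolve_stage(tag, "predict")
    raw_pred = np.asarray(predict_stage(bundle, X), dtype=float).ravel()

    results = []
    for i, rec in enumerate(series.records):
        score = float(raw_pred[i])
        y_pred = score
        is_copy = False
        experimental = None
        category = None
        halfwidth = None

        if confidential:
            category = "NA"
            halfwidth = 1.96 * bundle.global_sdep
            if bundle.mode == "discriminant" and bundle.cutoff is not None:
                y_pred = int(score >= bundle.cutoff)
        else:
            model = bundle.pls
            if config.detect_training_copy:
                idx = None
                for j, key in enumerate(bundle.structure_keys):
                    if key == rec.structure_key:
                        idx = j
                        break
                if idx is not None:
                    is_copy = True
                    experimental = float(bundle.activities[idx])
                    y_pred = experimental
            if model.mode == "discriminant" and not is_copy:
                y_pred = int(score >= model.cutoff)
            if bundle.adan_state is not None:
                xs = model.scaling.apply(X[i : i + 1]).ravel()
                t_q = transform_scores(model.core, xs, model.A_opt).ravel()
                category = adan_mod.assess(xs, t_q, bundle.adan_state)
                halfwidth = adan_mod.ci95(category, bundle.adan_state)

        results.append(PredictionResult(
            compound_id=rec.name,
            y_pred=y_pred,
            is_training_copy=is_copy,
            experimental_value=experimental,
            adan_category=category,
            ci95=halfwidth,
            score=score,
            record=rec,
        ))
    store.append_log(root, tag, f"predicted {len(results)} compounds with version {version}")
    return results


def retrain(root, tag: str, new_sdf_path) -> BuildReport:
    """Concatenate the stored training series with new compounds and
    rebuild a fresh sandbox version 0 under the stored configuration.

    New compounds whose structure key already occurs (in the original
    series or earlier in the new file) are dropped with a warning; the
    earlier record is kept.
    """
    versions = store.list_versions(root, tag)
    source = None
    for meta in sorted(versions, key=lambda m: m.version, reverse=True):
        if not meta.confidential:
            source = meta
            break
    if source is None:
        raise ValueError(
            f"model {tag!r} holds only confidential versions; no training series retained"
        )
    vdir = store.version_dir(root, tag, source.version)
    config = BuildConfig.from_text((vdir / "config.txt").read_text())

    original = chem_io.read_sdf(
        vdir / "training.sdf",
        activity_field=config.activity_field,
        activity_type=config.activity_type,
        label_map=config.label_map,
    )
    new = chem_io.read_sdf(
        new_sdf_path,
        activity_field=config.activity_field,
        activity_type=config.activity_type,
        label_map=config.label_map,
    )
    settings = config.normalization()
    known = {chem_io.normalize(rec, settings).structure_key for rec in original.records}
    kept = []
    dropped = 0
    for rec in new.records:
        key = chem_io.normalize(rec, settings).structure_key
        if key in known:
            dropped += 1
            continue
        known.add(key)
        kept.append(rec)

    combined = vdir.parent / "retrain-input.sdf"
    chem_io.write_sdf(original.records + kept, combined)
    report = build_workflow(root, tag, combined, config)
    if dropped:
        report.warnings.append(f"dropped {dropped} duplicate new compounds at retrain")
    store.append_log(root, tag, f"retrained with {len(kept)} new compounds ({dropped} duplicates dropped)")
    return report
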