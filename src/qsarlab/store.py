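"""Versioned on-disk model repository.

One directory tree per tag; ``version-0000`` is the development sandbox
and publication copies it to the next sequential integer.  Version
numbers are never reused after removal (forensic traceability).  Every
version directory is self-contained: config, training-series copy,
serialized model, AD state and metadata.

The confidential export is the only bit-specified format: UTF-8
tab-separated text, one ``VAR`` record per retained descriptor variable
(name, mean, scale, raw-space coefficient) and nothing sized by the
number of training compounds.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
import shutil
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .adan import ADANState
from .mva import PLSModel, ScalingState

__all__ = [
    "ModelVersionInfo",
    "ModelBundle",
    "ConfidentialModel",
    "version_dir",
    "save_version",
    "load_version",
    "publish",
    "list_versions",
    "remove_version",
    "export_version",
    "import_version",
    "export_confidential",
    "load_confidential",
    "import_confidential",
    "append_log",
]

_TAG_RE = re.compile(r"^[A-Za-z0-9_-]+$")
_VDIR_RE = re.compile(r"^version-(\d{4})$")

CONFIDENTIAL_MAGIC = "QSARLAB-CONFIDENTIAL 1"


@dataclass
class ModelVersionInfo:
    tag: str
    version: int
    created: str
    n_compounds: int
    activity_type: str
    A_opt: int
    r2_opt: float
    q2_opt: float
    sdep_opt: float
    confidential: bool = False
    custom: bool = False
    notes: str = ""


@dataclass
class ModelBundle:
    """Everything a stored (non-confidential) version needs to predict."""

    pls: PLSModel
    var_names: list
    descriptor_set_id: str
    embedded_fields: list
    structure_keys: list
    activities: list
    activity_raw: list
    activity_type: str
    adan_state: Optional[ADANState] = None
    label_map: dict = field(default_factory=dict)
    custom_stages: list = field(default_factory=list)


@dataclass
class ConfidentialModel:
    """Coefficient-only model: one (mean, scale, coefficient) triple per
    retained variable plus scalar header values; no per-compound data."""

    tag: str
    mode: str
    A_opt: int
    intercept_raw: float
    global_sdep: float
    descriptor_set_id: str
    var_names: list
    means: np.ndarray
    scales: np.ndarray
    coefficients_raw: np.ndarray
    cutoff: Optional[float] = None

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X_raw, dtype=float))
        return X @ self.coefficients_raw + self.intercept_raw


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def _arr(x) -> list:
    return np.asarray(x).tolist()


def _model_to_dict(m: PLSModel) -> dict:
    return {
        "W": _arr(m.W), "P": _arr(m.P), "c": _arr(m.c), "T": _arr(m.T), "B": _arr(m.B),
        "scaling": {"mode": m.scaling.mode, "means": _arr(m.scaling.means),
                    "scales": _arr(m.scaling.scales)},
        "y_mean": m.y_mean, "A_max": m.A_max, "A_opt": m.A_opt,
        "r2": _arr(m.r2), "q2": _arr(m.q2), "sdec": _arr(m.sdec), "sdep": _arr(m.sdep),
        "loo_pred": _arr(m.loo_pred), "mode": m.mode, "cutoff": m.cutoff,
        "sensitivity": m.sensitivity, "specificity": m.specificity,
        "coefficients_raw": _arr(m.coefficients_raw), "intercept_raw": m.intercept_raw,
    }


def _model_from_dict(d: dict) -> PLSModel:
    sc = d["scaling"]
    return PLSModel(
        W=np.array(d["W"]), P=np.array(d["P"]), c=np.array(d["c"]),
        T=np.array(d["T"]), B=np.array(d["B"]),
        scaling=ScalingState(sc["mode"], np.array(sc["means"]), np.array(sc["scales"])),
        y_mean=d["y_mean"], A_max=d["A_max"], A_opt=d["A_opt"],
        r2=np.array(d["r2"]), q2=np.array(d["q2"]),
        sdec=np.array(d["sdec"]), sdep=np.array(d["sdep"]),
        loo_pred=np.array(d["loo_pred"]), mode=d["mode"], cutoff=d["cutoff"],
        sensitivity=d["sensitivity"], specificity=d["specificity"],
        coefficients_raw=np.array(d["coefficients_raw"]),
        intercept_raw=d["intercept_raw"],
    )


def _adan_to_dict(s: ADANState) -> dict:
    return {
        "thresholds": _arr(s.thresholds), "x_centroid": _arr(s.x_centroid),
        "t_centroid": _arr(s.t_centroid), "loadings": _arr(s.loadings),
        "weights": _arr(s.weights), "training_Xs": _arr(s.training_Xs),
        "training_T": _arr(s.training_T), "training_y": _arr(s.training_y),
        "k_nn": s.k_nn, "category_ci95": _arr(s.category_ci95),
        "training_categories": _arr(s.training_categories),
    }


def _adan_from_dict(d: dict) -> ADANState:
    return ADANState(
        thresholds=np.array(d["thresholds"]), x_centroid=np.array(d["x_centroid"]),
        t_centroid=np.array(d["t_centroid"]), loadings=np.array(d["loadings"]),
        weights=np.array(d["weights"]), training_Xs=np.array(d["training_Xs"]),
        training_T=np.array(d["training_T"]), training_y=np.array(d["training_y"]),
        k_nn=d["k_nn"], category_ci95=np.array(d["category_ci95"]),
        training_categories=np.array(d["training_categories"], dtype=int),
    )


# ---------------------------------------------------------------------------
# tree layout
# ---------------------------------------------------------------------------

def _check_tag(tag: str) -> None:
    if not _TAG_RE.match(tag or ""):
        raise ValueError(f"invalid model tag {tag!r} (allowed: letters, digits, _ and -)")


def version_dir(root, tag: str, version: int) -> Path:
    return Path(root) / tag / f"version-{version:04d}"


def _existing_versions(root, tag: str) -> list:
    tag_dir = Path(root) / tag
    if not tag_dir.is_dir():
        raise FileNotFoundError(f"unknown model tag {tag!r}")
    out = []
    for child in tag_dir.iterdir():
        m = _VDIR_RE.match(child.name)
        if m and child.is_dir():
            out.append(int(m.group(1)))
    return sorted(out)


def append_log(root, tag: str, message: str) -> None:
    tag_dir = Path(root) / tag
    tag_dir.mkdir(parents=True, exist_ok=True)
    stamp = _dt.datetime.now().isoformat(timespec="seconds")
    with open(tag_dir / "activity.log", "a") as fh:
        fh.write(f"{stamp}\t{message}\n")


# ---------------------------------------------------------------------------
# save / load
# ---------------------------------------------------------------------------

def save_version(
    root,
    tag: str,
    bundle: ModelBundle,
    training_sdf_text: str,
    config_text: str,
    version: int = 0,
    notes: str = "",
) -> Path:
    """Write a self-contained version directory (default: sandbox 0,
    replacing any previous sandbox)."""
    _check_tag(tag)
    vdir = version_dir(root, tag, version)
    if vdir.exists():
        shutil.rmtree(vdir)
    vdir.mkdir(parents=True)
    (vdir / "training.sdf").write_text(training_sdf_text)
    (vdir / "config.txt").write_text(config_text)
    m = bundle.pls
    payload = {
        "model": _model_to_dict(m),
        "var_names": list(bundle.var_names),
        "descriptor_set_id": bundle.descriptor_set_id,
        "embedded_fields": list(bundle.embedded_fields),
        "structure_keys": list(bundle.structure_keys),
        "activities": _arr(bundle.activities),
        "activity_raw": list(bundle.activity_raw),
        "activity_type": bundle.activity_type,
        "label_map": dict(bundle.label_map),
        "custom_stages": list(bundle.custom_stages),
    }
    (vdir / "model.json").write_text(json.dumps(payload))
    if bundle.adan_state is not None:
        (vdir / "adan.json").write_text(json.dumps(_adan_to_dict(bundle.adan_state)))
    meta = ModelVersionInfo(
        tag=tag,
        version=version,
        created=_dt.datetime.now().isoformat(timespec="seconds"),
        n_compounds=len(bundle.structure_keys),
        activity_type=bundle.activity_type,
        A_opt=m.A_opt,
        r2_opt=float(m.r2[m.A_opt - 1]),
        q2_opt=float(m.q2[m.A_opt - 1]),
        sdep_opt=float(m.sdep[m.A_opt - 1]),
        confidential=False,
        custom=bool(bundle.custom_stages),
        notes=notes,
    )
    (vdir / "meta.json").write_text(json.dumps(meta.__dict__, indent=1))
    append_log(root, tag, f"saved version {version}")
    return vdir


def _read_meta(vdir: Path) -> ModelVersionInfo:
    return ModelVersionInfo(**json.loads((vdir / "meta.json").read_text()))


def load_version(root, tag: str, version: int):
    """Load a stored version.  Returns ``(meta, bundle_or_confidential)``."""
    vdir = version_dir(root, tag, version)
    if not vdir.is_dir():
        raise FileNotFoundError(f"model {tag!r} has no version {version}")
    meta = _read_meta(vdir)
    if meta.confidential:
        return meta, load_confidential(vdir / "confidential.txt")
    payload = json.loads((vdir / "model.json").read_text())
    adan_state = None
    if (vdir / "adan.json").exists():
        adan_state = _adan_from_dict(json.loads((vdir / "adan.json").read_text()))
    bundle = ModelBundle(
        pls=_model_from_dict(payload["model"]),
        var_names=payload["var_names"],
        descriptor_set_id=payload["descriptor_set_id"],
        embedded_fields=payload["embedded_fields"],
        structure_keys=payload["structure_keys"],
        activities=payload["activities"],
        activity_raw=payload["activity_raw"],
        activity_type=payload["activity_type"],
        adan_state=adan_state,
        label_map=payload.get("label_map", {}),
        custom_stages=payload.get("custom_stages", []),
    )
    return meta, bundle


# ---------------------------------------------------------------------------
# life cycle
# ---------------------------------------------------------------------------

def publish(root, tag: str) -> int:
    """Copy sandbox version 0 to the next sequential published number."""
    versions = _existing_versions(root, tag)
    if 0 not in versions:
        raise FileNotFoundError(f"model {tag!r} has no sandbox (version 0) to publish")
    published = [v for v in versions if v > 0]
    new = (max(published) + 1) if published else 1
    src = version_dir(root, tag, 0)
    dst = version_dir(root, tag, new)
    shutil.copytree(src, dst)
    meta = _read_meta(dst)
    meta.version = new
    (dst / "meta.json").write_text(json.dumps(meta.__dict__, indent=1))
    append_log(root, tag, f"published version {new}")
    return new


def list_versions(root, tag: str) -> list:
    return [_read_meta(version_dir(root, tag, v)) for v in _existing_versions(root, tag)]


def remove_version(root, tag: str, version: int) -> None:
    versions = _existing_versions(root, tag)
    if version not in versions:
        raise FileNotFoundError(f"model {tag!r} has no version {version}")
    if version == 0 and versions == [0]:
        raise ValueError("cannot remove the only remaining version (sandbox 0)")
    shutil.rmtree(version_dir(root, tag, version))
    append_log(root, tag, f"removed version {version}")


def export_version(root, tag: str, version: int, dest) -> Path:
    """Archive one version directory as a zip file (reimportable)."""
    vdir = version_dir(root, tag, version)
    if not vdir.is_dir():
        raise FileNotFoundError(f"model {tag!r} has no version {version}")
    dest = Path(dest)
    with zipfile.ZipFile(dest, "w", zipfile.ZIP_DEFLATED) as zf:
        for f in sorted(vdir.rglob("*")):
            zf.write(f, f.relative_to(vdir))
    append_log(root, tag, f"exported version {version} to {dest}")
    return dest


def import_version(root, tag: str, archive) -> int:
    """Unpack an exported archive into a tag; the original version number is
    preserved and must be free."""
    _check_tag(tag)
    archive = Path(archive)
    if not archive.exists():
        raise FileNotFoundError(f"archive not found: {archive}")
    with zipfile.ZipFile(archive) as zf:
        meta = ModelVersionInfo(**json.loads(zf.read("meta.json")))
        vdir = version_dir(root, tag, meta.version)
        if vdir.exists():
            raise FileExistsError(f"model {tag!r} already has version {meta.version}")
        vdir.mkdir(parents=True)
        zf.extractall(vdir)
    if meta.tag != tag:  # imported under a new tag: rewrite metadata
        meta.tag = tag
        (vdir / "meta.json").write_text(json.dumps(meta.__dict__, indent=1))
    append_log(root, tag, f"imported version {meta.version} from {archive}")
    return meta.version


# ---------------------------------------------------------------------------
# confidential mode
# ---------------------------------------------------------------------------

def _confidential_text(tag: str, bundle: ModelBundle) -> str:
    m = bundle.pls
    if bundle.custom_stages and any(s in ("build", "predict") for s in bundle.custom_stages):
        raise ValueError("confidential export undefined for overridden build/predict stage")
    lines = [CONFIDENTIAL_MAGIC]
    header = {
        "tag": tag,
        "mode": m.mode,
        "A_opt": str(m.A_opt),
        "intercept_raw": f"{m.intercept_raw:.17g}",
        "global_sdep": f"{float(m.sdep[m.A_opt - 1]):.17g}",
        "descriptor_set_id": bundle.descriptor_set_id,
    }
    if m.mode == "discriminant":
        header["cutoff"] = f"{m.cutoff:.17g}"
    for k, v in header.items():
        lines.append(f"{k}\t{v}")
    state = m.scaling
    for j, name in enumerate(bundle.var_names):
        lines.append(
            "VAR\t{}\t{:.17g}\t{:.17g}\t{:.17g}".format(
                name, float(state.means[j]), float(state.scales[j]),
                float(m.coefficients_raw[j]),
            )
        )
    return "\n".join(lines) + "\n"


def export_confidential(root, tag: str, version: int, dest) -> Path:
    """Write the coefficient-only text export of a stored version.

    The file holds scalar header values and one record per retained
    variable; nothing in it scales with or derives from individual
    training compounds.
    """
    meta, bundle = load_version(root, tag, version)
    if meta.confidential:
        raise ValueError("version is already confidential; copy the stored file instead")
    dest = Path(dest)
    dest.write_text(_confidential_text(tag, bundle), encoding="utf-8")
    append_log(root, tag, f"confidential export of version {version} to {dest}")
    return dest


def load_confidential(path) -> ConfidentialModel:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != CONFIDENTIAL_MAGIC:
        raise ValueError(f"{path} is not a confidential model file")
    header: dict = {}
    names, means, scales, coefs = [], [], [], []
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        if parts[0] == "VAR":
            _, name, mean, scale, coef = parts
            names.append(name)
            means.append(float(mean))
            scales.append(float(scale))
            coefs.append(float(coef))
        else:
            header[parts[0]] = parts[1]
    return ConfidentialModel(
        tag=header["tag"],
        mode=header["mode"],
        A_opt=int(header["A_opt"]),
        intercept_raw=float(header["intercept_raw"]),
        global_sdep=float(header["global_sdep"]),
        descriptor_set_id=header["descriptor_set_id"],
        var_names=names,
        means=np.array(means),
        scales=np.array(scales),
        coefficients_raw=np.array(coefs),
        cutoff=float(header["cutoff"]) if "cutoff" in header else None,
    )


def import_confidential(root, tag: str, path, version: int = 1) -> int:
    """Install a confidential model file as a (confidential) stored version."""
    _check_tag(tag)
    cm = load_confidential(path)
    vdir = version_dir(root, tag, version)
    if vdir.exists():
        raise FileExistsError(f"model {tag!r} already has version {version}")
    vdir.mkdir(parents=True)
    shutil.copyfile(path, vdir / "confidential.txt")
    meta = ModelVersionInfo(
        tag=tag,
        version=version,
        created=_dt.datetime.now().isoformat(timespec="seconds"),
        n_compounds=0,
        activity_type="quantitative" if cm.mode == "regression" else "qualitative",
        A_opt=cm.A_opt,
        r2_opt=float("nan"),
        q2_opt=float("nan"),
        sdep_opt=cm.global_sdep,
        confidential=True,
        notes="imported confidential model",
    )
    (vdir / "meta.json").write_text(json.dumps(meta.__dict__, indent=1))
    append_log(root, tag, f"imported confidential model as version {version}")
    return version
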