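"""SDF/CSV input-output, structure normalization and training-copy lookup.

Records are kept as verbatim V2000 mol-block text plus a map of data
fields; RDKit does all chemistry (parsing, fragment splitting, canonical
keys).  Only V2000 mol-blocks are accepted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
from pathlib import Path
from typing import Optional

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "TrainingSeries",
    "NormalizationSettings",
    "read_sdf",
    "normalize",
    "find_in_training",
    "write_sdf",
    "write_predictions",
]

DEFAULT_LABEL_MAP = {"0": 0, "1": 1}


@dataclass
class MoleculeRecord:
    """One SDF record: structure text, name, activity and extra data fields."""

    mol_text: str
    name: str
    activity_raw: str = ""
    extra_fields: dict = field(default_factory=dict)
    structure_key: str = ""

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromMolBlock(self.mol_text)
        if mol is None or mol.GetNumAtoms() == 0:
            raise ValueError(f"mol-block of record {self.name!r} does not parse")
        return mol


@dataclass
class TrainingSeries:
    records: list
    activity_field: str = "activity"
    activity_type: str = "quantitative"
    activities: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class NormalizationSettings:
    """Minimal built-in standardization: largest-fragment keep + H removal.

    Ionization adjustment and 2D->3D conversion are deliberately not
    implemented natively; they are available as external-tool stage
    overrides (see workflows).
    """

    strip_salts: bool = True
    remove_hs: bool = True


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _split_sdf_records(text: str) -> list:
    records = []
    current: list = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            records.append("\n".join(current))
            current = []
        else:
            current.append(line)
    if any(l.strip() for l in current):
        records.append("\n".join(current))
    return records


def _parse_record(raw: str, index: int) -> MoleculeRecord:
    lines = raw.splitlines()
    end = None
    for i, line in enumerate(lines):
        if line.startswith("M  END"):
            end = i
            break
    if end is None:
        raise ValueError(f"record {index}: no 'M  END' terminator (not a V2000 mol-block)")
    if len(lines) > 3 and "V3000" in lines[3]:
        raise ValueError(f"record {index}: V3000 mol-blocks are not supported (V2000 only)")
    mol_text = "\n".join(lines[: end + 1]) + "\n"
    name = lines[0].strip() if lines else ""

    fields: dict = {}
    i = end + 1
    while i < len(lines):
        line = lines[i]
        if line.startswith(">"):
            lt = line.find("<")
            gt = line.find(">", lt)
            if lt == -1 or gt == -1:
                raise ValueError(f"record {index}: malformed data-field header {line!r}")
            fname = line[lt + 1 : gt]
            i += 1
            vals = []
            while i < len(lines) and lines[i].strip() != "":
                vals.append(lines[i])
                i += 1
            fields[fname] = "\n".join(vals)
        i += 1

    if Chem.MolFromMolBlock(mol_text) is None:
        raise ValueError(f"record {index}: unparseable mol-block")
    return MoleculeRecord(mol_text=mol_text, name=name or f"mol{index}", extra_fields=fields)


def read_sdf(
    path,
    activity_field: str = "activity",
    activity_type: str = "quantitative",
    label_map: Optional[dict] = None,
    require_activity: bool = True,
) -> TrainingSeries:
    """Read a multi-record V2000 SDF into a :class:`TrainingSeries`.

    Record order is preserved.  Quantitative activities are parsed as
    floats; qualitative ones are mapped to 0/1 through ``label_map``
    (default ``{"0": 0, "1": 1}``).  Record indices in error messages are
    1-based.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SDF file not found: {path}")
    if activity_type not in ("quantitative", "qualitative"):
        raise ValueError(f"unknown activity type {activity_type!r}")
    label_map = dict(label_map) if label_map else dict(DEFAULT_LABEL_MAP)
    if activity_type == "qualitative":
        if len(label_map) != 2 or set(label_map.values()) != {0, 1}:
            raise ValueError("qualitative label map must map exactly two labels to 0 and 1")

    raws = _split_sdf_records(path.read_text())
    if not raws:
        raise ValueError(f"no records found in {path}")
    records = []
    activities = []
    for k, raw in enumerate(raws, start=1):
        rec = _parse_record(raw, k)
        if require_activity:
            if activity_field not in rec.extra_fields:
                raise ValueError(f"activity field missing in record {k}")
            val = rec.extra_fields[activity_field].strip()
            rec.activity_raw = val
            if activity_type == "quantitative":
                try:
                    activities.append(float(val))
                except ValueError:
                    raise ValueError(
                        f"record {k}: activity value {val!r} is not numeric"
                    ) from None
            else:
                if val not in label_map:
                    raise ValueError(
                        f"record {k}: qualitative label {val!r} not in mapping "
                        f"{sorted(label_map)}"
                    )
                activities.append(float(label_map[val]))
        records.append(rec)
    return TrainingSeries(
        records=records,
        activity_field=activity_field,
        activity_type=activity_type,
        activities=activities,
    )


# ---------------------------------------------------------------------------
# normalization and lookup
# ---------------------------------------------------------------------------

def normalize(record: MoleculeRecord, settings: Optional[NormalizationSettings] = None) -> MoleculeRecord:
    """Standardize a record: keep the largest covalent fragment, drop explicit
    hydrogens and compute the canonical structure key.  Idempotent."""
    settings = settings or NormalizationSettings()
    mol = record.to_mol()
    if settings.strip_salts:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
        if not frags:
            raise ValueError(f"record {record.name!r}: empty molecule after fragment selection")
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    if mol.GetNumAtoms() == 0:
        raise ValueError(f"record {record.name!r}: empty molecule after normalization")
    if settings.remove_hs:
        mol = Chem.RemoveHs(mol)
    key = Chem.MolToSmiles(mol)
    mol.SetProp("_Name", record.name)
    return replace(
        record,
        mol_text=Chem.MolToMolBlock(mol),
        structure_key=key,
    )


def find_in_training(query_key: str, series: TrainingSeries) -> Optional[int]:
    """Index of the first training record with the same structure key, else None."""
    for i, rec in enumerate(series.records):
        if rec.structure_key and rec.structure_key == query_key:
            return i
    return None


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, str):
        return value
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    try:
        return repr(float(value))  # shortest exact round-trip
    except (TypeError, ValueError):
        return str(value)


def write_sdf(records, path) -> None:
    """Write records back to SDF, mol-block verbatim plus data fields."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.mol_text.rstrip("\n") + "\n")
            for fname, val in rec.extra_fields.items():
                fh.write(f">  <{fname}>\n{val}\n\n")
            fh.write("$$$$\n")


PREDICTION_COLUMNS = ["name", "prediction", "is_training_copy", "experimental_value",
                      "adan_category", "ci95"]


def write_predictions(results, path, fmt: Optional[str] = None) -> None:
    """Export prediction results as CSV or SDF.

    SDF output reuses each query's structure and appends three data fields
    (prediction, AD category, 95% CI half-width); numbers are printed in
    shortest exact round-trip form so re-reading recovers them verbatim.
    """
    results = list(results)
    if not results:
        raise ValueError("no prediction results to write")
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("csv", "sdf"):
        raise ValueError(f"unsupported output format {fmt!r}")

    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(PREDICTION_COLUMNS)
            for r in results:
                writer.writerow([
                    r.compound_id,
                    _fmt(r.y_pred),
                    _fmt(bool(r.is_training_copy)),
                    _fmt(r.experimental_value),
                    _fmt(r.adan_category),
                    _fmt(r.ci95),
                ])
        return

    out_records = []
    for r in results:
        if r.record is None:
            raise ValueError(f"result {r.compound_id!r} carries no structure; cannot write SDF")
        fields = dict(r.record.extra_fields)
        fields["prediction"] = _fmt(r.y_pred)
        fields["adan_category"] = _fmt(r.adan_category)
        fields["ci95"] = _fmt(r.ci95)
        out_records.append(replace(r.record, extra_fields=fields))
    write_sdf(out_records, path)
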