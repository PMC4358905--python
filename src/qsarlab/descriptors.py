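"""Built-in 2D descriptor block, series extraction and model alignment.

The built-in block is a self-contained substitute for an external
descriptor engine: simple counts and two topological indices, identical
variable set for every molecule.  External engines can replace it through
the workflow stage registry, keyed by ``descriptor_set_id``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors as RDDescriptors
from rdkit.Chem import Lipinski, rdmolops

from .chem_io import MoleculeRecord, TrainingSeries

__all__ = [
    "DescriptorMatrix",
    "BUILTIN_SET_ID",
    "BUILTIN_VAR_NAMES",
    "compute_builtin",
    "extract",
    "align_to_model",
]

BUILTIN_SET_ID = "builtin-2d-v1"

BUILTIN_VAR_NAMES = [
    "n_C", "n_N", "n_O", "n_S", "n_P", "n_halogen", "n_other",
    "n_heavy",
    "n_bond_single", "n_bond_double", "n_bond_triple", "n_bond_aromatic",
    "n_rings", "n_aromatic_atoms",
    "n_hbd", "n_hba",
    "mol_weight",
    "zagreb_m1",
    "wiener",
]

_HALOGENS = {9, 17, 35, 53, 85}


@dataclass
class DescriptorMatrix:
    """n x p numeric description of a series, rows ordered as the input."""

    values: np.ndarray
    var_names: list
    compound_ids: list
    descriptor_set_id: str = BUILTIN_SET_ID

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("descriptor matrix must be 2-dimensional")
        if self.values.shape != (len(self.compound_ids), len(self.var_names)):
            raise ValueError("descriptor matrix shape does not match ids/names")
        if len(set(self.var_names)) != len(self.var_names):
            raise ValueError("variable names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor matrix contains non-finite values")


def compute_builtin(record: MoleculeRecord) -> np.ndarray:
    """Fixed-length descriptor vector for one normalized record.

    Element counts, heavy-atom count, bond counts by order, SSSR ring
    count, aromatic-atom count, H-bond donors/acceptors, molecular weight,
    first Zagreb index (sum of squared degrees) and Wiener index (sum of
    pairwise topological distances over heavy atoms).
    """
    mol = record.to_mol()
    if len(Chem.GetMolFrags(mol)) > 1:
        raise ValueError(
            f"record {record.name!r} is disconnected; normalize before extraction"
        )
    counts = {"C": 0, "N": 0, "O": 0, "S": 0, "P": 0, "hal": 0, "other": 0}
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        sym = atom.GetSymbol()
        if sym in counts:
            counts[sym] += 1
        elif z in _HALOGENS:
            counts["hal"] += 1
        else:
            counts["other"] += 1

    n_single = n_double = n_triple = n_aromatic = 0
    for bond in mol.GetBonds():
        bt = bond.GetBondType()
        if bt == Chem.BondType.AROMATIC:
            n_aromatic += 1
        elif bt == Chem.BondType.SINGLE:
            n_single += 1
        elif bt == Chem.BondType.DOUBLE:
            n_double += 1
        elif bt == Chem.BondType.TRIPLE:
            n_triple += 1
        else:
            n_single += 1

    n_rings = mol.GetRingInfo().NumRings()
    n_arom_atoms = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    zagreb = float(sum(a.GetDegree() ** 2 for a in mol.GetAtoms()))
    if mol.GetNumHeavyAtoms() > 1:
        dm = rdmolops.GetDistanceMatrix(mol)
        wiener = float(dm.sum() / 2.0)
    else:
        wiener = 0.0

    vec = np.array([
        counts["C"], counts["N"], counts["O"], counts["S"], counts["P"],
        counts["hal"], counts["other"],
        mol.GetNumHeavyAtoms(),
        n_single, n_double, n_triple, n_aromatic,
        n_rings, n_arom_atoms,
        Lipinski.NumHDonors(mol), Lipinski.NumHAcceptors(mol),
        RDDescriptors.MolWt(mol),
        zagreb,
        wiener,
    ], dtype=float)
    assert vec.shape[0] == len(BUILTIN_VAR_NAMES)
    return vec


def extract(
    series: TrainingSeries,
    embedded_fields: Optional[list] = None,
    descriptor_set_id: str = BUILTIN_SET_ID,
) -> tuple[DescriptorMatrix, np.ndarray]:
    """Compute the descriptor matrix of a normalized series.

    Embedded numeric SDF data fields named in ``embedded_fields`` are
    appended as extra variables after the built-in block.  Deterministic:
    repeated calls yield bit-identical matrices.
    """
    embedded_fields = list(embedded_fields or [])
    rows = []
    ids = []
    for k, rec in enumerate(series.records, start=1):
        row = list(compute_builtin(rec))
        for fname in embedded_fields:
            if fname not in rec.extra_fields:
                raise ValueError(f"record {k}: embedded field {fname!r} missing")
            try:
                row.append(float(rec.extra_fields[fname].strip()))
            except ValueError:
                raise ValueError(
                    f"record {k}: embedded field {fname!r} is not numeric"
                ) from None
        rows.append(row)
        ids.append(rec.name)
    matrix = DescriptorMatrix(
        values=np.array(rows, dtype=float),
        var_names=BUILTIN_VAR_NAMES + embedded_fields,
        compound_ids=ids,
        descriptor_set_id=descriptor_set_id,
    )
    y = np.asarray(series.activities, dtype=float)
    return matrix, y


def align_to_model(
    query_matrix: DescriptorMatrix,
    model_var_names: list,
    model_set_id: str,
) -> np.ndarray:
    """Reorder/subset query descriptor columns to a model's retained
    variable list (model order)."""
    if query_matrix.descriptor_set_id != model_set_id:
        raise ValueError(
            f"descriptor set mismatch: query {query_matrix.descriptor_set_id!r} "
            f"vs model {model_set_id!r}"
        )
    if not model_var_names:
        raise ValueError("empty model variable set")
    pos = {name: i for i, name in enumerate(query_matrix.var_names)}
    idx = []
    for name in model_var_names:
        if name not in pos:
            raise ValueError(f"query descriptors lack model variable {name!r}")
        idx.append(pos[name])
    return query_matrix.values[:, idx]
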