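"""Deterministic synthetic fixtures: latent-structure matrices and toy
SDF molecule sets whose activities are exact functions of the built-in
descriptors.  Every generator is a pure function of its arguments.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_io import MoleculeRecord
from .descriptors import BUILTIN_VAR_NAMES, compute_builtin

__all__ = [
    "gen_latent",
    "gen_toy_sdf",
    "gen_da_set",
    "default_activity_rule",
    "random_tree_record",
]

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}
_ELEMENTS = ["C", "C", "C", "C", "N", "O", "S"]  # carbon-weighted draw


# ---------------------------------------------------------------------------
# latent-structure matrices
# ---------------------------------------------------------------------------

def gen_latent(
    n: int,
    p: int,
    k: int,
    noise_sd: float,
    seed: int,
    x_noise_sd: float = 1e-3,
):
    """X = T P' + perturbation, y = T beta + noise.

    T is n x k standard normal, P is p x k random orthonormal, beta is a
    fixed-scale random coefficient vector.  Returns (X, y, T, P, beta).
    """
    if k > min(n, p):
        raise ValueError("k must not exceed min(n, p)")
    rng = np.random.default_rng(seed)
    T = rng.standard_normal((n, k))
    P, _ = np.linalg.qr(rng.standard_normal((p, k)))
    beta = rng.uniform(0.5, 1.5, size=k) * rng.choice([-1.0, 1.0], size=k)
    X = T @ P.T + x_noise_sd * rng.standard_normal((n, p))
    y = T @ beta + noise_sd * rng.standard_normal(n)
    return X, y, T, P, beta


# ---------------------------------------------------------------------------
# toy molecules
# ---------------------------------------------------------------------------

def random_tree_record(rng: np.random.Generator, name: str) -> MoleculeRecord:
    """One valence-legal random tree of 3-12 heavy atoms over C/N/O/S,
    single bonds only, emitted as a V2000 mol-block."""
    n_atoms = int(rng.integers(3, 13))
    mol = Chem.RWMol()
    symbols = [str(rng.choice(_ELEMENTS))]
    mol.AddAtom(Chem.Atom(symbols[0]))
    degrees = [0]
    for _ in range(1, n_atoms):
        open_sites = [i for i, s in enumerate(symbols) if degrees[i] < _VALENCE[s]]
        parent = int(rng.choice(open_sites))
        sym = str(rng.choice(_ELEMENTS))
        idx = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(parent, idx, Chem.BondType.SINGLE)
        symbols.append(sym)
        degrees.append(1)
        degrees[parent] += 1
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    AllChem.Compute2DCoords(m)
    m.SetProp("_Name", name)
    return MoleculeRecord(mol_text=Chem.MolToMolBlock(m), name=name)


_DEFAULT_WEIGHTS = {"n_C": 1.0, "n_N": 0.5, "n_O": -0.7, "n_S": 0.3, "wiener": 0.05}
_DEFAULT_INTERCEPT = 2.0


def default_activity_rule(descriptor_vector: np.ndarray) -> float:
    """Fixed linear combination of atom counts and the Wiener index."""
    value = _DEFAULT_INTERCEPT
    for name, w in _DEFAULT_WEIGHTS.items():
        value += w * float(descriptor_vector[BUILTIN_VAR_NAMES.index(name)])
    return value


def gen_toy_sdf(
    n: int,
    seed: int,
    path,
    rule: Optional[Callable[[np.ndarray], float]] = None,
    noise_sd: float = 0.0,
    activity_field: str = "activity",
) -> np.ndarray:
    """Write ``n`` toy molecules with computed activities to a V2000 SDF.

    The activity of each molecule is ``rule`` applied to its built-in
    descriptor vector (default: a fixed linear combination), plus optional
    Gaussian noise.  Returns the ground-truth (noise-free) activities.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rule = rule or default_activity_rule
    rng = np.random.default_rng(seed)
    truth = np.empty(n)
    with open(path, "w") as fh:
        for i in range(n):
            rec = random_tree_record(rng, f"toy{i + 1:03d}")
            vec = compute_builtin(rec)
            truth[i] = rule(vec)
            value = float(truth[i] + (noise_sd * rng.standard_normal() if noise_sd else 0.0))
            fh.write(rec.mol_text.rstrip("\n") + "\n")
            fh.write(f">  <{activity_field}>\n{value!r}\n\n$$$$\n")
    return truth


def gen_da_set(
    n_per_class: int,
    separation: float,
    seed: int,
    p: int = 10,
):
    """Two Gaussian classes shifted by ``separation`` SDs along a random
    latent direction.  Returns (X, labels) with labels 0/1."""
    if n_per_class < 5:
        raise ValueError("n_per_class must be >= 5")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(p)
    direction /= np.linalg.norm(direction)
    X0 = rng.standard_normal((n_per_class, p))
    X1 = rng.standard_normal((n_per_class, p)) + separation * direction
    X = np.vstack([X0, X1])
    labels = np.concatenate([np.zeros(n_per_class, dtype=int), np.ones(n_per_class, dtype=int)])
    return X, labels
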