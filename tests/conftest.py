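"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from qsarlab import workflows
from qsarlab.chem_io import MoleculeRecord
from qsarlab.mva import scale_fit
from qsarlab.synth import gen_toy_sdf


# ---------------------------------------------------------------------------
# molecule helpers
# ---------------------------------------------------------------------------

def record_from_smiles(smiles: str, name: str = "mol") -> MoleculeRecord:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    AllChem.Compute2DCoords(mol)
    mol.SetProp("_Name", name)
    return MoleculeRecord(mol_text=Chem.MolToMolBlock(mol), name=name)


@pytest.fixture
def ethanol():
    return record_from_smiles("CCO", "ethanol")


@pytest.fixture
def benzene():
    return record_from_smiles("c1ccccc1", "benzene")


@pytest.fixture
def sodium_acetate():
    return record_from_smiles("CC(=O)[O-].[Na+]", "sodium_acetate")


@pytest.fixture
def toy_sdf(tmp_path):
    """30-molecule training SDF with noise-free activities that are an exact
    linear function of the built-in descriptors."""
    path = tmp_path / "train.sdf"
    truth = gen_toy_sdf(30, seed=1, path=path)
    return path, truth


@pytest.fixture(autouse=True)
def _clean_stage_registry():
    yield
    workflows._REGISTRY.clear()


# ---------------------------------------------------------------------------
# independent oracles (no NIPALS code shared with the engine)
# ---------------------------------------------------------------------------

def krylov_pls_coef(Xs: np.ndarray, yc: np.ndarray, A: int) -> np.ndarray:
    """PLS1 coefficients at A components via the Krylov-subspace
    characterization: b = argmin ||yc - Xs b|| over span{v, Gv, ..., G^(A-1)v}
    with v = Xs'yc and G = Xs'Xs."""
    G = Xs.T @ Xs
    v = Xs.T @ yc
    K = [v]
    for _ in range(A - 1):
        K.append(G @ K[-1])
    K = np.column_stack(K)
    Q, _ = np.linalg.qr(K)
    M = Q.T @ G @ Q
    return Q @ np.linalg.solve(M, Q.T @ v)


def loo_oracle(X: np.ndarray, y: np.ndarray, A_max: int, scaling: str = "autoscale"):
    """Brute-force LOO: per fold, re-fit scaling and Krylov-PLS from
    scratch, predict the left-out sample at every dimensionality."""
    n, p = X.shape
    A_max = min(A_max, n - 2, p)
    loo_pred = np.zeros((n, A_max))
    for i in range(n):
        keep = np.arange(n) != i
        Xs, state = scale_fit(X[keep], scaling)
        ym = float(y[keep].mean())
        yc = y[keep] - ym
        xq = state.apply(X[i : i + 1]).ravel()
        for a in range(1, A_max + 1):
            b = krylov_pls_coef(Xs, yc, a)
            loo_pred[i, a - 1] = ym + xq @ b
    press = np.sum((y[:, None] - loo_pred) ** 2, axis=0)
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss, np.sqrt(press / n), loo_pred


def cutoff_oracle(scores: np.ndarray, labels: np.ndarray):
    """Exhaustive scan of all adjacent-midpoint cutoffs."""
    uniq = np.unique(scores)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else uniq
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best = None
    for cut in candidates:
        pred = scores >= cut
        se = (pred & (labels == 1)).sum() / n_pos
        sp = (~pred & (labels == 0)).sum() / n_neg
        key = (abs(se - sp), -(se + sp), cut)
        if best is None or key < best[0]:
            best = (key, float(cut), se, sp)
    return best[1], best[2], best[3]
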