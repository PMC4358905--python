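"""Variable selection driven by a two-level design with dummy variables.

Each design row switches a subset of variables on; the cross-validated
error of the reduced model is recorded and per-variable effects are
contrasted with the effect scale of data-free dummy columns.  Variables
whose exclusion reliably lowers the error are dropped, and the reduction
is kept only if cross-validated q2 does not decrease.

A seeded balanced random two-level design of the conventional size is
used instead of a strict fractional factorial, which would constrain
p + dummies to specific run counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import hadamard

from .mva import loo_cv

__all__ = ["FFDResult", "build_design", "ffd_select"]


@dataclass
class FFDResult:
    design: np.ndarray
    effects: np.ndarray
    dummy_effects: np.ndarray
    dummy_effect_scale: float
    mask: np.ndarray
    q2_before: float
    q2_after: float
    applied: bool
    warnings: list


def build_design(p: int, d: int, R: int, seed: int = 0) -> np.ndarray:
    """R x (p+d) matrix of +/-1 with every column balanced (R/2 each sign).

    Rows come in mirror pairs (each row followed later by its sign-flip)
    drawn from randomly signed/permuted Hadamard blocks: columns are
    balanced by construction and main-effect contrasts are free of
    two-factor interaction bias within each full block.
    """
    if R % 2 != 0:
        raise ValueError("number of design rows R must be even")
    if R < 2:
        raise ValueError("R must be >= 2")
    if d < 1:
        raise ValueError("at least one dummy variable is required")
    m = p + d
    size = 1
    while size < m + 1:
        size *= 2
    rng = np.random.default_rng(seed)
    rows = []
    remaining = R
    while remaining > 0:
        H = hadamard(size)
        cols = rng.permutation(np.arange(1, size))[:m]
        signs = rng.choice([-1, 1], size=m)
        block = H[:, cols] * signs
        take = min(size, remaining // 2)
        rows.append(block[:take])
        rows.append(-block[:take])
        remaining -= 2 * take
    return np.vstack(rows).astype(int)


def _row_sdep(X, y, included, A, scaling):
    """LOO SDEP at dimensionality A for the variable subset of one design row."""
    k = int(included.sum())
    n = X.shape[0]
    if k == 0:
        # null model: predict the mean
        return float(np.std(y, ddof=0))
    A_row = max(1, min(A, k, n - 2))
    _, sdep, _ = loo_cv(X[:, included], y, A_row, scaling=scaling)
    return float(sdep[min(A_row, sdep.shape[0]) - 1])


def ffd_select(
    X: np.ndarray,
    y: np.ndarray,
    A: int,
    d: Optional[int] = None,
    R: Optional[int] = None,
    threshold_factor: float = 2.0,
    seed: int = 0,
    scaling: str = "autoscale",
) -> FFDResult:
    """One-pass design-based variable selection.

    effect(v) = mean SDEP over rows excluding v minus mean over rows
    including v (positive => the variable helps).  A variable is removed
    iff its effect is negative and exceeds ``threshold_factor`` times the
    mean absolute dummy effect in magnitude.  The reduced mask is kept
    only when q2 does not decrease; otherwise the all-true mask is
    returned with ``applied=False``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 4:
        raise ValueError("FFD selection requires at least 4 variables")
    if n < 5:
        raise ValueError("FFD selection requires at least 5 samples")
    if d is None:
        d = max(1, round(p / 5))
    if R is None:
        # effect estimates need many runs to resolve weak per-variable
        # signals against the dummy noise floor; 32(p+d) is affordable with
        # the vectorized LOO and keeps the dummy scale tight
        R = 32 * (p + d)
    design = build_design(p, d, R, seed)
    warnings: list = []

    sdeps = np.empty(R)
    for r in range(R):
        included = design[r, :p] == 1
        sdeps[r] = _row_sdep(X, y, included, A, scaling)

    effects = np.empty(p + d)
    for v in range(p + d):
        inc = design[:, v] == 1
        effects[v] = sdeps[~inc].mean() - sdeps[inc].mean()
    var_effects = effects[:p]
    dummy_effects = effects[p:]
    # median rather than mean: a single outlier dummy must not blow up the
    # removal threshold
    dummy_scale = float(np.median(np.abs(dummy_effects)))

    remove = (var_effects < 0) & (np.abs(var_effects) > threshold_factor * dummy_scale)
    mask = ~remove
    if not mask.any():
        keep = int(np.argmax(var_effects))
        mask[keep] = True
        warnings.append("all variables flagged for removal; keeping best-effect variable")

    A_full = max(1, min(A, p, n - 2))
    q2_full, _, _ = loo_cv(X, y, A_full, scaling=scaling)
    q2_before = float(q2_full[A_full - 1])

    k = int(mask.sum())
    A_red = max(1, min(A, k, n - 2))
    q2_red, _, _ = loo_cv(X[:, mask], y, A_red, scaling=scaling)
    q2_after = float(q2_red[A_red - 1])

    applied = False
    if not mask.all():
        if q2_after >= q2_before:
            applied = True
        else:
            mask = np.ones(p, dtype=bool)
            q2_after = q2_before
            warnings.append("reduced model did not improve q2; selection reverted")

    return FFDResult(
        design=design,
        effects=var_effects,
        dummy_effects=dummy_effects,
        dummy_effect_scale=dummy_scale,
        mask=mask,
        q2_before=q2_before,
        q2_after=q2_after,
        applied=applied,
        warnings=warnings,
    )
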