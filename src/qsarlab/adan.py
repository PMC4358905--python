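"""Applicability-domain / reliability assessment.

Six training-derived criteria are each thresholded at their 95th
percentile over the training set; the number of violated criteria (0-6)
is the reliability category, which maps to an empirical 95% CI
half-width derived from the LOO residuals of the training compounds in
the same category.

The six-criterion scheme here is a documented reconstruction at the
granularity of the published method (six criteria, categories 0-6, 95th
percentile thresholds); its exact formulas were not published alongside
the framework this package follows.  Criteria:

1. Euclidean distance to the descriptor-space centroid (scaled space).
2. Distance to the nearest training neighbor in scaled descriptor space
   (self-excluded on the training set).
3. Distance to the score-space centroid.
4. Nearest-neighbor distance in score space (self-excluded).
5. DModX: residual norm after projection on the model's A_opt
   components, sqrt(e'e / (p - A_opt)).
6. SD of the activities of the k nearest score-space neighbors
   (self-excluded).

Percentiles use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .mva import PLSModel, transform_scores

__all__ = ["ADANState", "fit_adan", "criterion_values", "assess", "ci95"]

N_CRITERIA = 6


@dataclass
class ADANState:
    thresholds: np.ndarray          # length 6
    x_centroid: np.ndarray          # scaled descriptor space
    t_centroid: np.ndarray          # score space, A_opt dims
    loadings: np.ndarray            # p x A_opt (for DModX residuals)
    weights: np.ndarray             # p x A_opt (for score projection)
    training_Xs: np.ndarray
    training_T: np.ndarray
    training_y: np.ndarray
    k_nn: int
    category_ci95: np.ndarray       # length 7
    training_categories: np.ndarray


def _query_criteria(
    x_scaled: np.ndarray,
    t_query: np.ndarray,
    x_centroid: np.ndarray,
    t_centroid: np.ndarray,
    loadings: np.ndarray,
    Xs_ref: np.ndarray,
    T_ref: np.ndarray,
    y_ref: np.ndarray,
    k_nn: int,
) -> np.ndarray:
    p = x_scaled.shape[0]
    a_opt = loadings.shape[1]
    c1 = float(np.linalg.norm(x_scaled - x_centroid))
    c2 = float(np.min(np.linalg.norm(Xs_ref - x_scaled, axis=1)))
    c3 = float(np.linalg.norm(t_query - t_centroid))
    dt = np.linalg.norm(T_ref - t_query, axis=1)
    c4 = float(np.min(dt))
    resid = x_scaled - loadings @ t_query
    dof = max(p - a_opt, 1)
    c5 = float(np.sqrt(resid @ resid / dof))
    nn = np.argsort(dt, kind="stable")[:k_nn]
    c6 = float(np.std(y_ref[nn], ddof=0))
    return np.array([c1, c2, c3, c4, c5, c6])


def fit_adan(
    model: PLSModel,
    Xs: np.ndarray,
    y: np.ndarray,
    k_nn: int = 5,
) -> ADANState:
    """Derive thresholds and per-category CI half-widths from the training set.

    ``Xs`` is the scaled training matrix the model was fitted on.  For each
    training compound the six criterion values are computed with the
    compound itself excluded from neighbor searches; thresholds are the
    95th empirical percentiles.  category_ci95[c] is 1.96 times the RMSE
    of the LOO residuals (at A_opt) of the training compounds in category
    c, falling back to 1.96 times the global SDEP(A_opt) when fewer than 5
    compounds occupy the category.
    """
    Xs = np.asarray(Xs, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xs.shape
    if n < 10:
        raise ValueError("training series too small for ADAN (n >= 10 required)")
    if k_nn > n - 1:
        raise ValueError(f"k_nn={k_nn} exceeds n-1={n - 1}")
    a_opt = model.A_opt
    W = model.W[:, :a_opt]
    P = model.P[:, :a_opt]
    T = transform_scores(model.core, Xs, a_opt)

    x_centroid = Xs.mean(axis=0)
    t_centroid = T.mean(axis=0)

    dx = cdist(Xs, Xs)
    dtm = cdist(T, T)
    np.fill_diagonal(dx, np.inf)
    np.fill_diagonal(dtm, np.inf)

    crit = np.empty((n, N_CRITERIA))
    crit[:, 0] = np.linalg.norm(Xs - x_centroid, axis=1)
    crit[:, 1] = dx.min(axis=1)
    crit[:, 2] = np.linalg.norm(T - t_centroid, axis=1)
    crit[:, 3] = dtm.min(axis=1)
    resid = Xs - T @ P.T
    dof = max(p - a_opt, 1)
    crit[:, 4] = np.sqrt(np.sum(resid * resid, axis=1) / dof)
    order = np.argsort(dtm, axis=1, kind="stable")[:, :k_nn]
    crit[:, 5] = np.std(y[order], axis=1, ddof=0)

    thresholds = np.percentile(crit, 95, axis=0, method="linear")
    training_categories = np.sum(crit > thresholds, axis=1)

    loo_resid = y - model.loo_pred[:, a_opt - 1]
    global_hw = 1.96 * float(model.sdep[a_opt - 1])
    category_ci95 = np.empty(N_CRITERIA + 1)
    for c in range(N_CRITERIA + 1):
        members = training_categories == c
        if members.sum() >= 5:
            category_ci95[c] = 1.96 * float(np.sqrt(np.mean(loo_resid[members] ** 2)))
        else:
            category_ci95[c] = global_hw
    # degenerate guard: a zero half-width would claim exact predictions
    category_ci95[category_ci95 <= 0] = max(global_hw, 1e-12)

    return ADANState(
        thresholds=thresholds,
        x_centroid=x_centroid,
        t_centroid=t_centroid,
        loadings=P,
        weights=W,
        training_Xs=Xs,
        training_T=T,
        training_y=y,
        k_nn=k_nn,
        category_ci95=category_ci95,
        training_categories=training_categories,
    )


def criterion_values(x_query_scaled: np.ndarray, t_query: np.ndarray, state: ADANState) -> np.ndarray:
    """The six criterion values of one scaled query vector."""
    x = np.asarray(x_query_scaled, dtype=float).ravel()
    t = np.asarray(t_query, dtype=float).ravel()
    if x.shape[0] != state.training_Xs.shape[1]:
        raise ValueError("query descriptor dimension does not match the model")
    if t.shape[0] != state.training_T.shape[1]:
        raise ValueError("query score dimension does not match the model")
    return _query_criteria(
        x, t, state.x_centroid, state.t_centroid, state.loadings,
        state.training_Xs, state.training_T, state.training_y, state.k_nn,
    )


def assess(x_query_scaled: np.ndarray, t_query: np.ndarray, state: ADANState) -> int:
    """Reliability category 0-6: the number of violated criteria."""
    values = criterion_values(x_query_scaled, t_query, state)
    return int(np.sum(values > state.thresholds))


def ci95(category: int, state: ADANState) -> float:
    """95% CI half-width mapped from a reliability category."""
    if not 0 <= category <= N_CRITERIA:
        raise ValueError(f"category must be in 0..{N_CRITERIA}, got {category}")
    return float(state.category_ci95[category])
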