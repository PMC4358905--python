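"""In-house multivariate engine: NIPALS PCA / PLS1, LOO cross-validation,
discriminant cutoff estimation and fit diagnostics.

The PLS implementation is single-response NIPALS with X-side deflation only;
for one response the y-deflation step is algebraically redundant and is
omitted.  Coefficient vectors ``B[:, A-1]`` reconstruct the A-component
model as ``W (P'W)^-1 c`` so that predictions can be made with a single
matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500

__all__ = [
    "ScalingState",
    "PLSCore",
    "PLSModel",
    "scale_fit",
    "fit_pls",
    "predict_via_wpc",
    "transform_scores",
    "loo_cv",
    "select_A_opt",
    "estimate_cutoff",
    "fit_pca",
    "build_pls_model",
    "predict_model",
    "plot_fit",
]


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingState:
    """Column centering/scaling learned on a training matrix.

    ``scales`` are all 1 unless mode is ``autoscale`` (sample SD, n-1
    divisor).  ``apply`` followed by ``invert`` is the identity.
    """

    mode: str
    means: np.ndarray
    scales: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.scales

    def invert(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self.scales + self.means


def scale_fit(X: np.ndarray, mode: str = "autoscale") -> tuple[np.ndarray, ScalingState]:
    """Fit centering/scaling on ``X`` and return the transformed matrix.

    mode ``none``     : identity (means 0, scales 1)
    mode ``center``   : subtract column means
    mode ``autoscale``: center and divide by sample SD (n-1 divisor)
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n, p = X.shape
    if n < 2:
        raise ValueError("scaling requires at least 2 rows")
    if mode not in ("none", "center", "autoscale"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    if mode == "none":
        state = ScalingState(mode, np.zeros(p), np.ones(p))
        return X.copy(), state
    means = X.mean(axis=0)
    if mode == "center":
        state = ScalingState(mode, means, np.ones(p))
        return X - means, state
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 0.0):
        bad = int(np.flatnonzero(sd <= 0.0)[0])
        raise ValueError(
            f"autoscale: column {bad} has zero variance (mask constant columns first)"
        )
    state = ScalingState(mode, means, sd)
    return (X - means) / sd, state


# ---------------------------------------------------------------------------
# PLS1 core
# ---------------------------------------------------------------------------

@dataclass
class PLSCore:
    """Raw NIPALS-PLS1 decomposition.

    W, P are p x A; c is length A; T is n x A; B is p x A where column
    ``a`` holds the coefficients of the (a+1)-component model in the
    (scaled) space the fit was run in.
    """

    W: np.ndarray
    P: np.ndarray
    c: np.ndarray
    T: np.ndarray
    B: np.ndarray
    A: int  # effective number of components (may be < requested)


def fit_pls(Xs: np.ndarray, ys: np.ndarray, A_max: int) -> PLSCore:
    """NIPALS PLS1 on (centered) ``Xs``, ``ys`` with up to ``A_max`` components.

    Stops early when the X'y covariance or score norm collapses (y residual
    numerically exhausted); the effective component count is recorded in the
    result.
    """
    X = np.array(Xs, dtype=float)
    y = np.asarray(ys, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y row counts differ")
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    A_max = min(A_max, n - 1, p)

    W = np.zeros((p, A_max))
    Pl = np.zeros((p, A_max))
    c = np.zeros(A_max)
    T = np.zeros((n, A_max))
    yss0 = float(y @ y)
    eps = max(yss0, 1.0) * 1e-24

    A = 0
    for a in range(A_max):
        xty = X.T @ y
        cov = float(xty @ xty)
        if cov <= eps:
            break
        w = xty / np.sqrt(cov)
        t = X @ w
        tt = float(t @ t)
        if tt <= 1e-24:
            break
        pvec = (X.T @ t) / tt
        ca = float(t @ y) / tt
        W[:, a] = w
        Pl[:, a] = pvec
        c[a] = ca
        T[:, a] = t
        X -= np.outer(t, pvec)
        A = a + 1

    if A == 0:
        raise ValueError("no PLS component could be extracted (y residual ~ 0)")
    W, Pl, c, T = W[:, :A], Pl[:, :A], c[:A], T[:, :A]

    # B[:, a] = W_a (P_a' W_a)^{-1} c_a  (P'W is unit upper triangular)
    B = np.zeros((p, A))
    PtW = Pl.T @ W
    for a in range(A):
        sub = PtW[: a + 1, : a + 1]
        B[:, a] = W[:, : a + 1] @ np.linalg.solve(sub, c[: a + 1])
    return PLSCore(W=W, P=Pl, c=c, T=T, B=B, A=A)


def transform_scores(core: PLSCore, Xs: np.ndarray, A: Optional[int] = None) -> np.ndarray:
    """Project (scaled, centered) rows onto the model's score space."""
    A = core.A if A is None else min(A, core.A)
    X = np.array(np.atleast_2d(Xs), dtype=float)
    T = np.zeros((X.shape[0], A))
    for a in range(A):
        t = X @ core.W[:, a]
        T[:, a] = t
        X -= np.outer(t, core.P[:, a])
    return T


def predict_via_wpc(core: PLSCore, Xs: np.ndarray, A: Optional[int] = None) -> np.ndarray:
    """Predict (centered-scale response) by sequential score extraction."""
    A = core.A if A is None else min(A, core.A)
    T = transform_scores(core, Xs, A)
    return T @ core.c[:A]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _fit_quality(y: np.ndarray, yhat_per_A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """r2 and SDEC per dimensionality; TSS about the data mean."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = np.sum((y[:, None] - yhat_per_A) ** 2, axis=0)
    r2 = 1.0 - rss / tss if tss > 0 else np.full(yhat_per_A.shape[1], np.nan)
    sdec = np.sqrt(rss / n)
    return r2, sdec


def loo_cv(
    X: np.ndarray,
    y: np.ndarray,
    A_max: int,
    mode: str = "regression",
    scaling: str = "autoscale",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-out cross-validation with per-fold re-scaling and re-fitting.

    Returns ``(q2, sdep, loo_pred)`` where ``loo_pred[i, a]`` is the
    prediction of sample i by the (a+1)-component model fitted without it.
    SDEP(A) = sqrt(PRESS(A)/n); q2(A) = 1 - PRESS(A)/TSS with TSS about the
    full-data mean.  A_max is truncated to n-2 (each fold must keep n-1 >= 2
    usable samples).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("LOO cross-validation requires n >= 3")
    A_max = min(A_max, n - 2, p)
    if A_max < 1:
        A_max = 1

    # all folds fitted at once: NIPALS-PLS1 is non-iterative per component,
    # so the per-fold fit vectorizes exactly over a (fold, sample, var) stack
    keep = ~np.eye(n, dtype=bool)
    Xf = X[np.where(keep)[1].reshape(n, n - 1)]      # (n, n-1, p)
    yf = y[np.where(keep)[1].reshape(n, n - 1)]      # (n, n-1)

    means = Xf.mean(axis=1)
    if scaling == "autoscale":
        scales = Xf.std(axis=1, ddof=1)
        scales[scales <= 0.0] = 1.0  # fold-constant column: centered to zero anyway
    elif scaling == "center":
        scales = np.ones_like(means)
    elif scaling == "none":
        means = np.zeros_like(means)
        scales = np.ones_like(means)
    else:
        raise ValueError(f"unknown scaling mode {scaling!r}")
    Xf = (Xf - means[:, None, :]) / scales[:, None, :]
    xq = (X - means) / scales                        # (n, p) left-out rows
    ym = yf.mean(axis=1)
    yc = yf - ym[:, None]

    loo_pred = np.empty((n, A_max))
    pred = ym.copy()
    active = np.ones(n, dtype=bool)
    yss = np.einsum("fi,fi->f", yc, yc)
    eps = np.maximum(yss, 1.0) * 1e-24
    for a in range(A_max):
        xty = np.einsum("fij,fi->fj", Xf, yc)
        cov = np.einsum("fj,fj->f", xty, xty)
        active &= cov > eps
        norm = np.where(active, np.sqrt(np.maximum(cov, 1e-300)), 1.0)
        w = xty / norm[:, None]
        t = np.einsum("fij,fj->fi", Xf, w)
        tt = np.einsum("fi,fi->f", t, t)
        active &= tt > 1e-24
        tt_safe = np.where(active, tt, 1.0)
        pvec = np.einsum("fij,fi->fj", Xf, t) / tt_safe[:, None]
        c = np.einsum("fi,fi->f", t, yc) / tt_safe
        Xf -= t[:, :, None] * pvec[:, None, :]
        tq = np.einsum("fj,fj->f", xq, w)
        xq = xq - tq[:, None] * pvec
        pred = np.where(active, pred + c * tq, pred)
        loo_pred[:, a] = pred
    press = np.sum((y[:, None] - loo_pred) ** 2, axis=0)
    tss = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / tss if tss > 0 else np.full(A_max, np.nan)
    sdep = np.sqrt(press / n)
    return q2, sdep, loo_pred


def select_A_opt(q2: np.ndarray) -> int:
    """Dimensionality with the highest q2 (1-based); ties -> smallest A."""
    q2 = np.asarray(q2, dtype=float)
    if q2.size == 0:
        raise ValueError("q2 vector is empty")
    return int(np.argmax(q2)) + 1


def estimate_cutoff(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Class cutoff balancing sensitivity and specificity.

    Candidates are midpoints of adjacent sorted unique scores.  The chosen
    cutoff minimizes |sensitivity - specificity|; ties are broken by the
    larger sensitivity + specificity, then by the smaller cutoff.  Predicted
    class is 1 iff score >= cutoff.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("cutoff estimation requires both classes present")
    uniq = np.unique(scores)
    if uniq.size == 1:
        candidates = np.array([uniq[0]])
    else:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for cut in candidates:
        pred = scores >= cut
        se = float(np.sum(pred & (labels == 1))) / n_pos
        sp = float(np.sum(~pred & (labels == 0))) / n_neg
        key = (abs(se - sp), -(se + sp), cut)
        if best is None or key < best[0]:
            best = (key, float(cut), se, sp)
    _, cutoff, se, sp = best
    return cutoff, se, sp


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(Xs: np.ndarray, A: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS PCA on a centered matrix.

    Returns (scores n x A, loadings p x A orthonormal, explained variance
    fraction per component).
    """
    X = np.array(Xs, dtype=float)
    n, p = X.shape
    A = min(A, n - 1, p)
    total_ss = float(np.sum(X * X))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    ev = np.zeros(A)
    for a in range(A):
        col = int(np.argmax(np.sum(X * X, axis=0)))
        t = X[:, col].copy()
        if float(t @ t) <= 1e-30:
            T, P, ev = T[:, :a], P[:, :a], ev[:a]
            break
        for _ in range(NIPALS_MAX_ITER):
            pvec = X.T @ t
            pvec /= np.linalg.norm(pvec)
            t_new = X @ pvec
            if np.linalg.norm(t_new - t) < NIPALS_TOL * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                break
            t = t_new
        P[:, a] = pvec
        T[:, a] = t
        ev[a] = float(t @ t) / total_ss if total_ss > 0 else 0.0
        X -= np.outer(t, pvec)
    return T, P, ev


# ---------------------------------------------------------------------------
# full model assembly
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted PLS model plus validation arrays and scaling metadata.

    Coefficients live in two spaces: ``B`` (per-dimensionality, scaled
    space) and ``coefficients_raw``/``intercept_raw`` (original descriptor
    units at ``A_opt``), so predictions can be made from either.
    """

    W: np.ndarray
    P: np.ndarray
    c: np.ndarray
    T: np.ndarray
    B: np.ndarray
    scaling: ScalingState
    y_mean: float
    A_max: int
    A_opt: int
    r2: np.ndarray
    q2: np.ndarray
    sdec: np.ndarray
    sdep: np.ndarray
    loo_pred: np.ndarray
    mode: str = "regression"
    cutoff: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    coefficients_raw: np.ndarray = field(default=None)  # type: ignore[assignment]
    intercept_raw: float = 0.0

    @property
    def core(self) -> PLSCore:
        return PLSCore(W=self.W, P=self.P, c=self.c, T=self.T, B=self.B, A=self.A_max)

    def predict(self, X_raw: np.ndarray, A: Optional[int] = None) -> np.ndarray:
        """Numeric prediction for raw (unscaled, aligned) descriptor rows."""
        A = self.A_opt if A is None else min(A, self.A_max)
        Xs = self.scaling.apply(np.atleast_2d(X_raw))
        return Xs @ self.B[:, A - 1] + self.y_mean

    def predict_class(self, X_raw: np.ndarray) -> np.ndarray:
        if self.mode != "discriminant":
            raise ValueError("predict_class requires a discriminant model")
        return (self.predict(X_raw) >= self.cutoff).astype(int)


def build_pls_model(
    X: np.ndarray,
    y: np.ndarray,
    mode: str = "regression",
    scaling: str = "autoscale",
    A_max: Optional[int] = None,
) -> PLSModel:
    """Scale, fit, LOO-validate and assemble a complete PLS model.

    In discriminant mode y must be 0/1; the cutoff is estimated on the LOO
    predictions at A_opt (not the refitted scores) to avoid optimism.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if mode not in ("regression", "discriminant"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "discriminant" and not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("discriminant mode requires 0/1 activities")
    if A_max is None:
        A_max = min(n - 1, p, 10)
    A_max = max(1, min(A_max, n - 2, p))

    Xs, state = scale_fit(X, scaling)
    y_mean = float(y.mean())
    core = fit_pls(Xs, y - y_mean, A_max)
    A_eff = core.A

    yhat = Xs @ core.B + y_mean  # n x A_eff fitted values
    r2, sdec = _fit_quality(y, yhat)
    q2, sdep, loo_pred = loo_cv(X, y, A_eff, mode=mode, scaling=scaling)
    A_eff = min(A_eff, q2.shape[0])
    A_opt = select_A_opt(q2[:A_eff])

    b_opt = core.B[:, A_opt - 1]
    coef_raw = b_opt / state.scales
    intercept_raw = y_mean - float(state.means @ coef_raw)

    cutoff = se = sp = None
    if mode == "discriminant":
        cutoff, se, sp = estimate_cutoff(loo_pred[:, A_opt - 1], y.astype(int))

    return PLSModel(
        W=core.W[:, :A_eff],
        P=core.P[:, :A_eff],
        c=core.c[:A_eff],
        T=core.T[:, :A_eff],
        B=core.B[:, :A_eff],
        scaling=state,
        y_mean=y_mean,
        A_max=A_eff,
        A_opt=A_opt,
        r2=r2[:A_eff],
        q2=q2[:A_eff],
        sdec=sdec[:A_eff],
        sdep=sdep[:A_eff],
        loo_pred=loo_pred[:, :A_eff],
        mode=mode,
        cutoff=cutoff,
        sensitivity=se,
        specificity=sp,
        coefficients_raw=coef_raw,
        intercept_raw=intercept_raw,
    )


def predict_model(model: PLSModel, X_raw: np.ndarray, A: Optional[int] = None) -> np.ndarray:
    return model.predict(X_raw, A)


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_fit(y, y_recalculated, y_loo_predicted, path_prefix) -> list:
    """Write experimental-vs-recalculated and experimental-vs-predicted
    scatter plots (PNG) with an identity line; returns the file paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("cannot plot empty vectors")
    series = [("recalculated", np.asarray(y_recalculated, dtype=float)),
              ("predicted", np.asarray(y_loo_predicted, dtype=float))]
    paths = []
    for label, v in series:
        if v.shape != y.shape:
            raise ValueError("vector lengths differ")
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(y, v, s=18)
        lo = float(min(y.min(), v.min()))
        hi = float(max(y.max(), v.max()))
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel("experimental")
        ax.set_ylabel(label)
        out = f"{path_prefix}-{label}.png"
        fig.savefig(out, dpi=100)
        plt.close(fig)
        paths.append(out)
    return paths
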