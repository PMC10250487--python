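"""Latent-variable models and discriminant classifiers.

Everything latent here is written from the algorithm definitions: NIPALS
PCA, NIPALS PLS2 discriminant analysis, OPLS-DA with an orthogonal signal
correction filter, S-plot covariance/correlation marker selection, VIP
scores, LDA / PCA-LDA and k-nearest neighbours. Random Forest and SVM are
deliberately not re-implemented; :class:`SklearnAdapter` plugs any external
fit/predict estimator into the same evaluation machinery.

Conventions
-----------
* Class labels are sorted lexicographically; one-hot Y columns follow that
  order, and argmax ties resolve to the lowest class index with a logged
  warning.
* NIPALS tolerance 1e-10, at most 500 iterations, deterministic
  initialization from the column of maximal variance.
* R2X / R2Y are training explained-variance fractions; Q2 is the
  cross-validated 1 - PRESS/SS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500
_EPS = np.finfo(float).eps


class DegenerateLabelError(ValueError):
    pass


class RankError(ValueError):
    pass


class SingularCovarianceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# helpers


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _center_scale(X: np.ndarray, center: bool, scale: str):
    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    if scale == "none":
        sc = np.ones(X.shape[1])
    elif scale in ("uv", "pareto"):
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        sc = sd if scale == "uv" else np.sqrt(sd)
    else:
        raise ValueError(f"unknown scale mode {scale!r}")
    return (X - mean) / sc, mean, sc


def _one_hot(y):
    y = np.asarray(y)
    classes = sorted(pd.unique(pd.Series(y)).tolist())
    if len(classes) < 2:
        raise DegenerateLabelError("need at least two classes")
    Y = np.zeros((y.size, len(classes)))
    for j, c in enumerate(classes):
        Y[y == c, j] = 1.0
    return Y, classes


def _argmax_labels(scores: np.ndarray, classes) -> np.ndarray:
    ismax = scores == scores.max(axis=1, keepdims=True)
    ties = int((ismax.sum(axis=1) > 1).sum())
    if ties:
        log.warning("%d prediction tie(s) broken toward the lowest class index", ties)
    return np.asarray(classes, dtype=object)[scores.argmax(axis=1)]


@dataclass
class LatentModel:
    """Scores/loadings/weights of a fitted PCA, PLS-DA or OPLS-DA model
    plus variance bookkeeping. Orthogonal parts are populated for OPLS
    only."""

    kind: str
    mean: np.ndarray
    scale: np.ndarray
    T: np.ndarray
    P: np.ndarray
    W: np.ndarray | None = None
    C: np.ndarray | None = None           # Y loadings, (n_classes x a)
    T_o: np.ndarray | None = None
    P_o: np.ndarray | None = None
    W_o: np.ndarray | None = None
    coef: np.ndarray | None = None
    classes: list | None = None
    y_mean: np.ndarray | None = None
    r2x: float | None = None
    r2y: float | None = None
    q2: float | None = None
    explained_variance: np.ndarray | None = None  # per component (PCA)
    ssy: np.ndarray | None = None                 # explained Y SS per comp
    resid_ss_rows: np.ndarray | None = None       # training DModX material
    columns: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.T.shape[1]

    def x_scores(self, X) -> np.ndarray:
        """Project new rows onto the model's (predictive) score space."""
        Xc = (self._align(X) - self.mean) / self.scale
        Xc = self._osc_filter(Xc)
        if self.W is None:
            return Xc @ self.P
        R = self.W @ np.linalg.inv(self.P.T @ self.W)
        return Xc @ R

    def x_residual_ss(self, X) -> np.ndarray:
        """Row-wise squared residual distance to the model plane."""
        Xc = (self._align(X) - self.mean) / self.scale
        Xc = self._osc_filter(Xc)
        T = self.x_scores(X)
        E = Xc - T @ self.P.T
        return (E**2).sum(axis=1)

    def _osc_filter(self, Xc: np.ndarray) -> np.ndarray:
        if self.W_o is None:
            return Xc
        Xc = Xc.copy()
        for j in range(self.W_o.shape[1]):
            t_o = Xc @ self.W_o[:, j]
            Xc -= np.outer(t_o, self.P_o[:, j])
        return Xc

    def _align(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame) and self.columns:
            if list(X.columns) != list(self.columns):
                X = X[self.columns]
        return _as_array(X)


# ---------------------------------------------------------------------------
# PCA


def nipals_pca(
    X,
    n_components: int,
    tol: float = NIPALS_TOL,
    max_iter: int = NIPALS_MAX_ITER,
    center: bool = True,
    scale: str = "none",
) -> LatentModel:
    """NIPALS principal component extraction with deflation.

    Per-component explained variance is ||t p'||_F^2 / ||X||_F^2 and
    R2X(cum) their sum. Non-convergence raises a warning through the
    ``logging`` channel and keeps the component as-is.
    """
    frame = X if isinstance(X, pd.DataFrame) else None
    X = _as_array(X)
    Xc, mean, sc = _center_scale(X, center, scale)
    total = float((Xc**2).sum())
    if total <= 0:
        raise ValueError("zero-variance matrix")
    n_components = min(n_components, X.shape[0] - 1 if center else X.shape[0],
                       X.shape[1])
    E = Xc.copy()
    T, P, evr = [], [], []
    for _ in range(n_components):
        col_var = (E**2).sum(axis=0)
        j0 = int(col_var.argmax())
        if col_var[j0] <= total * 1e-14:
            break
        t = E[:, j0].copy()
        for it in range(max_iter):
            p = E.T @ t / (t @ t)
            p /= np.linalg.norm(p)
            t_new = E @ p
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), _EPS):
                t = t_new
                break
            t = t_new
        else:
            log.warning("NIPALS PCA component did not converge in %d iterations",
                        max_iter)
        E -= np.outer(t, p)
        T.append(t)
        P.append(p)
        evr.append(float(t @ t) / total)
    T = np.column_stack(T)
    P = np.column_stack(P)
    return LatentModel(
        kind="PCA",
        mean=mean,
        scale=sc,
        T=T,
        P=P,
        r2x=float(np.sum(evr)),
        explained_variance=np.asarray(evr),
        resid_ss_rows=(E**2).sum(axis=1),
        columns=list(frame.columns) if frame is not None else [],
    )


def q2_cv(
    X,
    n_components: int,
    y=None,
    folds: int = 7,
    seed: int = 0,
    center: bool = True,
    scale: str = "none",
):
    """Cross-validated Q2 with row-wise fold exclusion.

    PCA mode (``y is None``): per-component PRESS against the full-data
    residual SS, cumulative Q2 = 1 - prod(PRESS_a / SS_{a-1}).
    PLS mode: one-hot (or continuous) Y, cumulative Q2_a = 1 - PRESS_a/SS(Y)
    per retained component count.

    Returns ``(q2_per_component, q2_cum)`` where q2_cum is the final scalar.
    """
    X = _as_array(X)
    n = X.shape[0]
    if folds < 2 or folds > n:
        raise ValueError("folds must be between 2 and n")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for i, idx in enumerate(order):
        fold_of[idx] = i % folds

    if y is None:
        return _q2_pca(X, n_components, fold_of, folds, center, scale)
    return _q2_pls(X, y, n_components, fold_of, folds, center, scale)


def _q2_pca(X, a, fold_of, folds, center, scale):
    Xc, _, _ = _center_scale(X, center, scale)
    # full-data reference residual SS per component count (SVD = exact PCA)
    a = min(a, X.shape[0] - 1, X.shape[1])
    _, s, _ = np.linalg.svd(Xc, full_matrices=False)
    ss = [float((Xc**2).sum())]
    for i in range(a):
        ss.append(ss[-1] - float(s[i] ** 2))
    press = np.zeros(a)
    for f in range(folds):
        tr, te = fold_of != f, fold_of == f
        Xtr, mean, sc = _center_scale(X[tr], center, scale)
        _, _, Vt = np.linalg.svd(Xtr, full_matrices=False)
        E = (X[te] - mean) / sc
        for i in range(a):
            p = Vt[i]
            E = E - np.outer(E @ p, p)
            press[i] += float((E**2).sum())
    ratios = press / np.maximum(np.asarray(ss[:a]), _EPS)
    q2_comp = 1.0 - ratios
    q2_cum = 1.0 - float(np.prod(ratios))
    return q2_comp, q2_cum


def _q2_pls(X, y, a, fold_of, folds, center, scale):
    y = np.asarray(y)
    if y.dtype.kind in "OUSb":
        Y, _ = _one_hot(y)
    else:  # continuous response
        Y = y.astype(float)
        if Y.ndim == 1:
            Y = Y[:, None]
    press = np.zeros(a)
    ss = 0.0
    for f in range(folds):
        tr, te = fold_of != f, fold_of == f
        Xtr, mean, sc = _center_scale(X[tr], center, scale)
        y_mean = Y[tr].mean(axis=0)
        core = _pls2_core(Xtr, Y[tr] - y_mean, a)
        E = (X[te] - mean) / sc
        Yhat = np.tile(y_mean, (te.sum(), 1))
        ss += float(((Y[te] - y_mean) ** 2).sum())
        for i in range(core["W"].shape[1]):
            t = E @ core["W"][:, i]
            E = E - np.outer(t, core["P"][:, i])
            Yhat = Yhat + np.outer(t, core["C"][:, i])
            press[i] += float(((Y[te] - Yhat) ** 2).sum())
        for i in range(core["W"].shape[1], a):
            press[i] += float(((Y[te] - Yhat) ** 2).sum())
    q2_comp = 1.0 - press / max(ss, _EPS)
    return q2_comp, float(q2_comp[-1])


# ---------------------------------------------------------------------------
# PLS2 core and PLS-DA


def _pls2_core(Xc, Yc, n_components, tol=NIPALS_TOL, max_iter=NIPALS_MAX_ITER):
    """NIPALS PLS2 (regression deflation) on centered X, Y."""
    E, F = Xc.copy(), Yc.copy()
    total_x = float((E**2).sum())
    total_y = float((F**2).sum())
    W, T, P, C, ssy = [], [], [], [], []
    a = min(n_components, Xc.shape[0] - 1 if Xc.shape[0] > 1 else 1, Xc.shape[1])
    for _ in range(a):
        if (F**2).sum() <= total_y * 1e-14 or (E**2).sum() <= total_x * 1e-14:
            break
        u = F[:, int((F**2).sum(axis=0).argmax())].copy()
        t_old = np.zeros(E.shape[0])
        for it in range(max_iter):
            w = E.T @ u / max(u @ u, _EPS)
            nw = np.linalg.norm(w)
            if nw <= _EPS:
                break
            w /= nw
            t = E @ w
            c = F.T @ t / max(t @ t, _EPS)
            u = F @ c / max(c @ c, _EPS)
            if np.linalg.norm(t - t_old) <= tol * max(np.linalg.norm(t), _EPS):
                break
            t_old = t
        tt = float(t @ t)
        if tt <= total_x * 1e-14:
            break
        p = E.T @ t / tt
        E -= np.outer(t, p)
        F -= np.outer(t, c)
        W.append(w)
        T.append(t)
        P.append(p)
        C.append(c)
        ssy.append(tt * float(c @ c))
    if not W:
        raise RankError("no PLS component could be extracted")
    return {
        "W": np.column_stack(W),
        "T": np.column_stack(T),
        "P": np.column_stack(P),
        "C": np.column_stack(C),
        "ssy": np.asarray(ssy),
        "E": E,
        "F": F,
        "total_x": total_x,
        "total_y": total_y,
    }


def plsda_fit(
    X,
    y,
    n_components: int = 25,
    center: bool = True,
    scale: str = "none",
    cv_folds: int | None = None,
    seed: int = 0,
) -> LatentModel:
    """PLS2 discriminant analysis on one-hot class labels.

    ``n_components`` is capped at min(n-1, p). When ``cv_folds`` is given,
    Q2 is computed by row-wise cross-validation and stored on the model.
    """
    frame = X if isinstance(X, pd.DataFrame) else None
    X = _as_array(X)
    Y, classes = _one_hot(y)
    Xc, mean, sc = _center_scale(X, center, scale)
    y_mean = Y.mean(axis=0)
    core = _pls2_core(Xc, Y - y_mean, n_components)
    B = core["W"] @ np.linalg.inv(core["P"].T @ core["W"]) @ core["C"].T
    model = LatentModel(
        kind="PLS-DA",
        mean=mean,
        scale=sc,
        T=core["T"],
        P=core["P"],
        W=core["W"],
        C=core["C"],
        coef=B,
        classes=classes,
        y_mean=y_mean,
        r2x=1.0 - float((core["E"] ** 2).sum()) / max(core["total_x"], _EPS),
        r2y=1.0 - float((core["F"] ** 2).sum()) / max(core["total_y"], _EPS),
        ssy=core["ssy"],
        resid_ss_rows=(core["E"] ** 2).sum(axis=1),
        columns=list(frame.columns) if frame is not None else [],
    )
    if cv_folds:
        _, model.q2 = q2_cv(X, model.n_components, y=np.asarray(y), folds=cv_folds,
                            seed=seed, center=center, scale=scale)
    return model


def plsda_predict(model: LatentModel, X) -> np.ndarray:
    Xc = (model._align(X) - model.mean) / model.scale
    scores = Xc @ model.coef + model.y_mean
    return _argmax_labels(scores, model.classes)


# ---------------------------------------------------------------------------
# OPLS-DA


def oplsda_fit(
    X,
    y,
    n_ortho: int = 1,
    n_pred: int | None = None,
    center: bool = True,
    scale: str = "none",
) -> LatentModel:
    """OPLS-DA: orthogonal signal correction followed by a predictive PLS.

    Each orthogonal weight is the current X-loading orthogonalized against
    the full column space of X'Y, which makes every orthogonal score exactly
    uncorrelated with every class indicator (the single-y case reduces to
    the classical filter). The decomposition X = T P' + T_o P_o' + E holds
    by construction on the centered/scaled training data.
    """
    frame = X if isinstance(X, pd.DataFrame) else None
    X = _as_array(X)
    Y, classes = _one_hot(y)
    Xc, mean, sc = _center_scale(X, center, scale)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    total_x = float((Xc**2).sum())

    # orthonormal basis of span(X'Y): deflation by orthogonal components
    # leaves X'Y unchanged, so one basis serves every extraction
    XtY = Xc.T @ Yc
    Qb, Rb = np.linalg.qr(XtY)
    keep = np.abs(np.diag(Rb)) > max(np.abs(np.diag(Rb)).max(), _EPS) * 1e-12
    Qb = Qb[:, keep]

    E = Xc.copy()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_ortho):
        core = _pls2_core(E, Yc, 1)
        p = core["P"][:, 0]
        w_o = p - Qb @ (Qb.T @ p)
        nw = np.linalg.norm(w_o)
        if nw <= np.linalg.norm(p) * 1e-10:
            raise RankError("no orthogonal variation left to extract")
        w_o /= nw
        t_o = E @ w_o
        tt = float(t_o @ t_o)
        if tt <= total_x * 1e-14:
            raise RankError("orthogonal component count exceeds the data rank")
        p_o = E.T @ t_o / tt
        E -= np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)

    if n_pred is None:
        n_pred = max(1, len(classes) - 1)
    core = _pls2_core(E, Yc, n_pred)
    B = core["W"] @ np.linalg.inv(core["P"].T @ core["W"]) @ core["C"].T
    model = LatentModel(
        kind="OPLS-DA",
        mean=mean,
        scale=sc,
        T=core["T"],
        P=core["P"],
        W=core["W"],
        C=core["C"],
        T_o=np.column_stack(T_o) if T_o else None,
        P_o=np.column_stack(P_o) if P_o else None,
        W_o=np.column_stack(W_o) if W_o else None,
        coef=B,
        classes=classes,
        y_mean=y_mean,
        r2x=1.0 - float((core["E"] ** 2).sum()) / max(total_x, _EPS),
        r2y=1.0 - float((core["F"] ** 2).sum()) / max(core["total_y"], _EPS),
        ssy=core["ssy"],
        resid_ss_rows=(core["E"] ** 2).sum(axis=1),
        columns=list(frame.columns) if frame is not None else [],
    )
    return model


def oplsda_predict(model: LatentModel, X) -> np.ndarray:
    Xc = (model._align(X) - model.mean) / model.scale
    Xf = model._osc_filter(Xc)
    scores = Xf @ model.coef + model.y_mean
    return _argmax_labels(scores, model.classes)


# ---------------------------------------------------------------------------
# S-plot, biomarker selection, VIP


@dataclass
class SPlotResult:
    """Per-variable covariance (p1) and correlation (p(corr)1) with the
    predictive score of a one-vs-rest model."""

    covariance: pd.Series
    correlation: pd.Series
    contrast: str


def s_plot(model: LatentModel, X, contrast: str = "") -> SPlotResult:
    """S-plot statistics against the model's first predictive score."""
    names = (
        list(X.columns)
        if isinstance(X, pd.DataFrame)
        else list(range(_as_array(X).shape[1]))
    )
    Xc = (model._align(X) - model.mean) / model.scale
    t = model.T[:, 0]
    n = t.size
    tc = t - t.mean()
    xc = Xc - Xc.mean(axis=0)
    cov = xc.T @ tc / (n - 1)
    sd_t = tc.std(ddof=1)
    sd_x = xc.std(axis=0, ddof=1)
    denom = sd_t * sd_x
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    return SPlotResult(
        covariance=pd.Series(cov, index=names, name="p1"),
        correlation=pd.Series(corr, index=names, name="pcorr1"),
        contrast=contrast,
    )


def select_biomarkers(
    splots: list[SPlotResult],
    corr_cut: float = 0.5,
    cov_quantile: float = 0.95,
    min_contrasts: int = 3,
):
    """Marker selection from one-vs-rest S-plots.

    Per contrast, variables must pass |p(corr)1| >= corr_cut and |p1| >= the
    ``cov_quantile`` quantile of |p1|; survivors are ranked by |p(corr)1|.
    The consensus panel collects variables selected in at least
    ``min_contrasts`` contrasts. An empty selection is a logged warning, not
    an error.

    Returns ``(per_contrast, consensus)`` where per_contrast maps contrast
    name -> ranked index.
    """
    per_contrast = {}
    counts: dict = {}
    for sp in splots:
        cov_cut_val = sp.covariance.abs().quantile(cov_quantile)
        mask = (sp.correlation.abs() >= corr_cut) & (sp.covariance.abs() >= cov_cut_val)
        sel = sp.correlation[mask].abs().sort_values(ascending=False).index
        if len(sel) == 0:
            log.warning("no variable passed the cuts for contrast %r", sp.contrast)
        per_contrast[sp.contrast] = list(sel)
        for v in sel:
            counts[v] = counts.get(v, 0) + 1
    consensus = sorted(
        (v for v, c in counts.items() if c >= min_contrasts),
        key=lambda v: -counts[v],
    )
    return per_contrast, consensus


def vip(model: LatentModel) -> pd.Series:
    """Variable importance in projection for a PLS-family model.

    VIP_j = sqrt(p * sum_a[SSY_a (w_ja/||w_a||)^2] / sum_a SSY_a); the mean
    of VIP^2 over variables is exactly 1.
    """
    if model.W is None or model.ssy is None:
        raise ValueError("VIP requires a fitted PLS-family model")
    W = model.W / np.linalg.norm(model.W, axis=0, keepdims=True)
    p = W.shape[0]
    num = (W**2) @ model.ssy
    v = np.sqrt(p * num / model.ssy.sum())
    names = model.columns if model.columns else list(range(p))
    return pd.Series(v, index=names, name="VIP")


# ---------------------------------------------------------------------------
# LDA / PCA-LDA


@dataclass
class LDAModel:
    classes: list
    means: np.ndarray       # g x p
    cov_chol: tuple
    log_priors: np.ndarray


def lda_fit(X, y, priors: str = "proportional") -> LDAModel:
    """Linear discriminant analysis with a pooled within-class covariance.

    Raises :class:`SingularCovarianceError` when the pooled covariance is
    not invertible — reduce first (see :func:`pca_lda`).
    """
    X = _as_array(X)
    y = np.asarray(y)
    classes = sorted(pd.unique(pd.Series(y)).tolist())
    if len(classes) < 2:
        raise DegenerateLabelError("need at least two classes")
    n, p = X.shape
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    S = np.zeros((p, p))
    for c, m in zip(classes, means):
        d = X[y == c] - m
        S += d.T @ d
    S /= max(n - len(classes), 1)
    try:
        chol = cho_factor(S)
    except LinAlgError as exc:
        raise SingularCovarianceError(
            "pooled within-class covariance is singular; use pca_lda to reduce "
            "dimensionality first"
        ) from exc
    if priors == "proportional":
        pri = np.array([(y == c).mean() for c in classes])
    elif priors == "uniform":
        pri = np.full(len(classes), 1.0 / len(classes))
    else:
        raise ValueError(f"unknown priors {priors!r}")
    return LDAModel(classes, means, chol, np.log(pri))


def lda_scores(model: LDAModel, X) -> np.ndarray:
    X = _as_array(X)
    A = cho_solve(model.cov_chol, model.means.T)  # p x g
    return X @ A - 0.5 * np.einsum("gp,pg->g", model.means, A) + model.log_priors


def lda_predict(model: LDAModel, X) -> np.ndarray:
    return _argmax_labels(lda_scores(model, X), model.classes)


@dataclass
class PCALDAModel:
    mean: np.ndarray
    loadings: np.ndarray
    lda: LDAModel


def pca_lda(X, y, n_pcs: int = 25, priors: str = "proportional") -> PCALDAModel:
    """PCA compression to ``n_pcs`` followed by LDA on the scores; stores
    both transforms so prediction chains them."""
    X = _as_array(X)
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_pcs, Xc.shape[0] - 1, Xc.shape[1])
    k = max(1, int((s[:k] > s[0] * 1e-12).sum()))
    V = Vt[:k].T
    return PCALDAModel(mean, V, lda_fit(Xc @ V, y, priors=priors))


def pca_lda_predict(model: PCALDAModel, X) -> np.ndarray:
    X = _as_array(X)
    return lda_predict(model.lda, (X - model.mean) @ model.loadings)


# ---------------------------------------------------------------------------
# k-NN


def knn_predict(train_X, train_y, query_X, k: int = 5, metric: str = "euclidean"):
    """Majority vote among the k nearest training points.

    Vote ties break by the smallest mean distance among the tied classes,
    then by the lowest class index; distance ties break by training order
    (stable sort).
    """
    train_X = _as_array(train_X)
    query_X = _as_array(query_X)
    train_y = np.asarray(train_y)
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if not (1 <= k <= train_X.shape[0]):
        raise ValueError("k must be between 1 and n_train")
    classes = sorted(pd.unique(pd.Series(train_y)).tolist())
    D = cdist(query_X, train_X, metric=metric)
    out = []
    for row in D:
        order = np.argsort(row, kind="stable")[:k]
        labels = train_y[order]
        dists = row[order]
        counts = {c: int((labels == c).sum()) for c in classes}
        best = max(counts.values())
        tied = [c for c in classes if counts[c] == best]
        if len(tied) > 1:
            means = {c: float(dists[labels == c].mean()) for c in tied}
            lo = min(means.values())
            tied = [c for c in tied if means[c] == lo]
        out.append(tied[0])
    return np.asarray(out, dtype=object)


# ---------------------------------------------------------------------------
# Classifier adapters


class PLSDAClassifier:
    """PLS-DA with the published default of 25 components."""

    name = "plsda"

    def __init__(self, n_components: int = 25):
        self.n_components = n_components
        self.model_: LatentModel | None = None

    def fit(self, X, y):
        self.model_ = plsda_fit(X, y, n_components=self.n_components)
        return self

    def predict(self, X):
        return plsda_predict(self.model_, X)


class OPLSDAClassifier:
    name = "oplsda"

    def __init__(self, n_ortho: int = 1, n_pred: int | None = None):
        self.n_ortho = n_ortho
        self.n_pred = n_pred
        self.model_: LatentModel | None = None

    def fit(self, X, y):
        self.model_ = oplsda_fit(X, y, n_ortho=self.n_ortho, n_pred=self.n_pred)
        return self

    def predict(self, X):
        return oplsda_predict(self.model_, X)


class KNNClassifier:
    """k-NN with the published default k = 5."""

    name = "knn"

    def __init__(self, k: int = 5, metric: str = "euclidean"):
        self.k = k
        self.metric = metric

    def fit(self, X, y):
        self._X = _as_array(X).copy()
        self._y = np.asarray(y).copy()
        return self

    def predict(self, X):
        return knn_predict(self._X, self._y, X, k=self.k, metric=self.metric)


class LDAClassifier:
    name = "lda"

    def __init__(self, priors: str = "proportional"):
        self.priors = priors

    def fit(self, X, y):
        self.model_ = lda_fit(X, y, priors=self.priors)
        return self

    def predict(self, X):
        return lda_predict(self.model_, X)


class PCALDAClassifier:
    name = "pca_lda"

    def __init__(self, n_pcs: int = 25, priors: str = "proportional"):
        self.n_pcs = n_pcs
        self.priors = priors

    def fit(self, X, y):
        self.model_ = pca_lda(X, y, n_pcs=self.n_pcs, priors=self.priors)
        return self

    def predict(self, X):
        return pca_lda_predict(self.model_, X)


class SklearnAdapter:
    """Plug any scikit-learn style estimator into the evaluation machinery
    without mutating the caller's instance (a clone is fit)."""

    def __init__(self, estimator, name: str = "sklearn"):
        self.estimator = estimator
        self.name = name

    def fit(self, X, y):
        from sklearn.base import clone

        self.model_ = clone(self.estimator)
        self.model_.fit(_as_array(X), np.asarray(y))
        return self

    def predict(self, X):
        return np.asarray(self.model_.predict(_as_array(X)), dtype=object)


def make_random_forest(seed: int = 0, n_trees: int = 500, n_predictors: int = 15):
    """Random Forest slot with the published hyperparameters
    (ntree=500, npredic=15)."""
    from sklearn.ensemble import RandomForestClassifier

    return SklearnAdapter(
        RandomForestClassifier(
            n_estimators=n_trees, max_features=n_predictors, random_state=seed
        ),
        name="rf",
    )


def make_svm(seed: int = 0):
    """RBF-kernel SVM slot with library defaults."""
    from sklearn.svm import SVC

    return SklearnAdapter(SVC(kernel="rbf", random_state=seed), name="svm")
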