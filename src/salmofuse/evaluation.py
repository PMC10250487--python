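"""Model evaluation: cross-validation, outlier flagging, replicated test
sets, and the univariate element statistics.

Cross-validation here re-fits *everything* — block scaling, PCA
compression, the classifier — inside each training fold, so no information
from a held-out fold leaks into the transforms that score it. Published
workflows that compress once on the full data may therefore report slightly
more optimistic numbers than this implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chemometrics import LatentModel, q2_cv
from .fusion import FusedMatrix, low_level_fuse, mid_level_fuse, project
from .preprocess import ElementBlock, minmax_scale

log = logging.getLogger(__name__)

OUTLIER_LABEL = "Outlier"


class StratificationError(ValueError):
    pass


class InputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Fused pipeline estimator


class FusedClassifier:
    """Two-block fusion + classifier pipeline with a fit/predict contract.

    ``blocks`` arguments are lists of ``(matrix, name)`` with aligned sample
    rows. All fusion transforms are fitted in :meth:`fit` and reused —
    never re-fitted — by :meth:`predict`, which is what makes the estimator
    safe inside cross-validation.
    """

    def __init__(
        self,
        base,
        level: str = "mid",
        threshold: float = 0.85,
        scaling: dict | None = None,
        max_components: int = 250,
    ):
        self.base = base
        self.level = level
        self.threshold = threshold
        self.scaling = scaling
        self.max_components = max_components
        self.name = f"{level}+{getattr(base, 'name', type(base).__name__)}"
        self.fused_: FusedMatrix | None = None

    def fit(self, blocks, y):
        if self.level == "mid":
            self.fused_ = mid_level_fuse(
                blocks,
                threshold=self.threshold,
                scaling=self.scaling,
                max_components=self.max_components,
            )
        elif self.level == "low":
            self.fused_ = low_level_fuse(blocks)
        else:
            raise ValueError(f"unknown fusion level {self.level!r}")
        self.base.fit(self.fused_.data, np.asarray(y))
        return self

    def _project(self, blocks) -> pd.DataFrame:
        return project(self.fused_, {name: mat for mat, name in blocks})

    def predict(self, blocks):
        return self.base.predict(self._project(blocks))

    def flag(self, blocks, alpha: float = 0.05):
        """Outlier mask from the base classifier's latent model, when it
        has one; otherwise nothing is flagged."""
        model = getattr(self.base, "model_", None)
        Z = self._project(blocks)
        if isinstance(model, LatentModel):
            return flag_outliers(model, Z, alpha=alpha)
        return np.zeros(len(Z), dtype=bool)


def _n_rows(X):
    if isinstance(X, (list, tuple)):
        return len(pd.DataFrame(X[0][0]))
    return len(X)


def _take_rows(X, idx):
    if isinstance(X, (list, tuple)):
        return [(pd.DataFrame(mat).iloc[idx], name) for mat, name in X]
    if isinstance(X, pd.DataFrame):
        return X.iloc[idx]
    return np.asarray(X)[idx]


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    """Confusion matrix (true x predicted + Outlier column), rates in %,
    fold assignments and the seed that produced them."""

    confusion: pd.DataFrame
    per_class_rate: pd.Series
    overall_rate: float
    fold_assignments: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return int(self.confusion.to_numpy().sum())


def kfold_cv(
    classifier,
    X,
    y,
    folds: int = 5,
    stratified: bool = True,
    seed: int = 0,
    outlier_alpha: float | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of any fit/predict classifier.

    ``X`` may be a plain matrix or a list of ``(matrix, name)`` blocks fed
    to a :class:`FusedClassifier` — either way every transform the
    classifier owns is re-fit per training fold. When ``outlier_alpha`` is
    set and the classifier exposes ``flag``, flagged predictions land in the
    Outlier column and count as incorrect.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    y = np.asarray(y)
    n = _n_rows(X)
    if y.size != n:
        raise InputError("label vector length does not match the data")
    classes = sorted(pd.unique(pd.Series(y)).tolist())
    if stratified:
        smallest = min(int((y == c).sum()) for c in classes)
        if smallest < folds:
            raise StratificationError(
                f"smallest class has {smallest} members; cannot stratify into "
                f"{folds} folds"
            )
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)

    confusion = pd.DataFrame(
        0, index=classes, columns=classes + [OUTLIER_LABEL], dtype=int
    )
    fold_of = np.empty(n, dtype=int)
    for f, (tr, te) in enumerate(splitter.split(np.zeros(n), y)):
        fold_of[te] = f
        classifier.fit(_take_rows(X, tr), y[tr])
        pred = np.asarray(classifier.predict(_take_rows(X, te)), dtype=object)
        if outlier_alpha is not None and hasattr(classifier, "flag"):
            flags = np.asarray(classifier.flag(_take_rows(X, te), outlier_alpha))
        else:
            flags = np.zeros(len(te), dtype=bool)
        for true, p, fl in zip(y[te], pred, flags):
            confusion.loc[true, OUTLIER_LABEL if fl else p] += 1

    diag = np.array([confusion.loc[c, c] for c in classes], dtype=float)
    row_sums = confusion.sum(axis=1).to_numpy(dtype=float)
    per_class = pd.Series(100.0 * diag / np.maximum(row_sums, 1), index=classes)
    overall = float(100.0 * diag.sum() / n)
    return CVResult(confusion, per_class, overall, fold_of, seed)


# ---------------------------------------------------------------------------
# Outlier flagging


def flag_outliers(model: LatentModel, X, alpha: float = 0.05) -> np.ndarray:
    """Model-distance outlier mask.

    A row is flagged when its Hotelling T2 over the model scores exceeds
    the F-based limit, or its residual distance-to-model exceeds the
    empirical limit from the training residuals. Each test runs at
    alpha/2 so the union calibrates to roughly ``alpha`` on training-like
    data.
    """
    T_train = model.T
    n, a = T_train.shape
    var = T_train.var(axis=0, ddof=1)
    var[var == 0] = np.inf
    T_new = model.x_scores(X)
    t2 = ((T_new**2) / var).sum(axis=1)
    level = 1.0 - alpha / 2.0
    t2_lim = a * (n - 1) * (n + 1) / (n * (n - a)) * stats.f.ppf(level, a, n - a)
    resid_new = model.x_residual_ss(X)
    resid_lim = np.quantile(model.resid_ss_rows, level)
    return (t2 > t2_lim) | (resid_new > resid_lim)


# ---------------------------------------------------------------------------
# Replicated test samples


@dataclass
class TestReport:
    """Replicate-level predictions and the per-sample majority calls."""

    replicates: pd.DataFrame  # rows: replicate; columns: sample, predicted, outlier
    sample_calls: pd.Series   # sample id -> called class (or Outlier)
    outlier_count: int
    accuracy_pct: float


def evaluate_test_samples(
    pipeline,
    test_blocks,
    declared_labels: pd.Series,
    sample_of: pd.Series,
    replicates: int = 6,
    alpha: float = 0.05,
) -> TestReport:
    """Score a replicated test set and call each sample by majority vote
    over its non-outlier replicates (all-outlier samples are called
    Outlier). Accuracy is the fraction of samples whose call equals the
    declared label."""
    counts = sample_of.value_counts()
    if (counts != replicates).any():
        raise InputError(
            f"replicate count mismatch: expected {replicates}, got "
            f"{sorted(set(counts))}"
        )
    preds = np.asarray(pipeline.predict(test_blocks), dtype=object)
    if hasattr(pipeline, "flag"):
        flags = np.asarray(pipeline.flag(test_blocks, alpha))
    else:
        flags = np.zeros(len(preds), dtype=bool)
    rep = pd.DataFrame(
        {"sample": sample_of.to_numpy(), "predicted": preds, "outlier": flags},
        index=sample_of.index,
    )
    calls = {}
    for sid, grp in rep.groupby("sample", sort=False):
        valid = grp.loc[~grp["outlier"], "predicted"]
        if valid.empty:
            calls[sid] = OUTLIER_LABEL
            continue
        vc = valid.value_counts()
        best = vc[vc == vc.max()]
        calls[sid] = sorted(best.index)[0]
    sample_calls = pd.Series(calls).reindex(declared_labels.index)
    correct = (sample_calls == declared_labels).sum()
    return TestReport(
        replicates=rep,
        sample_calls=sample_calls,
        outlier_count=int(flags.sum()),
        accuracy_pct=float(100.0 * correct / len(declared_labels)),
    )


# ---------------------------------------------------------------------------
# Univariate statistics


def kruskal_wallis(groups):
    """Tie-corrected Kruskal-Wallis H with a chi-square tail p-value.

    Returns ``(H, p, df)``. All values identical across all groups is not
    an error: H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0, df
    H, p = stats.kruskal(*groups)
    return float(H), float(p), df


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def pairwise_compare(groups, names=None, correction: str = "holm") -> pd.DataFrame:
    """All pairwise two-sided Mann-Whitney tests with multiplicity
    correction ("holm" or "none"). Returns a symmetric p-value matrix with
    unit diagonal."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    g = len(groups)
    if g < 2:
        raise ValueError("need at least two groups")
    if names is None:
        names = [f"group{i + 1}" for i in range(g)]
    pairs = [(i, j) for i in range(g) for j in range(i + 1, g)]
    raw = []
    for i, j in pairs:
        if np.array_equal(groups[i], groups[j]):
            raw.append(1.0)
        else:
            raw.append(
                float(stats.mannwhitneyu(groups[i], groups[j],
                                         alternative="two-sided").pvalue)
            )
    if correction == "holm":
        adj = _holm(np.asarray(raw))
    elif correction == "none":
        adj = np.asarray(raw)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out = pd.DataFrame(np.ones((g, g)), index=names, columns=names)
    for (i, j), p in zip(pairs, adj):
        out.iloc[i, j] = out.iloc[j, i] = p
    return out


def heatmap_matrix(block: ElementBlock, labels) -> pd.DataFrame:
    """Per-element group means, min-max scaled per element across groups
    (values in [0, 1]; constant elements map to 0)."""
    labels = pd.Series(np.asarray(labels), index=block.data.index)
    means = block.data.groupby(labels).mean()
    scaled, _ = minmax_scale(means)
    return scaled


# ---------------------------------------------------------------------------
# CV-ANOVA


def cv_anova(
    X,
    y,
    n_components: int = 2,
    folds: int = 7,
    seed: int = 0,
    n_permutations: int = 999,
) -> dict:
    """Cross-validated ANOVA-style significance of a PLS-DA model.

    The F statistic compares the cross-validated explained sum of squares
    against the CV predictive residual (an approximation to proprietary
    CV-ANOVA implementations; labelled as such in the output). The
    label-permutation test on Q2 is the recommended measure; with N
    permutations its resolution is 1/(N+1).
    """
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X
    y = np.asarray(y)
    n = len(y)
    _, q2_obs = q2_cv(X, n_components, y=y, folds=folds, seed=seed)
    m = len(pd.unique(pd.Series(y)))
    press_frac = 1.0 - q2_obs           # PRESS / SS(Y)
    d1 = n_components * m
    d2 = max(n * m - d1 - m, 1)
    F = (q2_obs / d1) / max(press_frac / d2, np.finfo(float).eps)
    p_approx = float(stats.f.sf(F, d1, d2)) if F > 0 else 1.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        y_perm = rng.permutation(y)
        _, q2_perm = q2_cv(X, n_components, y=y_perm, folds=folds, seed=seed)
        if q2_perm >= q2_obs:
            exceed += 1
    p_perm = (1 + exceed) / (n_permutations + 1)
    return {
        "F_approx": float(F),
        "p_approx": p_approx,
        "q2": float(q2_obs),
        "p_permutation": float(p_perm),
        "n_permutations": n_permutations,
        "note": "F is an approximation; the permutation p-value is the "
                "recommended significance measure",
    }
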