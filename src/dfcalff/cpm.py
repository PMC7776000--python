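"""Connectome-based predictive modeling (CPM) with nested leave-one-out CV.

The model associates a continuous behavioral score with connectivity-derived
features (z-scored dFC-ALFF or static FC).  Inside each outer leave-one-out
fold, an inner leave-one-out loop picks the feature-selection p-threshold
from a grid (default .001-.05 in steps of .001) by maximizing the inner
Pearson correlation between predictions and observed scores; features whose
training-set Pearson correlation with the score has two-sided p below the
threshold enter a linear epsilon-SVR (C = 1, epsilon = 0).  The "integrated"
model keeps positively and negatively correlated features in one model;
sign-restricted variants are available.

Feature selection and threshold optimization never see the held-out subject;
the final association is the Pearson r (and its t-based two-sided p) between
the out-of-fold predictions and the observed scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted, check_X_y

from .variability import FeatureTable

try:  # low-level libsvm entry point: same solver SVR wraps, far less call overhead
    from sklearn.svm import _libsvm as _libsvm_raw

    _libsvm_raw.set_verbosity_wrap(0)
except Exception:  # pragma: no cover - depends on sklearn internals
    _libsvm_raw = None

__all__ = [
    "CpmConfig",
    "FoldRecord",
    "CpmResult",
    "CpmRegressor",
    "select_features",
    "inner_loocv_optimize",
    "nested_loocv",
    "evaluate_association",
    "correlation_pvalues",
]

DEFAULT_P_GRID = tuple(np.round(np.arange(1, 51) * 0.001, 3))


class EmptySelectionError(RuntimeError):
    """No feature survived the correlation-p threshold."""


@dataclass(frozen=True)
class CpmConfig:
    """Hyperparameters of the nested-LOOCV CPM run.

    p_grid defaults to .001-.05 in steps of .001; svr_c and svr_epsilon
    default to 1 and 0 (the fixed, un-tuned values); model_mode is one of
    "integrated", "positive_only", "negative_only".  ``inner_selection``
    chooses whether the inner loop recomputes feature selection on each
    inner-training subset ("per_inner_fold", the leakage-safe reading) or
    selects once on the outer-training set ("outer_train", cheaper,
    for comparison).
    """

    p_grid: tuple[float, ...] = DEFAULT_P_GRID
    svr_c: float = 1.0
    svr_epsilon: float = 0.0
    model_mode: str = "integrated"
    inner_selection: str = "per_inner_fold"

    def __post_init__(self) -> None:
        grid = np.asarray(self.p_grid, dtype=float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("p_grid must be strictly increasing")
        if np.any((grid <= 0) | (grid >= 1)):
            raise ValueError("p_grid values must lie in (0, 1)")
        if self.svr_c <= 0:
            raise ValueError("svr_c must be positive")
        if self.svr_epsilon < 0:
            raise ValueError("svr_epsilon must be >= 0")
        if self.model_mode not in ("integrated", "positive_only", "negative_only"):
            raise ValueError(f"unknown model_mode {self.model_mode!r}")
        if self.inner_selection not in ("per_inner_fold", "outer_train"):
            raise ValueError(f"unknown inner_selection {self.inner_selection!r}")


@dataclass
class FoldRecord:
    """One outer-LOOCV iteration: chosen threshold, selection, prediction."""

    held_out_subject_id: str
    chosen_p: float
    selected_links: np.ndarray  # link indices
    link_signs: np.ndarray  # +1/-1, sign of the training correlation
    prediction: float
    inner_r: float


@dataclass
class CpmResult:
    """Full nested-LOOCV outcome: per-fold records and overall association."""

    folds: list[FoldRecord]
    predictions: np.ndarray
    association_r: float
    association_p: float
    subject_ids: list[str] = field(default_factory=list)
    config: CpmConfig = field(default_factory=CpmConfig)
    label: str = "primary"

    @property
    def n_subjects(self) -> int:
        return len(self.folds)


def correlation_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each column of X with y, with two-sided t-based p-values.

    Vectorized over columns; r = +-1 maps to p = 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    yc = y - y.mean()
    sy = np.sqrt((yc ** 2).sum())
    if sy == 0:
        raise ValueError("scores are constant; correlation undefined")
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.where(sx == 0, 0.0, r)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def select_features(
    train_features: np.ndarray,
    train_scores: np.ndarray,
    p_threshold: float,
    model_mode: str = "integrated",
) -> tuple[np.ndarray, np.ndarray]:
    """Correlation-based feature selection.

    Returns (indices, signs): links whose two-sided correlation p is below
    the threshold, tagged with the sign of the training correlation.  The
    selection may be empty; callers decide how to handle that.
    """
    r, p = correlation_pvalues(train_features, train_scores)
    mask = p < p_threshold
    if model_mode == "positive_only":
        mask &= r > 0
    elif model_mode == "negative_only":
        mask &= r < 0
    idx = np.flatnonzero(mask)
    return idx, np.sign(r[idx]).astype(int)


def _fit_svr(X: np.ndarray, y: np.ndarray, config: CpmConfig) -> SVR:
    model = SVR(kernel="linear", C=config.svr_c, epsilon=config.svr_epsilon)
    model.fit(X, y)
    return model


def _svr_fit_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
                     config: CpmConfig) -> np.ndarray:
    """Fit linear epsilon-SVR and predict; identical solution to
    sklearn.svm.SVR(kernel='linear') (same libsvm solver, same tolerance),
    via the low-level interface when available."""
    if _libsvm_raw is None:
        return _fit_svr(Xtr, ytr, config).predict(Xte)
    # centering y is exact for epsilon-SVR (sum of dual coefs is zero) and
    # speeds up the solver; the offset is restored on the predictions
    y_mean = float(np.mean(ytr))
    out = _libsvm_raw.fit(
        np.ascontiguousarray(Xtr, dtype=np.float64),
        np.ascontiguousarray(ytr - y_mean, dtype=np.float64),
        svm_type=3, kernel="linear", C=config.svr_c,
        epsilon=config.svr_epsilon, tol=1e-3,
    )
    sv, dual_coef, intercept = out[1], out[3], out[4]
    w = (dual_coef @ sv).ravel()
    return Xte @ w + intercept[0] + y_mean


class CpmRegressor(RegressorMixin, BaseEstimator):
    """CPM at a fixed selection threshold: correlate-select then linear SVR.

    A scikit-learn regressor: ``fit`` selects the features whose Pearson
    correlation with ``y`` has two-sided p below ``p_threshold`` (optionally
    restricted by sign) and fits a linear epsilon-SVR on them; ``predict``
    applies the fitted model to the same columns.  Compose with sklearn
    model selection to tune ``p_threshold``; :func:`nested_loocv` implements
    the inner-LOOCV tuning rule used in the full analysis.

    Parameters
    ----------
    p_threshold : float
        Two-sided correlation p-value cut for feature selection.
    C : float
        SVR penalty constant.
    epsilon : float
        SVR insensitivity-tube width.
    model_mode : str
        "integrated" (both signs), "positive_only" or "negative_only".

    Attributes
    ----------
    selected_links_ : ndarray
        Indices of the selected feature columns.
    link_signs_ : ndarray
        Sign (+1/-1) of each selected feature's training correlation.
    svr_ : sklearn.svm.SVR
        The fitted linear SVR.
    """

    def __init__(self, p_threshold: float = 0.01, C: float = 1.0,
                 epsilon: float = 0.0, model_mode: str = "integrated"):
        self.p_threshold = p_threshold
        self.C = C
        self.epsilon = epsilon
        self.model_mode = model_mode

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 training subjects")
        idx, signs = select_features(X, y, self.p_threshold, self.model_mode)
        if idx.size == 0:
            raise EmptySelectionError(
                f"no feature passed p < {self.p_threshold} on {X.shape[0]} "
                "training subjects"
            )
        self.selected_links_ = idx
        self.link_signs_ = signs
        self.svr_ = SVR(kernel="linear", C=self.C, epsilon=self.epsilon)
        self.svr_.fit(X[:, idx], y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "svr_")
        X = np.asarray(X, dtype=float)
        return self.svr_.predict(X[:, self.selected_links_])


def inner_loocv_optimize(
    train_features: np.ndarray,
    train_scores: np.ndarray,
    config: CpmConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Pick the selection threshold by inner leave-one-out CV.

    For each grid threshold, runs LOOCV inside the training set (feature
    selection recomputed on each inner-training subset by default), predicts
    each inner-held-out subject with a linear SVR, and scores the threshold
    by the Pearson correlation of inner predictions vs true scores.  A grid
    point whose selection is empty in any inner fold is invalid (NaN).
    Returns (best_p, inner_r per grid point); ties break toward the smallest
    threshold.  Raises if every grid point is invalid.

    Within each inner fold the feature correlations are computed once and
    thresholded repeatedly across the grid, and SVR fits are shared between
    thresholds that select the same feature set — identical results to the
    naive per-threshold loop.
    """
    config = config or CpmConfig()
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_scores, dtype=float)
    n = y.shape[0]
    if n < 4:
        raise ValueError("need at least 4 training subjects for inner LOOCV")
    grid = np.asarray(config.p_grid, dtype=float)
    G = grid.size
    preds = np.full((G, n), np.nan)
    valid = np.ones(G, dtype=bool)

    if config.inner_selection == "outer_train":
        outer_r, outer_p = correlation_pvalues(X, y)

    for k in range(n):
        tr = np.ones(n, dtype=bool)
        tr[k] = False
        Xtr, ytr = X[tr], y[tr]
        if config.inner_selection == "per_inner_fold":
            r, p = correlation_pvalues(Xtr, ytr)
        else:
            r, p = outer_r, outer_p
        if config.model_mode == "positive_only":
            p = np.where(r > 0, p, np.inf)
        elif config.model_mode == "negative_only":
            p = np.where(r < 0, p, np.inf)
        cache: dict[bytes, float] = {}
        for gi in np.flatnonzero(valid):
            idx = np.flatnonzero(p < grid[gi])
            if idx.size == 0:
                valid[gi] = False
                continue
            key = idx.tobytes()
            if key not in cache:
                cache[key] = float(
                    _svr_fit_predict(Xtr[:, idx], ytr, X[k, idx][None, :], config)[0]
                )
            preds[gi, k] = cache[key]

    inner_r = np.full(G, np.nan)
    for gi in np.flatnonzero(valid):
        pg = preds[gi]
        if np.std(pg) == 0 or np.std(y) == 0:
            inner_r[gi] = -np.inf
        else:
            inner_r[gi] = float(np.corrcoef(pg, y)[0, 1])
    if not valid.any():
        raise EmptySelectionError(
            "every threshold on the grid produced an empty selection in some "
            "inner fold"
        )
    # grid ascending + argmax-first => ties resolve to the smallest threshold
    masked = np.where(valid, inner_r, -np.inf)
    best_p = float(grid[int(np.argmax(masked))])
    return best_p, inner_r


def _masked_pvalues(X: np.ndarray, y: np.ndarray, model_mode: str) -> np.ndarray:
    r, p = correlation_pvalues(X, y)
    if model_mode == "positive_only":
        p = np.where(r > 0, p, np.inf)
    elif model_mode == "negative_only":
        p = np.where(r < 0, p, np.inf)
    return p


def _pairwise_inner_predictions(
    X: np.ndarray, y: np.ndarray, config: CpmConfig
) -> tuple[np.ndarray, np.ndarray]:
    """All inner-LOOCV predictions for every outer fold, shared across folds.

    The inner fold (outer h, inner k) and (outer k, inner h) train on the
    identical subject set (everyone but h and k), so selection and SVR fit
    are computed once per unordered pair.  Returns preds[gi, h, k] (the
    prediction of subject k inside outer fold h at grid point gi) and
    invalid[gi, h] flags (empty selection in some inner fold of h).
    """
    n = y.shape[0]
    grid = np.asarray(config.p_grid, dtype=float)
    G = grid.size
    preds = np.full((G, n, n), np.nan)
    invalid = np.zeros((G, n), dtype=bool)
    if config.inner_selection == "outer_train":
        # selection fixed per outer fold; still per-pair SVR fits
        outer_p = [
            _masked_pvalues(np.delete(X, h, axis=0), np.delete(y, h), config.model_mode)
            for h in range(n)
        ]
    for a in range(n):
        for b in range(a + 1, n):
            tr = np.ones(n, dtype=bool)
            tr[a] = tr[b] = False
            Xtr, ytr = X[tr], y[tr]
            Xte = X[[a, b]]
            if config.inner_selection == "per_inner_fold":
                p = _masked_pvalues(Xtr, ytr, config.model_mode)
                p_for = {a: p, b: p}
            else:
                p_for = {a: outer_p[a], b: outer_p[b]}
            cache: dict[bytes, np.ndarray] = {}
            for h, k in ((a, b), (b, a)):
                p = p_for[h]
                for gi in range(G):
                    idx = np.flatnonzero(p < grid[gi])
                    if idx.size == 0:
                        invalid[gi, h] = True
                        continue
                    key = idx.tobytes()
                    if key not in cache:
                        cache[key] = _svr_fit_predict(Xtr[:, idx], ytr, Xte[:, idx], config)
                    preds[gi, h, k] = cache[key][1 if k == b else 0]
    return preds, invalid


def _inner_r_for_fold(preds: np.ndarray, invalid: np.ndarray, y: np.ndarray,
                      h: int) -> np.ndarray:
    """Inner association r per grid point for outer fold h (NaN if invalid)."""
    G, n, _ = preds.shape
    keep = np.ones(n, dtype=bool)
    keep[h] = False
    yk = y[keep]
    out = np.full(G, np.nan)
    for gi in range(G):
        if invalid[gi, h]:
            continue
        pg = preds[gi, h, keep]
        if np.std(pg) == 0:
            out[gi] = -np.inf
        else:
            out[gi] = float(np.corrcoef(pg, yk)[0, 1])
    return out


def evaluate_association(predictions: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    """Pearson r between predicted and observed scores with two-sided p.

    p comes from the t transform with n-2 degrees of freedom.
    """
    predictions = np.asarray(predictions, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predictions.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if np.std(predictions) == 0 or np.std(observed) == 0:
        raise ValueError("constant vector; correlation undefined")
    res = stats.pearsonr(predictions, observed)
    return float(res.statistic), float(res.pvalue)


def nested_loocv(
    features: FeatureTable | np.ndarray,
    config: CpmConfig | None = None,
    scores: np.ndarray | None = None,
    subject_ids: list[str] | None = None,
    label: str = "primary",
) -> CpmResult:
    """Full nested leave-one-out CPM run.

    Each subject is held out in turn; the inner loop tunes the selection
    threshold on the remaining subjects, the final selection and SVR fit use
    the full training set at that threshold, and the held-out subject is
    predicted.  The association r/p compares the out-of-fold predictions to
    the observed scores.
    """
    config = config or CpmConfig()
    if isinstance(features, FeatureTable):
        X = features.values
        y = features.scores if scores is None else np.asarray(scores, dtype=float)
        ids = features.subject_ids
    else:
        if scores is None:
            raise ValueError("scores are required when features is a bare matrix")
        X = np.asarray(features, dtype=float)
        y = np.asarray(scores, dtype=float)
        ids = subject_ids or [f"sub_{k:03d}" for k in range(X.shape[0])]
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects for nested LOOCV")

    folds: list[FoldRecord] = []
    predictions = np.empty(n)
    grid = np.asarray(config.p_grid, dtype=float)
    preds, invalid = _pairwise_inner_predictions(X, y, config)
    for h in range(n):
        tr = np.ones(n, dtype=bool)
        tr[h] = False
        inner_r = _inner_r_for_fold(preds, invalid, y, h)
        masked = np.where(invalid[:, h], -np.inf, np.nan_to_num(inner_r, nan=-np.inf))
        if not np.isfinite(masked).any():
            raise EmptySelectionError(
                f"outer fold {h} (subject {ids[h]}): every threshold on the "
                "grid produced an empty selection in some inner fold"
            )
        gi = int(np.argmax(masked))  # ties resolve to the smallest threshold
        best_p = float(grid[gi])
        idx, signs = select_features(X[tr], y[tr], best_p, config.model_mode)
        if idx.size == 0:
            raise EmptySelectionError(
                f"outer fold {h} (subject {ids[h]}): selection empty at tuned "
                f"threshold {best_p}"
            )
        pred = float(_svr_fit_predict(X[tr][:, idx], y[tr], X[h, idx][None, :], config)[0])
        predictions[h] = pred
        folds.append(FoldRecord(ids[h], best_p, idx, signs, pred, float(inner_r[gi])))

    r, p = evaluate_association(predictions, y)
    return CpmResult(folds, predictions, r, p, list(ids), config, label)
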