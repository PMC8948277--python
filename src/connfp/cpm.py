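"""Connectome-based predictive modelling (CPM) and a linear-SVR variant.

CPM predicts a behavioural score from edge vectors in three steps: edgewise
feature selection (Pearson correlation of every edge with the score in the
training fold, thresholded at a p-value), model building (edges split by
correlation sign, summed into positive and negative summary scores S+ and
S-, each regressed on the score by least squares), and prediction (the same
edge sets and coefficients applied to test subjects).  The whole procedure
runs inside repeated k-fold cross-validation; per-subject predictions are
averaged over repeats and evaluated by Spearman correlation against the
measured scores, with a right-tailed permutation test.

:class:`CPMRegressor` packages the per-fold procedure as a scikit-learn
estimator, so it composes with sklearn model selection; the module-level
functions are thin wrappers implementing the repeated-CV protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import SGDRegressor
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .fingerprint import EdgeMask, threshold_percentile

logger = logging.getLogger(__name__)

__all__ = [
    "CPMConfig",
    "PredictionResult",
    "CPMRegressor",
    "edgewise_correlation",
    "cpm_fold",
    "run_cpm",
    "predict_with_fixed_edges",
    "run_svr",
    "prediction_permutation_test",
]

SIDES = ("positive", "negative")


@dataclass
class CPMConfig:
    threshold_p: float = 0.01
    k_folds: int = 10
    n_repeats: int = 100
    model_side: str = "positive"
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0.0 < self.threshold_p < 1.0:
            raise ValueError("threshold_p must be in (0, 1)")
        if self.model_side not in ("positive", "negative", "both"):
            raise ValueError("model_side must be positive, negative or both")


@dataclass
class PredictionResult:
    """Averaged cross-validated predictions and their evaluation."""

    predictions: np.ndarray  # per complete subject, averaged over repeats
    subjects: list[str]
    selection_frequency: dict[str, np.ndarray]  # side -> per-edge fold fraction
    rho: float  # Spearman(predictions, measured), primary statistic
    pearson_r: float
    p_value: float | None
    n_complete: int
    perm_rhos: np.ndarray | None = field(default=None, repr=False)


def edgewise_correlation(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of every edge (column of X) with y, plus two-sided p.

    p comes from the exact t transform ``t = r sqrt(df / (1 - r^2))`` with
    ``df = n - 2``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 training subjects")
    if np.std(y) == 0:
        raise ValueError("constant target: edgewise correlations are undefined")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    xnorm = np.sqrt(np.sum(Xc**2, axis=0))
    denom = xnorm * np.sqrt(np.sum(yc**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / denom
    r = np.where(denom == 0, 0.0, r)  # constant edges carry no information
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return r, p


class CPMRegressor(BaseEstimator, RegressorMixin):
    """One CPM training fold as a scikit-learn estimator.

    Parameters
    ----------
    threshold_p
        Two-sided p-value threshold for edgewise feature selection.
    model_side
        Which summary model drives :meth:`predict`: ``positive`` (edges
        positively correlated with the score), ``negative``, or ``both``
        (bivariate least squares on S+ and S-).
    fixed_edges
        Optional boolean edge mask.  When given, feature selection is
        skipped and the mask's edges are split into positive/negative sets
        by their training-fold correlation sign (the fixed-edge control
        model used to test whether discriminatory edges predict behaviour).

    Attributes (after fit)
    ----------------------
    r_, pvals_ : per-edge training correlation and p-value
    pos_edges_, neg_edges_ : boolean selection masks per side
    coef_ : dict side -> (intercept, slope[s])
    """

    def __init__(
        self,
        threshold_p: float = 0.01,
        model_side: str = "positive",
        fixed_edges: np.ndarray | None = None,
    ):
        self.threshold_p = threshold_p
        self.model_side = model_side
        self.fixed_edges = fixed_edges

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_subjects, n_edges) aligned with y")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 training subjects")
        r, p = edgewise_correlation(X, y)
        self.r_, self.pvals_ = r, p
        if self.fixed_edges is not None:
            mask = np.asarray(self.fixed_edges, dtype=bool)
            if not mask.any():
                raise ValueError("fixed_edges mask is empty")
            self.pos_edges_ = mask & (r > 0)
            self.neg_edges_ = mask & (r < 0)
        else:
            self.pos_edges_ = (r > 0) & (p < self.threshold_p)
            self.neg_edges_ = (r < 0) & (p < self.threshold_p)
        self.ymean_ = float(y.mean())
        self.coef_ = {}
        for side, mask in (("positive", self.pos_edges_), ("negative", self.neg_edges_)):
            if not mask.any():
                logger.info("empty %s edge set; side predicts the training mean", side)
                self.coef_[side] = (self.ymean_, 0.0)
                continue
            s = X[:, mask].sum(axis=1)
            if np.std(s) == 0:
                self.coef_[side] = (self.ymean_, 0.0)
            else:
                slope, intercept = np.polyfit(s, y, 1)
                self.coef_[side] = (float(intercept), float(slope))
        sp = X[:, self.pos_edges_].sum(axis=1)
        sn = X[:, self.neg_edges_].sum(axis=1)
        A = np.column_stack([np.ones_like(y), sp, sn])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.coef_["both"] = tuple(float(c) for c in coef)
        return self

    def _summary(self, X, side: str) -> np.ndarray:
        mask = self.pos_edges_ if side == "positive" else self.neg_edges_
        return np.asarray(X, dtype=float)[:, mask].sum(axis=1)

    def predict_side(self, X, side: str) -> np.ndarray:
        check_is_fitted(self, "coef_")
        if side == "both":
            b0, b1, b2 = self.coef_["both"]
            return b0 + b1 * self._summary(X, "positive") + b2 * self._summary(X, "negative")
        intercept, slope = self.coef_[side]
        if slope == 0.0:
            return np.full(np.asarray(X).shape[0], intercept)
        return intercept + slope * self._summary(X, side)

    def predict(self, X):
        return self.predict_side(X, self.model_side)


def cpm_fold(
    train_edges: np.ndarray,
    train_y: np.ndarray,
    test_edges: np.ndarray,
    threshold_p: float = 0.01,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """One CPM fold: test predictions and selected edge sets per side."""
    est = CPMRegressor(threshold_p=threshold_p).fit(train_edges, train_y)
    preds = {side: est.predict_side(test_edges, side) for side in SIDES}
    sets = {"positive": est.pos_edges_, "negative": est.neg_edges_}
    return preds, sets


def _complete_cases(X, y, subjects):
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    subs = [s for s, k in zip(subjects, keep) if k] if subjects is not None else None
    return np.asarray(X, dtype=float)[keep], y[keep], subs


def _repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    config: CPMConfig,
    fold_fn,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Repeated k-fold protocol shared by CPM, fixed-edge CPM and SVR.

    ``fold_fn(train_X, train_y, test_X, rep, fold)`` returns
    (per-side test predictions, per-side boolean selected sets).
    """
    n, E = X.shape
    if n < config.k_folds:
        raise ValueError("fewer complete subjects than folds")
    rng = np.random.default_rng(config.seed)
    pred_sum = {side: np.zeros(n) for side in ("positive", "negative", "both")}
    sel_count = {side: np.zeros(E) for side in SIDES}
    for rep in range(config.n_repeats):
        kf = KFold(
            n_splits=config.k_folds,
            shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        for fold, (tr, te) in enumerate(kf.split(X)):
            preds, sets = fold_fn(X[tr], y[tr], X[te], rep, fold)
            for side in preds:
                pred_sum[side][te] += preds[side]
            for side in SIDES:
                sel_count[side] += sets[side]
    predictions = {s: v / config.n_repeats for s, v in pred_sum.items()}
    frequency = {
        s: c / (config.k_folds * config.n_repeats) for s, c in sel_count.items()
    }
    return predictions, frequency


def _evaluate(
    predictions: dict[str, np.ndarray],
    frequency: dict[str, np.ndarray],
    y: np.ndarray,
    subjects,
    config: CPMConfig,
) -> PredictionResult:
    pred = predictions[config.model_side]
    rho = float(stats.spearmanr(pred, y).statistic)
    pearson = float(stats.pearsonr(pred, y).statistic)
    result = PredictionResult(
        predictions=pred,
        subjects=subjects if subjects is not None else [str(i) for i in range(y.size)],
        selection_frequency=frequency,
        rho=rho,
        pearson_r=pearson,
        p_value=None,
        n_complete=int(y.size),
    )
    if config.n_perm > 0:
        result.p_value, result.perm_rhos = prediction_permutation_test(
            pred, y, n_perm=config.n_perm, seed=config.seed
        )
    return result


def run_cpm(
    X: np.ndarray,
    y: np.ndarray,
    config: CPMConfig | None = None,
    subjects: list[str] | None = None,
) -> PredictionResult:
    """Full CPM protocol: repeated k-fold CV, averaged predictions, evaluation.

    ``X`` is the (n_subjects, E) session-mean edge matrix; subjects with a
    missing (NaN) score are dropped case by case.  Each repeat draws a fresh
    shuffled size-balanced partition into ``k_folds`` folds; each subject is
    predicted once per repeat and the predictions are averaged over repeats.
    ``selection_frequency`` is the fraction of all folds in which each edge
    entered the positive/negative set.
    """
    config = config or CPMConfig()
    X, y, subjects = _complete_cases(X, y, subjects)

    def fold_fn(tr_X, tr_y, te_X, rep, fold):
        est = CPMRegressor(
            threshold_p=config.threshold_p, model_side=config.model_side
        ).fit(tr_X, tr_y)
        preds = {s: est.predict_side(te_X, s) for s in ("positive", "negative", "both")}
        return preds, {"positive": est.pos_edges_, "negative": est.neg_edges_}

    predictions, frequency = _repeated_cv(X, y, config, fold_fn)
    return _evaluate(predictions, frequency, y, subjects, config)


def predict_with_fixed_edges(
    X: np.ndarray,
    y: np.ndarray,
    mask: EdgeMask | np.ndarray,
    config: CPMConfig | None = None,
    subjects: list[str] | None = None,
) -> PredictionResult:
    """CPM with the feature-selection step replaced by a fixed edge set.

    Used as the control model that asks whether highly discriminatory edges
    can predict behaviour directly: every fold uses the same mask, split into
    positive/negative sets by each edge's training-fold correlation sign.
    """
    config = config or CPMConfig()
    bits = mask.bits if isinstance(mask, EdgeMask) else np.asarray(mask, dtype=bool)
    if not bits.any():
        raise ValueError("fixed edge mask is empty")
    X, y, subjects = _complete_cases(X, y, subjects)

    def fold_fn(tr_X, tr_y, te_X, rep, fold):
        est = CPMRegressor(
            threshold_p=config.threshold_p,
            model_side=config.model_side,
            fixed_edges=bits,
        ).fit(tr_X, tr_y)
        preds = {s: est.predict_side(te_X, s) for s in ("positive", "negative", "both")}
        return preds, {"positive": est.pos_edges_, "negative": est.neg_edges_}

    predictions, frequency = _repeated_cv(X, y, config, fold_fn)
    return _evaluate(predictions, frequency, y, subjects, config)


def run_svr(
    X: np.ndarray,
    y: np.ndarray,
    config: CPMConfig | None = None,
    weight_pct: float = 99,
    subjects: list[str] | None = None,
) -> PredictionResult:
    """Linear support-vector-regression variant of the prediction protocol.

    Per fold, an L1-regularised linear model with epsilon-insensitive loss
    (regularisation strength 0.0035) is fitted on all edges; the "selected"
    edges of the fold are those at or above the ``weight_pct`` percentile of
    |weight| (reported symmetrically under both sides, split by weight
    sign).  Selection frequencies aggregate exactly as in CPM, so the
    at-least-80%-of-folds rule yields the SVR predictive mask.
    """
    config = config or CPMConfig()
    X, y, subjects = _complete_cases(X, y, subjects)
    rng = np.random.default_rng(config.seed)

    def fold_fn(tr_X, tr_y, te_X, rep, fold):
        est = SGDRegressor(
            loss="epsilon_insensitive",
            penalty="l1",
            alpha=0.0035,
            max_iter=2000,
            tol=1e-4,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(tr_X, tr_y)
        w = est.coef_
        sel = threshold_percentile(np.abs(w), pct=weight_pct).bits
        pred = est.predict(te_X)
        preds = {"positive": pred, "negative": pred, "both": pred}
        return preds, {"positive": sel & (w > 0), "negative": sel & (w <= 0)}

    predictions, frequency = _repeated_cv(X, y, config, fold_fn)
    frequency["combined"] = frequency["positive"] + frequency["negative"]
    return _evaluate(predictions, frequency, y, subjects, config)


def prediction_permutation_test(
    predictions: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Right-tailed permutation p for Spearman(predictions, y).

    Each permutation correlates the (fixed) averaged predictions with a
    random permutation of the measured scores;
    ``p = #{perm rho > observed rho} / (n_perm + 1)``.
    """
    pred = np.asarray(predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    rp = stats.rankdata(pred)
    ry = stats.rankdata(y)
    rp = (rp - rp.mean()) / rp.std()
    ry_c = ry - ry.mean()
    sd = ry_c.std()
    observed = float(np.mean(rp * ry_c / sd))
    perm = np.empty(n_perm)
    for b in range(n_perm):
        perm[b] = np.mean(rp * rng.permutation(ry_c)) / sd
    p = float(np.sum(perm > observed) / (n_perm + 1))
    return p, perm
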