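"""Chemometric building blocks: PLS-DA, Bayes thresholds, VIP, splits, ROC.

Everything here is implemented from first principles, the way the classical
chemometrics toolchain defines it:

* PLS1 regression by NIPALS with X-deflation; at full rank its predictions
  coincide with ordinary least squares, which the test suite exploits as an
  oracle.
* PLS-DA: PLS on a 0/1 class indicator, with the decision threshold placed
  where the posterior class probability equals 0.5 under per-class Gaussian
  densities of the predicted response (Bayes' rule with class-frequency
  priors).
* VIP (variable importance in projection) with the standard normalization
  (the squared scores average to 1 over variables).
* Kennard-Stone max-min selection for calibration/validation splitting,
  venetian-blinds (interleaved) cross-validation for choosing the number of
  latent variables, ROC/AUC by threshold sweep, PCA by SVD, and RSD%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "mean_center",
    "PlsModel",
    "fit_pls",
    "GaussianPosterior",
    "bayes_threshold",
    "PlsDaClassifier",
    "fit_plsda",
    "vip_scores",
    "SplitPlan",
    "kennard_stone_split",
    "venetian_blinds_cv",
    "RocResult",
    "roc_curve",
    "pca",
    "rsd_percent",
]

log = logging.getLogger(__name__)


def mean_center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column mean-centering; returns the centered matrix and the offsets."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("mean_center needs a 2-D matrix with >= 2 rows")
    offsets = X.mean(axis=0)
    return X - offsets, offsets


# ----------------------------------------------------------------- PLS1
@dataclass
class PlsModel:
    """Fitted PLS1 model (NIPALS, X-deflation).

    ``weights`` W, ``x_loadings`` P and ``y_loadings`` q are per-component;
    ``scores`` T holds the training latent variables; ``coef`` b gives
    predictions ``y_hat = y_mean + (X - x_mean) @ b``.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray     # (p, A), unit-norm columns
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    scores: np.ndarray      # (n, A)
    coef: np.ndarray        # (p,)
    x_names: list[str] = field(default_factory=list)

    def coef_for(self, a: int) -> np.ndarray:
        """Regression vector using only the first ``a`` components."""
        W, P, q = self.weights[:, :a], self.x_loadings[:, :a], self.y_loadings[:a]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        b = self.coef if n_components is None else self.coef_for(n_components)
        return self.y_mean + (X - self.x_mean) @ b

    def explained_y_variance(self) -> np.ndarray:
        """Per-component y sum of squares captured (q_a^2 * t_a't_a)."""
        tt = (self.scores**2).sum(axis=0)
        return self.y_loadings**2 * tt


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int,
            x_names: list[str] | None = None) -> PlsModel:
    """Fit a PLS1 model by NIPALS with X-deflation.

    Components are extracted sequentially: the weight vector is the
    covariance direction ``X'y`` (unit norm), scores ``t = Xw``, and X is
    deflated by the rank-one reconstruction ``t p'`` before the next
    component.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X rows must match y length")
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, min(n-1, p)] = "
                         f"[1, {min(n - 1, p)}]")
    Xc, x_mean = mean_center(X)
    if not np.any(Xc):
        raise ValueError("zero-variance X: PLS is degenerate")
    y_mean = float(y.mean())
    yc = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            raise ValueError(f"component {a + 1}: X carries no remaining "
                             "covariance with y")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-14:
            raise ValueError(f"component {a + 1}: degenerate score vector")
        P[:, a] = Xd.T @ t / tt
        q[a] = float(yd @ t) / tt
        W[:, a], T[:, a] = w, t
        Xd -= np.outer(t, P[:, a])
        yd = yd - q[a] * t
    model = PlsModel(n_components, x_mean, y_mean, W, P, q, T,
                     coef=np.zeros(p), x_names=list(x_names or []))
    model.coef = model.coef_for(n_components)
    return model


def vip_scores(model: PlsModel) -> np.ndarray:
    """Variable importance in projection.

    ``VIP_j = sqrt(p * sum_a SSY_a * w_ja^2 / sum_a SSY_a)`` with unit-norm
    weight vectors, so the squared scores always average to 1.
    """
    ssy = model.explained_y_variance()
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no y variance: VIP undefined")
    p = model.weights.shape[0]
    return np.sqrt(p * (model.weights**2 @ ssy) / total)


# ------------------------------------------------------- Bayes threshold
@dataclass
class GaussianPosterior:
    """Posterior P(class 1 | y_hat) under per-class Gaussian score densities."""

    mu0: float
    sd0: float
    mu1: float
    sd1: float
    prior1: float

    def __call__(self, y_hat) -> np.ndarray | float:
        y = np.asarray(y_hat, dtype=float)
        log0 = (np.log1p(-self.prior1) - np.log(self.sd0)
                - 0.5 * ((y - self.mu0) / self.sd0) ** 2)
        log1 = (np.log(self.prior1) - np.log(self.sd1)
                - 0.5 * ((y - self.mu1) / self.sd1) ** 2)
        m = np.maximum(log0, log1)
        post = np.exp(log1 - m) / (np.exp(log0 - m) + np.exp(log1 - m))
        return float(post) if np.isscalar(y_hat) else post


def bayes_threshold(y_hat_cal: np.ndarray, y_true_cal: np.ndarray,
                    ) -> tuple[float, GaussianPosterior]:
    """Decision threshold and probability map from calibration predictions.

    One Gaussian is fitted per class to the calibration predicted responses;
    priors are the class frequencies; the threshold is the response value
    between the class means where the posterior probability of class 1
    equals 0.5.  With (near-)zero within-class variance the midpoint of the
    class means is used instead and a warning is logged.
    """
    y_hat = np.asarray(y_hat_cal, dtype=float).ravel()
    y_true = np.asarray(y_true_cal).ravel().astype(int)
    s1, s0 = y_hat[y_true == 1], y_hat[y_true == 0]
    if len(s0) < 3 or len(s1) < 3:
        raise ValueError("each class needs >= 3 calibration samples "
                         f"(got {len(s0)} / {len(s1)})")
    mu0, mu1 = float(s0.mean()), float(s1.mean())
    sd0 = float(s0.std(ddof=1))
    sd1 = float(s1.std(ddof=1))
    prior1 = len(s1) / len(y_hat)
    lo, hi = sorted((mu0, mu1))
    if min(sd0, sd1) < 1e-12 * max(1.0, hi - lo) or hi - lo < 1e-12:
        log.warning("degenerate class score distributions; falling back to "
                    "midpoint threshold")
        sd = max(sd0, sd1, 1e-12)
        posterior = GaussianPosterior(mu0, sd, mu1, sd, prior1)
        return 0.5 * (mu0 + mu1), posterior
    posterior = GaussianPosterior(mu0, sd0, mu1, sd1, prior1)
    f = lambda x: posterior(x) - 0.5
    if f(lo) * f(hi) < 0:
        thr = float(brentq(f, lo, hi, xtol=1e-12))
    else:  # near-coincident classes or extreme priors: no crossing between means
        log.debug("posterior does not cross 0.5 between class means; "
                  "using midpoint threshold")
        thr = 0.5 * (mu0 + mu1)
    return thr, posterior


# --------------------------------------------------------------- PLS-DA
@dataclass
class PlsDaClassifier:
    """Binary PLS-DA: PLS on a 0/1 indicator plus a Bayes decision rule."""

    pls: PlsModel
    threshold: float
    posterior: GaussianPosterior
    positive_label: str = "1"
    negative_label: str = "0"
    cv_errors: np.ndarray | None = None  # per-n_components CV error

    @property
    def n_components(self) -> int:
        return self.pls.n_components

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.pls.predict(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Posterior probability of the positive class."""
        return np.asarray(self.posterior(self.decision_values(X)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def fit_plsda(X: np.ndarray, y: np.ndarray,
              max_components: int = 10,
              n_splits: int = 10,
              positive_label: str = "1",
              negative_label: str = "0",
              x_names: list[str] | None = None) -> PlsDaClassifier:
    """Fit a PLS-DA classifier with CV-selected latent-variable count.

    The number of components is chosen by venetian-blinds cross-validation
    (smallest count minimizing the misclassification rate); the Bayes
    threshold is then refitted on the full calibration set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    errors, a_best = venetian_blinds_cv(X, y, n_splits=n_splits,
                                        max_components=max_components)
    model = fit_pls(X, y, a_best, x_names=x_names)
    thr, posterior = bayes_threshold(model.predict(X), y)
    return PlsDaClassifier(model, thr, posterior, positive_label,
                           negative_label, cv_errors=errors)


# ---------------------------------------------------------- Kennard-Stone
@dataclass
class SplitPlan:
    """Calibration/validation split with optional CV fold assignment."""

    calibration: np.ndarray  # indices in Kennard-Stone selection order
    validation: np.ndarray   # remaining indices, original order
    n_total: int

    def __post_init__(self) -> None:
        combined = np.sort(np.concatenate([self.calibration, self.validation]))
        if not np.array_equal(combined, np.arange(self.n_total)):
            raise ValueError("calibration and validation must partition samples")


def kennard_stone_split(X: np.ndarray,
                        calibration_fraction: float = 0.75) -> SplitPlan:
    """Greedy max-min (Kennard-Stone) selection of a calibration subset.

    The first two picks are the most distant pair; every further pick
    maximizes its minimum Euclidean distance (on mean-centered features) to
    the already-selected set.  Deterministic; distance ties break to the
    lowest sample index.  The selection order is preserved in the plan so
    interleaved CV folds can be laid across the design space.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("Kennard-Stone needs >= 4 samples")
    n_cal = int(round(calibration_fraction * n))
    n_cal = min(max(n_cal, 2), n - 1)
    Xc = X - X.mean(axis=0)
    sq = (Xc**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Xc @ Xc.T)
    np.maximum(d2, 0.0, out=d2)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)  # first occurrence
    selected = [min(i, j), max(i, j)]
    min_d2 = np.minimum(d2[selected[0]], d2[selected[1]])
    min_d2[selected] = -1.0
    while len(selected) < n_cal:
        nxt = int(np.argmax(min_d2))
        selected.append(nxt)
        np.minimum(min_d2, d2[nxt], out=min_d2)
        min_d2[nxt] = -1.0
    mask = np.zeros(n, dtype=bool)
    mask[selected] = True
    return SplitPlan(calibration=np.array(selected),
                     validation=np.flatnonzero(~mask), n_total=n)


# --------------------------------------------------- venetian blinds CV
def venetian_blinds_cv(X: np.ndarray, y: np.ndarray,
                       n_splits: int = 10,
                       max_components: int = 10) -> tuple[np.ndarray, int]:
    """Interleaved-fold CV misclassification per latent-variable count.

    Fold *f* holds the samples at positions f, f+n_splits, f+2*n_splits, ...
    of the given sample order.  Each fold is predicted by a model (PLS fit +
    Bayes threshold) trained on the remaining samples; the selected count is
    the smallest one minimizing the pooled misclassification rate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    n, p = X.shape
    if n_splits > n:
        raise ValueError("more CV splits than samples")
    n_splits = max(2, n_splits)
    a_cap = 0
    errors: list[list[int]] = []
    fold_sizes = []
    for f in range(n_splits):
        test = np.arange(f, n, n_splits)
        train = np.setdiff1d(np.arange(n), test)
        ytr = y[train]
        if len(np.unique(ytr)) < 2:
            warnings.warn(f"CV fold {f}: training remainder has one class; "
                          "fold skipped")
            continue
        if len(np.unique(y[test])) < 2:
            warnings.warn(f"CV fold {f}: held-out samples are single-class")
        a_max = min(max_components, min(len(train) - 1, p))
        a_cap = max(a_cap, a_max)
        model = fit_pls(X[train], ytr, a_max)
        fold_err = []
        for a in range(1, a_max + 1):
            yhat_tr = model.predict(X[train], n_components=a)
            thr, posterior = bayes_threshold(yhat_tr, ytr)
            pred = np.asarray(posterior(model.predict(X[test],
                                                      n_components=a))) >= 0.5
            fold_err.append(int(np.sum(pred.astype(int) != y[test])))
        errors.append(fold_err)
        fold_sizes.append(len(test))
    if not errors:
        raise ValueError("no usable CV folds")
    total = sum(fold_sizes)
    rates = np.full(a_cap, np.nan)
    for a in range(a_cap):
        got = [e[a] for e in errors if len(e) > a]
        if len(got) == len(errors):
            rates[a] = sum(got) / total
    valid = np.flatnonzero(~np.isnan(rates))
    best = valid[np.argmin(rates[valid])]  # argmin → smallest index on ties
    return rates, int(best) + 1


# ----------------------------------------------------------------- ROC
@dataclass
class RocResult:
    fpr: np.ndarray  # 1 - specificity, nondecreasing
    tpr: np.ndarray  # sensitivity, nondecreasing
    auc: float
    operating_point: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")


def roc_curve(y_true: np.ndarray, scores: np.ndarray,
              operating_threshold: float | None = None) -> RocResult:
    """ROC by sweeping the decision threshold over the unique scores.

    AUC is the trapezoid-rule area; with an ``operating_threshold`` (the
    model's Bayes threshold) the achieved (1-specificity, sensitivity) pair
    is recorded as the operating point.
    """
    y = np.asarray(y_true).astype(int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    # collapse tied scores into single threshold steps
    distinct = np.r_[np.flatnonzero(np.diff(s[order])), y.size - 1]
    tps = np.cumsum(ys)[distinct]
    fps = distinct + 1 - tps
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    auc = float(np.trapezoid(tpr, fpr))
    op = None
    if operating_threshold is not None:
        pred = s >= operating_threshold
        op = (float(np.sum(pred & (y == 0)) / n0),
              float(np.sum(pred & (y == 1)) / n1))
    return RocResult(fpr, tpr, auc, op)


# ----------------------------------------------------------------- PCA
def pca(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA by SVD of the mean-centered matrix.

    Returns (scores, loadings, explained-variance %); percentages sum to 100
    over all components and ``scores @ loadings.T`` reconstructs the
    centered data.
    """
    Xc, _ = mean_center(np.asarray(X, dtype=float))
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    var = s**2
    expl = 100.0 * var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return scores, Vt.T, expl


def rsd_percent(values) -> float:
    """Relative standard deviation, 100 * sample SD / mean."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("RSD%% needs >= 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("RSD%% undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)
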