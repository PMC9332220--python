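"""Weighted multinomial lasso with unpenalized covariates.

The marker-selection model is an L1-penalized multinomial logistic
regression fitted on binary seropositivity calls, with age and sex
entering unpenalized (penalty factor zero) and per-sample weights
balancing the disease classes. The fitted objective is

    (1 / sum w) * sum_i w_i * [logsumexp_k(eta_ik) - eta_i,y(i)]
        + lambda * sum_j pf_j * sum_k |beta_jk|

with eta_ik = b_k + x_i . beta_k, solved by FISTA (accelerated proximal
gradient with backtracking line search and adaptive restart) over the
symmetric (over-parameterized) multinomial coding. The L1 penalty pins
down the penalized coefficients; for unpenalized rows the gradient is
orthogonal to the all-classes-equal null direction, so starting from
zero keeps them sum-to-zero across classes — the identifiability
convention under which coefficient signs are reported.

``lambda`` is chosen on a geometric grid below the smallest value that
zeroes every penalized coefficient, by inner stratified cross-validation
on the weighted multinomial deviance. The default one-SE rule picks the
sparsest model within one standard error of the deviance minimum —
appropriate when the goal is marker selection; the prediction-oriented
minimum rule is available as a config flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted


class ConvergenceError(RuntimeError):
    """The proximal-gradient solver did not reach the requested tolerance."""


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = {c: k for k, c in enumerate(classes)}
    Y = np.zeros((len(y), len(classes)))
    Y[np.arange(len(y)), [idx[v] for v in y]] = 1.0
    return Y


def _nll(Xa: np.ndarray, Y: np.ndarray, wn: np.ndarray, B: np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted mean negative log-likelihood and class probabilities."""
    eta = Xa @ B
    lse = logsumexp(eta, axis=1)
    val = float(np.sum(wn * (lse - (eta * Y).sum(axis=1))))
    P = np.exp(eta - lse[:, None])
    return val, P


def _fista(
    Xa: np.ndarray,
    Y: np.ndarray,
    wn: np.ndarray,
    pen: np.ndarray,
    lam: float,
    B0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int]:
    """Minimise the penalized objective; returns (B, objective, iterations)."""

    def g_val(B: np.ndarray) -> float:
        return float(lam * (pen[:, None] * np.abs(B)).sum())

    def prox(B: np.ndarray, step: float) -> np.ndarray:
        thresh = step * lam * pen[:, None]
        return np.sign(B) * np.maximum(np.abs(B) - thresh, 0.0)

    B = B0.copy()
    Z = B0.copy()
    t = 1.0
    # Softmax Hessian is bounded by (1/2) X' diag(wn) X; a crude spectral
    # bound seeds the backtracking.
    L = max(0.5 * float((wn[:, None] * Xa**2).sum()), 1e-8)
    f_b, _ = _nll(Xa, Y, wn, B)
    obj_prev = f_b + g_val(B)
    B_best, obj_best = B.copy(), obj_prev
    hits = 0
    for it in range(1, max_iter + 1):
        f_z, P_z = _nll(Xa, Y, wn, Z)
        G = Xa.T @ ((P_z - Y) * wn[:, None])
        while True:
            Bn = prox(Z - G / L, 1.0 / L)
            D = Bn - Z
            f_bn, _ = _nll(Xa, Y, wn, Bn)
            if f_bn <= f_z + float((G * D).sum()) + 0.5 * L * float((D * D).sum()) + 1e-12:
                break
            L *= 2.0
        new_obj = f_bn + g_val(Bn)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        if new_obj > obj_prev:  # adaptive restart: drop momentum
            Z = Bn.copy()
            t = 1.0
        else:
            Z = Bn + ((t - 1.0) / t_next) * (Bn - B)
            t = t_next
        delta = abs(obj_prev - new_obj)
        B = Bn
        obj_prev = new_obj
        if new_obj < obj_best:
            B_best, obj_best = Bn.copy(), new_obj
        if delta <= tol * max(1.0, abs(new_obj)):
            hits += 1
            if hits >= 3:
                return B_best, obj_best, it
        else:
            hits = 0
        L = max(L * 0.9, 1e-8)
    raise ConvergenceError(
        f"FISTA did not converge in {max_iter} iterations "
        f"(last objective change {delta:.3e}, lambda={lam:.3e})"
    )


@dataclass
class PathFit:
    """A lasso path at a fixed lambda grid."""

    lambdas: np.ndarray
    intercepts: np.ndarray  # n_lambda x K
    coefs: np.ndarray  # n_lambda x p x K
    train_deviance: np.ndarray
    classes: np.ndarray


def fit_multinomial_path(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    penalty_factor: np.ndarray | None = None,
    lambdas: np.ndarray | None = None,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
    classes: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 20000,
) -> PathFit:
    """Fit the weighted multinomial lasso along a decreasing lambda grid.

    The grid starts at the smallest lambda at which every penalized
    coefficient is exactly zero (found from the gradient at the
    unpenalized-covariates-only fit) and decreases geometrically;
    solutions warm-start each other. The intercept is always unpenalized.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, p = X.shape
    if classes is None:
        classes = np.unique(y)
    K = len(classes)
    Y = _one_hot(y, classes)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("sample weights must be non-negative with positive sum")
    wn = w / w.sum()
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    if len(pf) != p or (pf < 0).any():
        raise ValueError("penalty_factor must be non-negative, one per feature")

    Xa = np.hstack([np.ones((n, 1)), X])
    pen = np.concatenate([[0.0], pf])

    # Null model: intercept + unpenalized covariates only.
    free = pen == 0.0
    B_null = np.zeros((p + 1, K))
    B_free, _, _ = _fista(Xa[:, free], Y, wn, np.zeros(free.sum()), 0.0, B_null[free], tol, max_iter)
    B_null[free] = B_free
    _, P0 = _nll(Xa, Y, wn, B_null)
    G0 = Xa.T @ ((P0 - Y) * wn[:, None])
    with np.errstate(divide="ignore"):
        lam_rows = np.abs(G0).max(axis=1) / np.where(pen > 0, pen, np.inf)
    lam_max = float(lam_rows.max())
    if lambdas is None:
        if lam_max <= 0:
            lam_max = 1e-3
        lambdas = lam_max * np.power(lambda_min_ratio, np.linspace(0.0, 1.0, n_lambdas))
    lambdas = np.asarray(lambdas, float)
    if not np.all(np.diff(lambdas) < 0):
        raise ValueError("lambda grid must be strictly decreasing")

    intercepts = np.zeros((len(lambdas), K))
    coefs = np.zeros((len(lambdas), p, K))
    train_dev = np.zeros(len(lambdas))
    B = B_null.copy()
    for i, lam in enumerate(lambdas):
        B, _, _ = _fista(Xa, Y, wn, pen, float(lam), B, tol, max_iter)
        intercepts[i] = B[0]
        coefs[i] = B[1:]
        f_val, _ = _nll(Xa, Y, wn, B)
        train_dev[i] = 2.0 * f_val
    return PathFit(
        lambdas=lambdas,
        intercepts=intercepts,
        coefs=coefs,
        train_deviance=train_dev,
        classes=np.asarray(classes),
    )


def weighted_deviance(
    P: np.ndarray, y: np.ndarray, classes: np.ndarray, sample_weight: np.ndarray | None = None
) -> float:
    """Weighted mean multinomial deviance, -2 * mean_w log p(true class)."""
    Y = _one_hot(np.asarray(y), np.asarray(classes))
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
    p_true = np.clip((P * Y).sum(axis=1), 1e-12, None)
    return float(-2.0 * np.sum(w * np.log(p_true)) / w.sum())


class MultinomialLassoCV(BaseEstimator, ClassifierMixin):
    """Weighted multinomial lasso classifier with inner-CV lambda selection.

    Parameters
    ----------
    penalty_factor : array-like of shape (n_features,) or None
        Per-feature L1 multipliers; 0 leaves a covariate unpenalized.
    n_lambdas, lambda_min_ratio : grid geometry below the data-driven
        lambda_max.
    cv : int
        Inner stratified folds for lambda selection.
    rule : {"1se", "min"}
        The sparsest lambda within one standard error of the
        minimum-deviance lambda (default, selection-oriented), or the
        minimum itself (prediction-oriented).
    class_order : sequence or None
        Report/argmax order of classes; defaults to np.unique(y).
    """

    def __init__(
        self,
        penalty_factor=None,
        n_lambdas: int = 50,
        lambda_min_ratio: float = 0.01,
        cv: int = 5,
        rule: str = "1se",
        class_order=None,
        tol: float = 1e-9,
        max_iter: int = 20000,
        random_state: int | None = None,
    ):
        self.penalty_factor = penalty_factor
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.rule = rule
        self.class_order = class_order
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        if self.rule not in ("min", "1se"):
            raise ValueError("rule must be 'min' or '1se'")
        if self.class_order is not None:
            classes = np.asarray(list(self.class_order))
            missing = set(np.unique(y)) - set(classes)
            if missing:
                raise ValueError(f"labels {missing} not in class_order")
        else:
            classes = np.unique(y)
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)

        path = fit_multinomial_path(
            X,
            y,
            sample_weight=w,
            penalty_factor=self.penalty_factor,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            classes=classes,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        lambdas = path.lambdas

        skf = StratifiedKFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        fold_dev = np.zeros((self.cv, len(lambdas)))
        for fi, (tr, va) in enumerate(skf.split(X, y)):
            sub = fit_multinomial_path(
                X[tr],
                y[tr],
                sample_weight=w[tr],
                penalty_factor=self.penalty_factor,
                lambdas=lambdas,
                classes=classes,
                tol=self.tol,
                max_iter=self.max_iter,
            )
            for li in range(len(lambdas)):
                eta = sub.intercepts[li] + X[va] @ sub.coefs[li]
                P = softmax(eta, axis=1)
                fold_dev[fi, li] = weighted_deviance(P, y[va], classes, w[va])
        dev_mean = fold_dev.mean(axis=0)
        dev_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(self.cv)
        best = int(np.argmin(dev_mean))
        if self.rule == "1se":
            ok = dev_mean <= dev_mean[best] + dev_se[best]
            best = int(np.argmax(ok))  # largest lambda within one SE

        self.classes_ = classes
        self.lambda_path_ = lambdas
        self.cv_deviance_ = dev_mean
        self.cv_deviance_se_ = dev_se
        self.lambda_index_ = best
        self.lambda_ = float(lambdas[best])
        self.intercept_ = path.intercepts[best].copy()
        self.coef_ = path.coefs[best].T.copy()  # K x p, sklearn convention
        self.coef_path_ = path.coefs
        self.intercept_path_ = path.intercepts
        self.train_deviance_ = path.train_deviance
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return self.intercept_ + np.asarray(X, float) @ self.coef_.T

    def predict_proba(self, X):
        return softmax(self.decision_function(X), axis=1)

    def predict(self, X):
        P = self.predict_proba(X)
        return self.classes_[np.argmax(P, axis=1)]


def selected_markers(
    coef: np.ndarray, feature_names, penalty_factor=None
) -> list[str]:
    """Penalized features with any nonzero class coefficient.

    Ordered by the max-over-classes absolute coefficient, descending,
    ties broken by name. ``coef`` is (K, p) as fitted.
    """
    coef = np.asarray(coef)
    names = list(feature_names)
    pf = np.ones(len(names)) if penalty_factor is None else np.asarray(penalty_factor, float)
    mag = np.abs(coef).max(axis=0)
    picked = [(names[j], mag[j]) for j in range(len(names)) if pf[j] > 0 and mag[j] > 0]
    picked.sort(key=lambda t: (-t[1], t[0]))
    return [name for name, _ in picked]


def fit_design(design, **params) -> tuple[MultinomialLassoCV, list[str]]:
    """Fit the marker-selection model on a CohortDesign.

    Features are the binary antigen calls (penalized) plus standardized
    age and a sex indicator (unpenalized). Returns the fitted estimator
    and the selected antigen list.
    """
    from .arrays import CLASS_ORDER  # local import to avoid cycle at module load

    antigens = list(design.X.columns)
    X = np.column_stack(
        [design.X.to_numpy(float), design.age_z.to_numpy(float), design.sex01.to_numpy(float)]
    )
    pf = np.concatenate([np.ones(len(antigens)), [0.0, 0.0]])
    present = [c for c in CLASS_ORDER if c in set(design.y)]
    est = MultinomialLassoCV(penalty_factor=pf, class_order=present, **params)
    est.fit(X, design.y.to_numpy(), sample_weight=design.weights.to_numpy(float))
    markers = selected_markers(est.coef_[:, : len(antigens)], antigens)
    return est, markers
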