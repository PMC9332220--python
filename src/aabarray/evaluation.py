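"""Multiclass discrimination metrics and marker/panel performance.

Pairwise AUCs follow Hand and Till: for classes i and j, all samples of
the two classes are ranked by the model's probability of class i, and

    A(i|j) = (S_i - n_i (n_i + 1) / 2) / (n_i n_j)

with S_i the sum of midranks of the class-i samples (the Mann–Whitney
statistic, ties counting one half). The symmetrized A(i, j) is the mean
of A(i|j) and A(j|i), and the M-value — a global multiclass AUC — is the
average of the c(c-1)/2 symmetrized pairwise AUCs.

Cross-validated counterparts come from an outer stratified k-fold loop
that refits the whole model (lambda re-chosen by inner CV, class weights
recomputed on the training split) and pools the held-out class
probabilities.

Marker and panel sensitivity/specificity address the clinical low-risk
vs high-risk IPMN dichotomy (LR = low-grade; HR = high-grade or with
associated invasive carcinoma): a marker is scored in the group where it
is the more prevalent, and a panel calls a sample positive when at least
one member antigen does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .arrays import CLASS_ORDER, IPMN_HR_CLASSES, IPMN_LR_CLASSES
from .features import CohortDesign, class_weights
from .model import MultinomialLassoCV, fit_design, selected_markers, weighted_deviance


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (102.25 -> 102.3), as in tabular reporting."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Hand–Till AUCs
# ---------------------------------------------------------------------------


def pairwise_auc(scores: np.ndarray, labels: np.ndarray, class_i, class_j) -> float:
    """A(i|j): probability-of-class-i ranking restricted to classes i and j."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    mask = (labels == class_i) | (labels == class_j)
    s = scores[mask]
    is_i = labels[mask] == class_i
    n_i = int(is_i.sum())
    n_j = int((~is_i).sum())
    if n_i == 0 or n_j == 0:
        raise ValueError("both classes must be represented")
    ranks = rankdata(s)  # midranks
    S_i = float(ranks[is_i].sum())
    return (S_i - n_i * (n_i + 1) / 2.0) / (n_i * n_j)


def auc_matrix(
    P: pd.DataFrame | np.ndarray, labels: Sequence, classes: Sequence | None = None
) -> pd.DataFrame:
    """Symmetrized pairwise AUC matrix A(i, j); diagonal is NaN.

    Pairs with an absent class are reported missing (NaN).
    """
    if isinstance(P, pd.DataFrame):
        classes = list(P.columns) if classes is None else list(classes)
        Pv = P[classes].to_numpy(float)
    else:
        if classes is None:
            raise ValueError("classes required with a bare array of probabilities")
        classes = list(classes)
        Pv = np.asarray(P, float)
    labels = np.asarray(labels)
    out = pd.DataFrame(np.nan, index=classes, columns=classes)
    present = set(labels)
    for a, b in combinations(classes, 2):
        if a not in present or b not in present:
            continue
        ia, ib = classes.index(a), classes.index(b)
        a_given_b = pairwise_auc(Pv[:, ia], labels, a, b)
        b_given_a = pairwise_auc(Pv[:, ib], labels, b, a)
        out.loc[a, b] = out.loc[b, a] = 0.5 * (a_given_b + b_given_a)
    return out


def m_value(P, labels, classes: Sequence | None = None) -> float:
    """Hand–Till M: the mean of the symmetrized pairwise AUCs."""
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("M-value needs at least two classes present")
    A = auc_matrix(P, labels, classes)
    vals = [A.loc[a, b] for a, b in combinations(A.index, 2) if not np.isnan(A.loc[a, b])]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Outer cross-validation
# ---------------------------------------------------------------------------


@dataclass
class OuterCVResult:
    """Apparent vs cross-validated discrimination of the fitted pipeline."""

    apparent_probs: pd.DataFrame
    cv_probs: pd.DataFrame
    apparent_m: float
    cv_m: float
    apparent_auc: pd.DataFrame
    cv_auc: pd.DataFrame
    apparent_confusion: pd.DataFrame
    cv_confusion: pd.DataFrame
    estimator: MultinomialLassoCV
    markers: list[str]
    n_folds: int


def confusion_frame(y_true: Sequence, y_pred: Sequence, classes: Sequence) -> pd.DataFrame:
    """Rows = true class, columns = predicted class, in the given order."""
    classes = list(classes)
    out = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        out.loc[t, p] += 1
    out.index.name = "true"
    out.columns.name = "predicted"
    return out


def outer_cv(
    design: CohortDesign,
    k: int = 10,
    seed: int | None = 0,
    **model_params,
) -> OuterCVResult:
    """Outer stratified k-fold CV of the full marker-selection model.

    Each fold holds out about 1/k of every class; the training split
    refits the model end to end (class weights recomputed, lambda
    re-chosen on inner CV). Held-out class probabilities are pooled and
    the cross-validated M-value and confusion matrix computed from them.
    Predicted class is the argmax probability, ties resolved to the
    earlier class in the fixed reporting order.
    """
    y = design.y
    present = [c for c in CLASS_ORDER if c in set(y)]
    min_class = int(y.value_counts().min())
    if min_class < k:
        warnings.warn(
            f"smallest class has {min_class} samples; outer folds reduced "
            f"from {k} to {min_class}",
            stacklevel=2,
        )
        k = min_class
    if k < 2:
        raise ValueError("outer CV needs at least 2 usable folds")

    est, markers = fit_design(design, random_state=seed, **model_params)
    antigens = list(design.X.columns)
    Xfull = np.column_stack(
        [design.X.to_numpy(float), design.age_z.to_numpy(float), design.sex01.to_numpy(float)]
    )
    apparent = pd.DataFrame(est.predict_proba(Xfull), index=design.X.index, columns=est.classes_)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    cv_probs = pd.DataFrame(np.nan, index=design.X.index, columns=present)
    pf = np.concatenate([np.ones(len(antigens)), [0.0, 0.0]])
    yv = y.to_numpy()
    for tr, va in skf.split(Xfull, yv):
        w_tr = class_weights(y.iloc[tr]).to_numpy(float)
        sub = MultinomialLassoCV(
            penalty_factor=pf,
            class_order=[c for c in present if c in set(yv[tr])],
            random_state=seed,
            **model_params,
        )
        sub.fit(Xfull[tr], yv[tr], sample_weight=w_tr)
        P_va = pd.DataFrame(
            sub.predict_proba(Xfull[va]), index=design.X.index[va], columns=sub.classes_
        )
        cv_probs.loc[P_va.index, P_va.columns] = P_va
    cv_probs = cv_probs.fillna(0.0)

    def _predict(P: pd.DataFrame) -> np.ndarray:
        Pv = P[present].to_numpy(float)
        return np.asarray(present, object)[np.argmax(Pv, axis=1)]

    apparent_auc = auc_matrix(apparent, yv, present)
    cv_auc = auc_matrix(cv_probs, yv, present)
    return OuterCVResult(
        apparent_probs=apparent,
        cv_probs=cv_probs,
        apparent_m=m_value(apparent, yv, present),
        cv_m=m_value(cv_probs, yv, present),
        apparent_auc=apparent_auc,
        cv_auc=cv_auc,
        apparent_confusion=confusion_frame(yv, _predict(apparent), present),
        cv_confusion=confusion_frame(yv, _predict(cv_probs), present),
        estimator=est,
        markers=markers,
        n_folds=k,
    )


# ---------------------------------------------------------------------------
# Low-risk vs high-risk marker and panel performance
# ---------------------------------------------------------------------------


@dataclass
class MarkerPerformance:
    antigen: str
    direction: str  # "HR" or "LR"
    n_target: int
    n_other: int
    sensitivity_pct: float
    specificity_pct: float


def marker_sens_spec(
    calls: pd.DataFrame,
    classes: pd.Series,
    marker: str,
    direction: str | None = None,
) -> MarkerPerformance:
    """Sensitivity/specificity of one marker for the IPMN LR/HR dichotomy.

    For an HR-marker, sensitivity is the positive fraction among
    high-risk IPMN and specificity the negative fraction among low-risk;
    for an LR-marker the roles swap. Direction defaults to the group
    with the higher positivity rate. Percentages are rounded half-up to
    one decimal.
    """
    cls = classes.reindex(calls.index)
    hr_mask = cls.isin(IPMN_HR_CLASSES)
    lr_mask = cls.isin(IPMN_LR_CLASSES)
    n_hr, n_lr = int(hr_mask.sum()), int(lr_mask.sum())
    if n_hr == 0 or n_lr == 0:
        raise ValueError("both IPMN risk groups must be nonempty")
    pos = calls[marker].astype(float)
    rate_hr = float(pos[hr_mask].mean())
    rate_lr = float(pos[lr_mask].mean())
    if direction is None:
        direction = "HR" if rate_hr >= rate_lr else "LR"
    if direction == "HR":
        sens = rate_hr
        spec = 1.0 - rate_lr
        n_target, n_other = n_hr, n_lr
    elif direction == "LR":
        sens = rate_lr
        spec = 1.0 - rate_hr
        n_target, n_other = n_lr, n_hr
    else:
        raise ValueError("direction must be 'HR', 'LR' or None")
    return MarkerPerformance(
        antigen=marker,
        direction=direction,
        n_target=n_target,
        n_other=n_other,
        sensitivity_pct=round_half_up(100.0 * sens),
        specificity_pct=round_half_up(100.0 * spec),
    )


def marker_table(
    calls: pd.DataFrame, classes: pd.Series, markers: Sequence[str]
) -> pd.DataFrame:
    """Per-marker LR/HR sensitivity and specificity table."""
    rows = [marker_sens_spec(calls, classes, m).__dict__ for m in markers]
    return pd.DataFrame(rows).set_index("antigen")


@dataclass
class PanelReport:
    members: list[str]
    specificity_gate_pct: float
    empty: bool
    sensitivity_pct: float | None
    specificity_pct: float | None
    n_panel_positive_hr: int | None
    n_hr: int | None
    n_lr: int | None


def panel_evaluate(
    calls: pd.DataFrame,
    classes: pd.Series,
    markers: Sequence[str],
    specificity_gate_pct: float = 90.0,
    table: pd.DataFrame | None = None,
) -> PanelReport:
    """Combine the HR-markers exceeding a specificity gate into a panel.

    Membership requires strict ``specificity > gate``. A sample is
    panel-positive when positive for at least one member; sensitivity
    and specificity are then computed exactly as for a single HR-marker.
    """
    if table is None:
        table = marker_table(calls, classes, markers)
    members = [
        a
        for a in table.index
        if table.loc[a, "direction"] == "HR"
        and table.loc[a, "specificity_pct"] > specificity_gate_pct
    ]
    if not members:
        return PanelReport(
            members=[],
            specificity_gate_pct=specificity_gate_pct,
            empty=True,
            sensitivity_pct=None,
            specificity_pct=None,
            n_panel_positive_hr=None,
            n_hr=None,
            n_lr=None,
        )
    cls = classes.reindex(calls.index)
    hr_mask = cls.isin(IPMN_HR_CLASSES)
    lr_mask = cls.isin(IPMN_LR_CLASSES)
    panel_pos = calls[members].astype(float).max(axis=1) >= 1.0
    n_hr = int(hr_mask.sum())
    n_lr = int(lr_mask.sum())
    hits_hr = int(panel_pos[hr_mask].sum())
    hits_lr = int(panel_pos[lr_mask].sum())
    return PanelReport(
        members=members,
        specificity_gate_pct=specificity_gate_pct,
        empty=False,
        sensitivity_pct=round_half_up(100.0 * hits_hr / n_hr),
        specificity_pct=round_half_up(100.0 * (1.0 - hits_lr / n_lr)),
        n_panel_positive_hr=hits_hr,
        n_hr=n_hr,
        n_lr=n_lr,
    )
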