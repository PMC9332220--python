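"""Hand–Till AUCs, M-value, outer CV partitioning, marker/panel metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from aabarray.evaluation import (
    auc_matrix,
    confusion_frame,
    m_value,
    marker_sens_spec,
    marker_table,
    pairwise_auc,
    panel_evaluate,
    round_half_up,
)


def brute_force_auc(scores_i, scores_j):
    """Concordant-pair proportion with ties counting one half."""
    wins = 0.0
    for a in scores_i:
        for b in scores_j:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(scores_i) * len(scores_j))


def test_perfect_separation_gives_auc_one():
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    labels = np.array(["i", "i", "j", "j"])
    assert pairwise_auc(scores, labels, "i", "j") == 1.0


def test_all_tied_scores_give_half():
    scores = np.zeros(10)
    labels = np.array(["i"] * 4 + ["j"] * 6)
    assert pairwise_auc(scores, labels, "i", "j") == 0.5


def test_pairwise_auc_matches_brute_force_enumeration():
    rng = np.random.default_rng(17)
    for _ in range(300):
        n_i, n_j = rng.integers(2, 12), rng.integers(2, 12)
        # coarse grid scores force plenty of ties
        si = rng.integers(0, 5, size=n_i) / 4.0
        sj = rng.integers(0, 5, size=n_j) / 4.0
        scores = np.concatenate([si, sj])
        labels = np.array(["i"] * n_i + ["j"] * n_j)
        assert pairwise_auc(scores, labels, "i", "j") == pytest.approx(
            brute_force_auc(si, sj), abs=1e-12
        )


def test_pairwise_auc_matches_sklearn_without_ties():
    rng = np.random.default_rng(3)
    scores = rng.normal(size=30)
    labels = np.array(["i"] * 12 + ["j"] * 18)
    ours = pairwise_auc(scores, labels, "i", "j")
    ref = roc_auc_score((labels == "i").astype(int), scores)
    assert ours == pytest.approx(ref, abs=1e-12)


def test_two_class_m_equals_auc_exactly():
    rng = np.random.default_rng(8)
    P = rng.dirichlet([1, 1], size=40)
    labels = np.array(["i"] * 15 + ["j"] * 25)
    P = pd.DataFrame(P, columns=["i", "j"])
    auc = pairwise_auc(P["i"].to_numpy(), labels, "i", "j")
    assert m_value(P, labels) == auc


def test_m_value_perfect_classifier_any_c():
    for c in (2, 3, 5):
        labels = np.repeat([f"c{k}" for k in range(c)], 6)
        P = pd.DataFrame(
            np.eye(c)[np.repeat(np.arange(c), 6)], columns=[f"c{k}" for k in range(c)]
        )
        assert m_value(P, labels) == 1.0


def test_m_value_invariant_under_monotone_transform():
    rng = np.random.default_rng(5)
    c = 4
    P = rng.dirichlet(np.ones(c), size=60)
    labels = np.array([f"c{k}" for k in rng.integers(0, c, size=60)])
    cols = [f"c{k}" for k in range(c)]
    base = m_value(pd.DataFrame(P, columns=cols), labels)
    transformed = m_value(pd.DataFrame(np.exp(3 * P), columns=cols), labels)
    assert transformed == pytest.approx(base, abs=1e-12)


def test_m_value_requires_two_classes():
    P = pd.DataFrame({"a": [0.6, 0.7], "b": [0.4, 0.3]})
    with pytest.raises(ValueError):
        m_value(P, np.array(["a", "a"]))


def test_auc_matrix_symmetric_with_missing_class():
    P = pd.DataFrame({"a": [0.9, 0.1, 0.5], "b": [0.1, 0.9, 0.3], "c": [0.0, 0.0, 0.2]})
    labels = np.array(["a", "b", "a"])
    A = auc_matrix(P, labels)
    assert A.loc["a", "b"] == A.loc["b", "a"]
    assert np.isnan(A.loc["a", "c"])


def test_stratified_folds_partition_each_class():
    y = np.repeat(["c1", "c2", "c3", "c4", "c5"], 20)
    X = np.zeros((100, 1))
    skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
    seen = {c: [] for c in np.unique(y)}
    for _, va in skf.split(X, y):
        labels, counts = np.unique(y[va], return_counts=True)
        assert (counts == 2).all()  # every fold holds out 2 per class
        for c, idxs in zip(y[va], va):
            seen[c].append(idxs)
    for c, idxs in seen.items():
        assert sorted(idxs) == sorted(np.flatnonzero(y == c))


def test_confusion_frame_ties_resolve_to_fixed_order():
    cm = confusion_frame(["Co", "PDAC"], ["Co", "Co"], ["Co", "PDAC"])
    assert cm.loc["Co", "Co"] == 1 and cm.loc["PDAC", "Co"] == 1
    P = pd.DataFrame({"Co": [0.4], "PDAC": [0.4]})
    pred = np.asarray(["Co", "PDAC"], object)[np.argmax(P.to_numpy(), axis=1)]
    assert pred[0] == "Co"  # earlier class wins exact ties


# --- marker and panel metrics ---


def lr_hr_calls(hr_pos, hr_total, lr_pos, lr_total, marker="M1"):
    idx = [f"H{i}" for i in range(hr_total)] + [f"L{i}" for i in range(lr_total)]
    calls = pd.DataFrame(
        {marker: [1.0] * hr_pos + [0.0] * (hr_total - hr_pos) + [1.0] * lr_pos + [0.0] * (lr_total - lr_pos)},
        index=idx,
    )
    classes = pd.Series(
        ["IPMN-HG"] * hr_total + ["IPMN-LG"] * lr_total, index=idx, name="class"
    )
    return calls, classes


def test_marker_perfect_discrimination():
    calls, classes = lr_hr_calls(10, 10, 0, 8)
    perf = marker_sens_spec(calls, classes, "M1")
    assert perf.direction == "HR"
    assert perf.sensitivity_pct == 100.0 and perf.specificity_pct == 100.0


def test_marker_published_style_fractions():
    # 8 of 86 high-risk positive, 0 of 84 low-risk: 9.3% / 100.0%
    calls, classes = lr_hr_calls(8, 86, 0, 84)
    perf = marker_sens_spec(calls, classes, "M1")
    assert perf.sensitivity_pct == 9.3
    assert perf.specificity_pct == 100.0


def test_lr_marker_roles_swap():
    calls, classes = lr_hr_calls(1, 20, 15, 20)
    perf = marker_sens_spec(calls, classes, "M1")
    assert perf.direction == "LR"
    assert perf.sensitivity_pct == 75.0
    assert perf.specificity_pct == 95.0


def test_class_independent_marker_sensitivity_tracks_false_positive_rate():
    rng = np.random.default_rng(31)
    sens, fpr = [], []
    for _ in range(300):
        p = rng.uniform(0.05, 0.5)
        hr = rng.binomial(1, p, size=60)
        lr = rng.binomial(1, p, size=60)
        idx = [f"H{i}" for i in range(60)] + [f"L{i}" for i in range(60)]
        calls = pd.DataFrame({"M1": np.concatenate([hr, lr]).astype(float)}, index=idx)
        classes = pd.Series(["IPMN-CA"] * 60 + ["IPMN-LG"] * 60, index=idx)
        perf = marker_sens_spec(calls, classes, "M1", direction="HR")
        sens.append(perf.sensitivity_pct)
        fpr.append(100.0 - perf.specificity_pct)
    assert np.mean(sens) == pytest.approx(np.mean(fpr), abs=1.5)


def test_panel_disjoint_members_add_sensitivities():
    idx = [f"H{i}" for i in range(10)] + [f"L{i}" for i in range(10)]
    calls = pd.DataFrame(
        {
            "M1": [1, 1, 0, 0, 0, 0, 0, 0, 0, 0] + [0] * 10,
            "M2": [0, 0, 1, 1, 1, 0, 0, 0, 0, 0] + [0] * 10,
        },
        index=idx,
        dtype=float,
    )
    classes = pd.Series(["IPMN-HG"] * 10 + ["IPMN-LG"] * 10, index=idx)
    report = panel_evaluate(calls, classes, ["M1", "M2"], specificity_gate_pct=90.0)
    assert report.members == ["M1", "M2"]
    assert report.sensitivity_pct == 50.0  # 20% + 30%
    assert report.specificity_pct == 100.0


def test_panel_monotone_in_members():
    rng = np.random.default_rng(13)
    idx = [f"H{i}" for i in range(40)] + [f"L{i}" for i in range(40)]
    classes = pd.Series(["IPMN-CA"] * 40 + ["IPMN-LG"] * 40, index=idx)
    for _ in range(50):
        calls = pd.DataFrame(
            rng.binomial(1, 0.15, size=(80, 3)).astype(float),
            index=idx,
            columns=["M1", "M2", "M3"],
        )
        tbl = marker_table(calls, classes, ["M1", "M2", "M3"])
        tbl["direction"] = "HR"  # force all into the panel arithmetic
        small = panel_evaluate(calls, classes, ["M1", "M2"], 0.001, table=tbl.loc[["M1", "M2"]])
        big = panel_evaluate(calls, classes, ["M1", "M2", "M3"], 0.001, table=tbl)
        assert big.sensitivity_pct >= small.sensitivity_pct
        assert big.specificity_pct <= small.specificity_pct
        member_sens = [
            marker_sens_spec(calls, classes, m, direction="HR").sensitivity_pct
            for m in ["M1", "M2", "M3"]
        ]
        member_spec = [
            marker_sens_spec(calls, classes, m, direction="HR").specificity_pct
            for m in ["M1", "M2", "M3"]
        ]
        assert big.sensitivity_pct >= max(member_sens)
        assert big.specificity_pct <= min(member_spec)


def test_empty_panel_flagged():
    calls, classes = lr_hr_calls(5, 10, 5, 10)  # 50% specificity, below any gate
    report = panel_evaluate(calls, classes, ["M1"], specificity_gate_pct=90.0)
    assert report.empty and report.members == []


def test_round_half_up_matches_tabular_convention():
    assert round_half_up(9.25) == 9.3
    assert round_half_up(12.885714285714286) == 12.9
    assert round_half_up(3.44) == 3.4
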