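"""Analysis design assembly: binary features, cohort filters, class weights.

Only the binary call — binding or no binding — enters the model, not the
fold change. Antigens that are never seropositive, or whose call pattern
duplicates another antigen's, carry no extra information for selection
and are dropped. Age distributions of the classes are forced into
approximate overlap by a percentile window, and per-sample weights make
the weighted class totals equal so the smallest class is not drowned out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arrays import CLASS_ORDER, SampleRecord, cohort_frame
from .seropositivity import SeroCallMatrix


class DesignError(ValueError):
    """The analysis design cannot be assembled as configured."""


@dataclass
class CohortDesign:
    """Samples retained for modelling plus their feature matrix and weights."""

    samples: pd.DataFrame  # index sample_id; class, age, sex
    X: pd.DataFrame  # binary calls, samples x retained antigens
    age_z: pd.Series  # standardized age
    sex01: pd.Series  # 0 = F, 1 = M
    weights: pd.Series  # positive, sums to n retained
    dropped_antigens: dict[str, str] = field(default_factory=dict)
    trim_removed: dict[str, int] = field(default_factory=dict)

    @property
    def y(self) -> pd.Series:
        return self.samples["class"]

    def validate(self) -> None:
        vals = self.X.to_numpy()
        if not np.isin(vals, (0.0, 1.0)).all():
            raise DesignError("X entries must be binary")
        if (self.weights <= 0).any():
            raise DesignError("weights must be positive")
        if not np.isclose(self.weights.sum(), len(self.samples)):
            raise DesignError("weights must sum to the number of retained samples")


def filter_antigens(calls: pd.DataFrame) -> tuple[list[str], dict[str, str]]:
    """Keep antigens seropositive for >=1 sample with a unique call pattern.

    All-zero columns are dropped as ``all_negative``; within each group
    of identical columns the lexicographically first antigen name is
    kept and the rest recorded as ``duplicate_of:<kept>``. Retained
    antigens keep their original column order.
    """
    dropped: dict[str, str] = {}
    patterns: dict[bytes, list[str]] = {}
    for antigen in calls.columns:
        col = calls[antigen].to_numpy(float)
        if np.isnan(col).any():
            raise DesignError(f"antigen {antigen} has missing calls; complete the matrix first")
        if not col.any():
            dropped[antigen] = "all_negative"
            continue
        patterns.setdefault(col.astype(np.uint8).tobytes(), []).append(antigen)
    keep: set[str] = set()
    for names in patterns.values():
        first = min(names)
        keep.add(first)
        for other in names:
            if other != first:
                dropped[other] = f"duplicate_of:{first}"
    retained = [a for a in calls.columns if a in keep]
    return retained, dropped


def trim_age_overlap(
    cohort: pd.DataFrame,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
) -> tuple[list[str], dict[str, int]]:
    """Restrict to the age window shared by all classes.

    The window is [max over classes of the class ``lower_pct`` percentile,
    min over classes of the class ``upper_pct`` percentile]; samples
    outside it (exclusive) are removed. Returns retained sample ids and
    per-class removal counts. Emptying a class — or an empty window — is
    an error.
    """
    lows, highs = [], []
    for _, sub in cohort.groupby("class"):
        ages = sub["age"].to_numpy(float)
        lows.append(np.percentile(ages, lower_pct))
        highs.append(np.percentile(ages, upper_pct))
    lo, hi = max(lows), min(highs)
    if lo > hi:
        raise DesignError(
            f"age-overlap window is empty (lower {lo:.1f} > upper {hi:.1f}); "
            "the class age distributions do not overlap at these percentiles"
        )
    keep_mask = (cohort["age"] >= lo) & (cohort["age"] <= hi)
    removed = (
        cohort.loc[~keep_mask, "class"].value_counts().reindex(
            cohort["class"].unique(), fill_value=0
        )
    )
    if set(cohort["class"]) - set(cohort.loc[keep_mask, "class"]):
        empty = set(cohort["class"]) - set(cohort.loc[keep_mask, "class"])
        raise DesignError(f"age trimming removed every sample of class(es) {sorted(empty)}")
    return cohort.index[keep_mask].tolist(), {str(k): int(v) for k, v in removed.items()}


def class_weights(classes: pd.Series) -> pd.Series:
    """Per-sample weights inversely proportional to class size.

    ``w_i = n_total / (K * n_class(i))`` with K the number of classes, so
    the weighted total of every class is n_total / K and the weights sum
    to n_total.
    """
    counts = classes.value_counts()
    if (counts == 0).any():
        raise DesignError("every class must be nonempty")
    k = len(counts)
    n = len(classes)
    w = classes.map(lambda c: n / (k * counts[c]))
    return w.rename("weight").astype(float)


def build_design(
    calls: SeroCallMatrix | pd.DataFrame,
    cohort: Sequence[SampleRecord] | pd.DataFrame,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
    trim: bool = True,
) -> CohortDesign:
    """Trim ages, drop incomplete samples, filter antigens, weight classes.

    Samples with any missing antigen call (all replicates flagged) are
    excluded listwise; there is no imputation. ``trim=False`` skips the
    age-overlap window (appropriate when age is independent of
    serostatus by construction, e.g. in simulation experiments).
    """
    call_df = calls.calls if isinstance(calls, SeroCallMatrix) else calls
    cf = cohort if isinstance(cohort, pd.DataFrame) else cohort_frame(cohort)
    cf = cf.loc[call_df.index.intersection(cf.index)]
    if trim:
        retained_ids, removed = trim_age_overlap(cf, lower_pct, upper_pct)
    else:
        retained_ids, removed = cf.index.tolist(), {}
    cf = cf.loc[retained_ids]
    sub = call_df.loc[retained_ids]

    incomplete = sub.index[sub.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"{len(incomplete)} sample(s) dropped for missing antigen calls",
            stacklevel=2,
        )
        sub = sub.drop(index=incomplete)
        cf = cf.drop(index=incomplete)

    retained_antigens, dropped = filter_antigens(sub)
    X = sub[retained_antigens].astype(float)
    age = cf["age"].astype(float)
    sd = age.std(ddof=0)
    age_z = (age - age.mean()) / (sd if sd > 0 else 1.0)
    design = CohortDesign(
        samples=cf[["class", "age", "sex"]].copy(),
        X=X,
        age_z=age_z.rename("age_z"),
        sex01=(cf["sex"] == "M").astype(float).rename("sex01"),
        weights=class_weights(cf["class"]),
        dropped_antigens=dropped,
        trim_removed=removed,
    )
    design.validate()
    return design
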