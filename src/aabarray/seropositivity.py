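"""Regional background estimation and seropositivity calling.

Background is estimated per patient, because serum composition and array
production shift every slide's baseline: for each antigen spot, the
negative-control spots within a radius are averaged with inverse-distance
weights, giving a regional mean ``mu_r`` and weighted SD ``sigma_r``. A
protein is called immunoreactive when its MFI reaches at least
``mu_r + 5 * sigma_r``; the fold change is the MFI divided by that
threshold, so a call is exactly ``fold_change >= 1``. Replicate spots of
one antigen are aggregated by the median fold change.

Because both the MFI and the threshold scale linearly with any per-sample
intensity factor, calls and fold changes are invariant under rescaling a
whole sample — the operational meaning of per-patient normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .arrays import ArrayLayout, SampleRecord, SpotRole, SpotTable, cohort_frame


class NormalizationError(ValueError):
    """Background estimation is impossible for at least one spot."""


#: Offset (coordinate units) added to distances in the IDW weight so a
#: control coincident with a spot cannot dominate the average.
DISTANCE_OFFSET = 1.0


@dataclass
class RegionalBackground:
    """Per-antigen-spot background: weighted mean, SD and effective n."""

    frame: pd.DataFrame  # index spot_id; columns mu, sigma, n_eff
    radius: float
    power: float


@dataclass
class SeroCallMatrix:
    """Aggregated per-sample x per-antigen thresholds, fold changes, calls.

    Antigens with no usable replicate in a sample are NaN everywhere and
    excluded from that sample's immunoreactive-proportion denominator.
    """

    threshold: pd.DataFrame
    fold_change: pd.DataFrame
    calls: pd.DataFrame  # float 0/1 with NaN for missing

    @property
    def prop_immunoreactive(self) -> pd.Series:
        return self.calls.mean(axis=1, skipna=True).rename("prop_immunoreactive")


def estimate_background(
    table: SpotTable,
    layout: ArrayLayout,
    radius: float | None = None,
    power: float = 2.0,
    min_controls: int = 3,
) -> RegionalBackground:
    """Inverse-distance-weighted background at every antigen spot.

    For a spot at position p and unflagged negative controls at distances
    ``d_j <= radius``, the weights are ``w_j = 1 / (d_j + 1)**power``;
    ``mu_r`` and ``sigma_r`` are the weighted mean and SD of the control
    MFIs and ``n_eff = (sum w)^2 / sum w^2``. Fewer than ``min_controls``
    controls in range is a normalization error naming the spot.
    """
    if radius is None:
        radius = layout.default_radius
    lf = layout.frame
    ag = lf[lf["role"] == SpotRole.ANTIGEN.value]
    neg = lf[lf["role"] == SpotRole.NEGATIVE_CONTROL.value]
    neg_ok = neg.index[table.ok.reindex(neg.index, fill_value=False)]
    if len(neg_ok) < min_controls:
        raise NormalizationError(
            f"sample {table.sample_id}: only {len(neg_ok)} unflagged negative controls"
        )
    nx = lf.loc[neg_ok, "x"].to_numpy(float)
    ny = lf.loc[neg_ok, "y"].to_numpy(float)
    d = np.hypot(
        ag["x"].to_numpy(float)[:, None] - nx[None, :],
        ag["y"].to_numpy(float)[:, None] - ny[None, :],
    )
    in_range = d <= radius
    counts = in_range.sum(axis=1)
    if (counts < min_controls).any():
        bad = ag.index[counts < min_controls][0]
        raise NormalizationError(
            f"sample {table.sample_id}: spot {bad} has only "
            f"{int(counts.min())} negative controls within radius {radius:g}"
        )
    w = np.where(in_range, 1.0 / (d + DISTANCE_OFFSET) ** power, 0.0)
    m = table.mfi.loc[neg_ok].to_numpy(float)
    wsum = w.sum(axis=1)
    mu = w @ m / wsum
    var = (w * (m[None, :] - mu[:, None]) ** 2).sum(axis=1) / wsum
    n_eff = wsum**2 / (w**2).sum(axis=1)
    # Bessel-style correction with the effective sample size: the plain
    # weighted SD is biased low when a few nearby controls dominate, and
    # the 5-sigma rule amplifies that into spurious calls.
    corr = np.where(n_eff > 1.0, n_eff / (n_eff - 1.0), 1.0)
    sigma = np.sqrt(np.maximum(var * corr, 0.0))
    frame = pd.DataFrame(
        {"mu": mu, "sigma": sigma, "n_eff": n_eff}, index=ag.index.copy()
    )
    return RegionalBackground(frame=frame, radius=radius, power=power)


def call_spots(
    table: SpotTable,
    background: RegionalBackground,
    multiplier: float = 5.0,
) -> pd.DataFrame:
    """Per-spot threshold, fold change and call for all antigen spots.

    ``T = mu_r + multiplier * sigma_r``; ``f = MFI / T`` with T floored at
    machine epsilon (keeping the fold change finite) when ``sigma_r = 0``
    drives it to zero; the call is the inclusive comparison ``MFI >= T``.
    """
    bg = background.frame
    mfi = table.mfi.loc[bg.index].to_numpy(float)
    T = bg["mu"].to_numpy() + multiplier * bg["sigma"].to_numpy()
    call = mfi >= T
    f = mfi / np.maximum(T, np.finfo(float).eps)
    return pd.DataFrame(
        {
            "threshold": T,
            "fold_change": f,
            "call": call,
            "ok": table.ok.loc[bg.index].to_numpy(bool),
        },
        index=bg.index.copy(),
    )


def aggregate_replicates(
    spot_calls: pd.DataFrame,
    layout: ArrayLayout,
    rule: str = "median_f",
) -> pd.DataFrame:
    """Collapse replicate spots to one row per antigen.

    The antigen fold change is the median of its unflagged replicates'
    fold changes (thresholds likewise), and the antigen call is the
    inclusive ``fold_change >= 1`` on the aggregate. Antigens whose spots
    are all flagged bad come back as NaN.
    """
    if rule != "median_f":
        raise ValueError(f"unknown aggregation rule {rule!r}")
    lf = layout.frame
    df = spot_calls.join(lf["antigen"])
    usable = df[df["ok"]]
    agg = usable.groupby("antigen")[["threshold", "fold_change"]].median()
    agg = agg.reindex(layout.antigens)
    agg["call"] = (agg["fold_change"] >= 1.0).astype(float)
    agg.loc[agg["fold_change"].isna(), "call"] = np.nan
    agg.index.name = "antigen"
    return agg


def call_sample(
    table: SpotTable,
    layout: ArrayLayout,
    radius: float | None = None,
    power: float = 2.0,
    multiplier: float = 5.0,
) -> pd.DataFrame:
    """Background -> spot calls -> per-antigen aggregate for one sample."""
    bg = estimate_background(table, layout, radius=radius, power=power)
    return aggregate_replicates(call_spots(table, bg, multiplier=multiplier), layout)


def call_cohort(
    tables: Sequence[SpotTable],
    layout: ArrayLayout,
    radius: float | None = None,
    power: float = 2.0,
    multiplier: float = 5.0,
) -> SeroCallMatrix:
    """Seropositivity calling for a whole cohort of spot tables."""
    thresholds, folds, calls, ids = [], [], [], []
    all_flagged_counts: dict[str, int] = {}
    for table in tables:
        agg = call_sample(table, layout, radius=radius, power=power, multiplier=multiplier)
        ids.append(table.sample_id)
        thresholds.append(agg["threshold"])
        folds.append(agg["fold_change"])
        calls.append(agg["call"])
        for antigen in agg.index[agg["fold_change"].isna()]:
            all_flagged_counts[antigen] = all_flagged_counts.get(antigen, 0) + 1
    n = len(tables)
    chronic = [a for a, c in all_flagged_counts.items() if c > 0.5 * n]
    if chronic:
        warnings.warn(
            f"antigen(s) {chronic[:5]} unmeasurable (all spots flagged) in >50% of samples",
            stacklevel=2,
        )
    index = pd.Index(ids, name="sample_id")
    return SeroCallMatrix(
        threshold=pd.DataFrame(thresholds, index=index),
        fold_change=pd.DataFrame(folds, index=index),
        calls=pd.DataFrame(calls, index=index),
    )


# ---------------------------------------------------------------------------
# Cohort-level immunoreactivity profile
# ---------------------------------------------------------------------------


@dataclass
class ImmunoreactivityProfile:
    """Per-class spread of immunoreactive proportions plus group tests."""

    summary: pd.DataFrame  # index class; n, median, q1, q3
    kruskal_h: float
    kruskal_p: float
    dunn: pd.DataFrame  # class_a, class_b, z, p, p_adj (Bonferroni)


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons with Bonferroni adjustment.

    Uses midranks over the pooled sample with the standard tie
    correction; two-sided normal p-values multiplied by the number of
    pairs (capped at 1).
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    ranks = stats.rankdata(values)
    mean_rank: dict[str, float] = {}
    start = 0
    for g in names:
        mean_rank[g] = float(ranks[start : start + sizes[g]].mean())
        start += sizes[g]
    N = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    base_var = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    rows = []
    pairs = list(combinations(names, 2))
    for a, b in pairs:
        denom = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if denom == 0 else (mean_rank[a] - mean_rank[b]) / denom
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append({"class_a": a, "class_b": b, "z": z, "p": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = np.minimum(df["p"] * len(pairs), 1.0)
    return df


def immunoreactivity_profile(
    matrix: SeroCallMatrix,
    cohort: Sequence[SampleRecord] | pd.DataFrame,
) -> ImmunoreactivityProfile:
    """Distribution of the per-sample immunoreactive proportion by class.

    Classes with fewer than two samples are excluded (with a warning).
    Returns per-class median and quartiles, the tie-corrected
    Kruskal–Wallis H, and Dunn's pairwise z / Bonferroni-adjusted p.
    """
    cf = cohort if isinstance(cohort, pd.DataFrame) else cohort_frame(cohort)
    prop = matrix.prop_immunoreactive
    cls = cf["class"].reindex(prop.index)
    groups: dict[str, np.ndarray] = {}
    for g, sub in prop.groupby(cls):
        if len(sub) < 2:
            warnings.warn(f"class {g} has <2 samples; excluded from profile", stacklevel=2)
            continue
        groups[str(g)] = sub.to_numpy(float)
    if len(groups) < 2:
        raise ValueError("need at least two classes with >=2 samples")
    summary = pd.DataFrame(
        {
            "n": {g: len(v) for g, v in groups.items()},
            "median": {g: float(np.median(v)) for g, v in groups.items()},
            "q1": {g: float(np.percentile(v, 25)) for g, v in groups.items()},
            "q3": {g: float(np.percentile(v, 75)) for g, v in groups.items()},
        }
    )
    summary.index.name = "class"
    try:
        h, p = stats.kruskal(*groups.values())
    except ValueError:  # all values identical across the pooled sample
        h, p = 0.0, 1.0
    return ImmunoreactivityProfile(
        summary=summary,
        kruskal_h=float(h),
        kruskal_p=float(p),
        dunn=dunn_posthoc(groups),
    )
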