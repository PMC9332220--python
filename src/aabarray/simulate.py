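"""Synthetic cohorts and microarray scans with the structure the analysis assumes.

The generator emulates a serum-profiling study on a 249-antigen
full-length protein array: a six-group cohort (healthy controls, IPMN of
three grades, early-stage PDAC), replicate antigen spots spread over
blocks, negative-control spots for background estimation, a spatially
smooth background field with additive Gaussian noise, a per-serum
log-normal intensity scale, and class-conditional seropositive antigens.

Signal strength for a truly seropositive antigen is expressed in units of
the 5-SD calling threshold: its expected MFI sits ``signal_fold`` times
``5 * background_noise_sd`` above the local background, so the calling
margin is invariant to the absolute background settings.

Randomness is a single global seed; each sample draws its spot-level
noise from a substream keyed by (seed, crc32(sample_id)), so tables are
reproducible sample-by-sample and independent of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .arrays import (
    ArrayLayout,
    DiseaseClass,
    CLASS_ORDER,
    SampleRecord,
    SpotDef,
    SpotRole,
    SpotTable,
)
import pandas as pd


class ConfigError(ValueError):
    """A simulation or pipeline configuration violates its invariants."""


def _default_class_sizes() -> dict[str, int]:
    return {"Co": 54, "IPMN-LG": 91, "IPMN-HG": 66, "IPMN-CA": 30, "PDAC": 137}


def _default_age_model() -> dict[str, tuple[float, float]]:
    # Per-class mean / SD of age in years, matching the reference cohort.
    return {
        "Co": (43.7, 15.7),
        "IPMN-LG": (63.9, 10.9),
        "IPMN-HG": (63.6, 10.2),
        "IPMN-CA": (66.9, 7.9),
        "PDAC": (67.3, 10.5),
    }


def _default_sex_male_frac() -> dict[str, float]:
    return {
        "Co": 23 / 54,
        "IPMN-LG": 40 / 91,
        "IPMN-HG": 40 / 66,
        "IPMN-CA": 20 / 30,
        "PDAC": 61 / 137,
    }


def _default_baseline_reactivity() -> dict[str, float]:
    # Expected per-class fraction of antigens a serum reacts against,
    # absent any designated discriminative antigen.
    return {"Co": 0.004, "IPMN-LG": 0.008, "IPMN-HG": 0.008, "IPMN-CA": 0.018, "PDAC": 0.004}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the reference study design."""

    seed: int = 0
    class_sizes: dict[str, int] = field(default_factory=_default_class_sizes)
    n_antigens: int = 249
    replicates_per_antigen: int = 2
    neg_controls: int = 48
    pos_controls: int = 8
    n_blocks: int = 4
    spot_pitch: float = 250.0  # µm between adjacent spots
    background_mean: float = 500.0  # fluorescence units
    background_gradient_amplitude: float = 150.0
    background_noise_sd: float = 50.0
    serum_scale_sd: float = 0.3  # SD of log serum scale
    signal_fold: float = 3.0  # κ: multiples of the 5-SD threshold
    prevalence: dict[str, dict[str, float]] = field(default_factory=dict)
    age_model: dict[str, tuple[float, float]] = field(default_factory=_default_age_model)
    sex_male_frac: dict[str, float] = field(default_factory=_default_sex_male_frac)
    baseline_reactivity: dict[str, float] = field(default_factory=_default_baseline_reactivity)
    pdac_t1_frac: float = 24 / 137
    bad_spot_rate: float = 0.0

    def validate(self) -> None:
        if self.signal_fold <= 1:
            raise ConfigError("signal_fold must exceed 1 (signal above threshold)")
        if any(n <= 0 for n in self.class_sizes.values()):
            raise ConfigError("class sizes must be positive")
        if set(self.class_sizes) - set(CLASS_ORDER):
            raise ConfigError(f"unknown class in class_sizes: {set(self.class_sizes) - set(CLASS_ORDER)}")
        for d in (self.baseline_reactivity, self.sex_male_frac):
            if any(not (0.0 <= p <= 1.0) for p in d.values()):
                raise ConfigError("probabilities must lie in [0, 1]")
        for cls, per_antigen in self.prevalence.items():
            if any(not (0.0 <= p <= 1.0) for p in per_antigen.values()):
                raise ConfigError(f"prevalence for class {cls} outside [0, 1]")
        if not (0.0 <= self.bad_spot_rate < 1.0) or not (0.0 <= self.pdac_t1_frac <= 1.0):
            raise ConfigError("rates must lie in [0, 1)")
        if self.n_antigens <= 0 or self.replicates_per_antigen <= 0 or self.neg_controls <= 0:
            raise ConfigError("counts must be positive")

    @property
    def antigen_names(self) -> list[str]:
        width = max(3, len(str(self.n_antigens)))
        return [f"AG{i:0{width}d}" for i in range(1, self.n_antigens + 1)]


@dataclass
class GroundTruth:
    """What the generator injected, for parameter-recovery testing."""

    seropositive: dict[str, frozenset[str]]  # sample_id -> antigens
    discriminative: dict[str, dict[str, float]]  # class -> antigen -> prevalence

    def discriminative_antigens(self) -> set[str]:
        out: set[str] = set()
        for per_antigen in self.discriminative.values():
            out.update(per_antigen)
        return out


# ---------------------------------------------------------------------------
# Layout construction
# ---------------------------------------------------------------------------


def make_layout(config: SimulationConfig) -> ArrayLayout:
    """Lay spots out on a block grid with controls interleaved.

    Replicates of one antigen land in distinct blocks; negative controls
    are spread at even strides within each block so that every antigen
    spot sees at least three of them within the default radius (half the
    block pitch) — violating that coverage contract is a config error.
    """
    config.validate()
    if config.replicates_per_antigen > config.n_blocks:
        raise ConfigError(
            "replicates_per_antigen must not exceed n_blocks "
            "(replicates go to distinct blocks)"
        )
    n_spots = (
        config.n_antigens * config.replicates_per_antigen
        + config.neg_controls
        + config.pos_controls
    )
    per_block = -(-n_spots // config.n_blocks)  # ceil
    ncols = int(np.ceil(np.sqrt(per_block)))
    nrows = -(-per_block // ncols)
    block_cols = int(np.ceil(np.sqrt(config.n_blocks)))
    pitch = config.spot_pitch
    block_pitch = ncols * pitch  # blocks abut

    # Queue of antigen names per block; replicates land in distinct blocks.
    queues: list[list[str]] = [[] for _ in range(config.n_blocks)]
    for i, antigen in enumerate(config.antigen_names):
        for r in range(config.replicates_per_antigen):
            queues[(i + r) % config.n_blocks].append(antigen)
    base_neg = config.neg_controls // config.n_blocks
    extra_neg = config.neg_controls % config.n_blocks
    base_pos = config.pos_controls // config.n_blocks
    extra_pos = config.pos_controls % config.n_blocks

    spots: list[SpotDef] = []
    for b in range(config.n_blocks):
        n_neg_b = base_neg + (1 if b < extra_neg else 0)
        n_pos_b = base_pos + (1 if b < extra_pos else 0)
        n_slots = len(queues[b]) + n_neg_b + n_pos_b
        nrows_b = -(-n_slots // ncols)
        # Negative controls sit on an even sub-grid spanning the block
        # (endpoints included) so corner spots keep coverage too.
        neg_slots: set[int] = set()
        if n_neg_b:
            nr = max(1, int(round(np.sqrt(n_neg_b))))
            nc = -(-n_neg_b // nr)
            rr = np.unique(np.round(np.linspace(0, nrows_b - 1, nr)).astype(int))
            cc = np.unique(np.round(np.linspace(0, ncols - 1, nc)).astype(int))
            last_width = n_slots - (nrows_b - 1) * ncols
            for r in rr:
                for c in cc:
                    r_, c_ = int(r), int(c)
                    if r_ == nrows_b - 1 and c_ >= last_width:
                        r_ = max(nrows_b - 2, 0)  # lift into the last full row
                    slot = r_ * ncols + c_
                    while slot in neg_slots and slot > 0:
                        slot -= 1
                    if len(neg_slots) < n_neg_b and slot < n_slots:
                        neg_slots.add(slot)
            slot = 0  # fill from the front if the grid ran short
            while len(neg_slots) < n_neg_b:
                if slot not in neg_slots and slot < n_slots:
                    neg_slots.add(slot)
                slot += 1
        pos_slots: set[int] = set()
        if n_pos_b:
            for j in range(n_pos_b):
                slot = int(round((j + 0.5) * (n_slots - 1) / n_pos_b))
                while slot in neg_slots or slot in pos_slots:
                    slot = (slot + 1) % n_slots
                pos_slots.add(slot)
        queue_iter = iter(queues[b])
        bx = (b % block_cols) * block_pitch
        by = (b // block_cols) * (nrows * pitch)
        for slot in range(n_slots):
            row, col = divmod(slot, ncols)
            if slot in neg_slots:
                role, antigen = SpotRole.NEGATIVE_CONTROL, ""
            elif slot in pos_slots:
                role, antigen = SpotRole.POSITIVE_CONTROL, ""
            else:
                role, antigen = SpotRole.ANTIGEN, next(queue_iter)
            spots.append(
                SpotDef(
                    spot_id=f"B{b + 1}R{row + 1}C{col + 1}",
                    block=b + 1,
                    row=row + 1,
                    col=col + 1,
                    x=bx + col * pitch,
                    y=by + row * pitch,
                    role=role,
                    antigen=antigen,
                )
            )

    layout = ArrayLayout(spots=spots, n_blocks=config.n_blocks, block_pitch=block_pitch)
    _check_control_coverage(layout, layout.default_radius)
    return layout


def _check_control_coverage(layout: ArrayLayout, radius: float, minimum: int = 3) -> None:
    lf = layout.frame
    ag = lf[lf["role"] == SpotRole.ANTIGEN.value]
    neg = lf[lf["role"] == SpotRole.NEGATIVE_CONTROL.value]
    if len(neg) < minimum:
        raise ConfigError(
            f"only {len(neg)} negative controls on the array; "
            f"at least {minimum} required within radius of every antigen spot"
        )
    d = np.hypot(
        ag["x"].to_numpy()[:, None] - neg["x"].to_numpy()[None, :],
        ag["y"].to_numpy()[:, None] - neg["y"].to_numpy()[None, :],
    )
    counts = (d <= radius).sum(axis=1)
    if (counts < minimum).any():
        bad = ag.index[counts < minimum][:3].tolist()
        raise ConfigError(
            f"antigen spot(s) {bad} have fewer than {minimum} negative controls "
            f"within radius {radius:g}; increase neg_controls"
        )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _sample_rng(config: SimulationConfig, sample_id: str) -> np.random.Generator:
    key = zlib.crc32(sample_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), key]))


def simulate_cohort(config: SimulationConfig) -> tuple[list[SampleRecord], GroundTruth]:
    """Draw a cohort and each sample's true seropositive antigen set.

    Class counts match the config exactly; ages come from per-class
    normal models truncated to (15, 95) years; sex follows per-class
    male fractions. Deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    antigens = config.antigen_names
    known = set(antigens)
    for cls, per_antigen in config.prevalence.items():
        stray = set(per_antigen) - known
        if stray:
            raise ConfigError(f"prevalence names unknown antigens for {cls}: {sorted(stray)[:3]}")

    records: list[SampleRecord] = []
    seropositive: dict[str, frozenset[str]] = {}
    idx = 0
    for cls in CLASS_ORDER:
        n = config.class_sizes.get(cls, 0)
        if n == 0:
            continue
        mean, sd = config.age_model[cls]
        a, b = (15.0 - mean) / sd, (95.0 - mean) / sd
        ages = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        male = rng.random(n) < config.sex_male_frac.get(cls, 0.5)
        # Per-antigen seropositivity probability for this class.
        base = config.baseline_reactivity.get(cls, 0.0)
        overrides = config.prevalence.get(cls, {})
        p = np.full(len(antigens), base)
        for name, prob in overrides.items():
            p[antigens.index(name)] = prob
        for j in range(n):
            idx += 1
            sid = f"S{idx:04d}"
            stage = None
            if cls == DiseaseClass.PDAC.value:
                stage = "T1" if rng.random() < config.pdac_t1_frac else "T2"
            records.append(
                SampleRecord(
                    sample_id=sid,
                    disease_class=DiseaseClass(cls),
                    age=float(ages[j]),
                    sex="M" if male[j] else "F",
                    pdac_stage=stage,
                )
            )
            hits = rng.random(len(antigens)) < p
            seropositive[sid] = frozenset(np.array(antigens)[hits].tolist())

    truth = GroundTruth(
        seropositive=seropositive,
        discriminative={cls: dict(m) for cls, m in config.prevalence.items()},
    )
    return records, truth


def background_field(x: np.ndarray, y: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Smooth background B(x, y): affine plane plus one localized bump.

    The bump is deliberately narrow (Gaussian, ~10% of the slide span):
    a broad field mostly inflates the global control SD, whereas a local
    hotspot is exactly the regime where per-spot distance-weighted
    background estimation beats a global control mean.
    """
    xmax = x.max() if len(x) else 1.0
    ymax = y.max() if len(y) else 1.0
    u = x / max(xmax, 1e-12)
    v = y / max(ymax, 1e-12)
    amp = config.background_gradient_amplitude
    bump = np.exp(-(((u - 0.7) ** 2) + ((v - 0.3) ** 2)) / (2 * 0.1**2))
    return config.background_mean + amp * 0.25 * (u + v - 1.0) + amp * bump


def simulate_spot_table(
    sample: SampleRecord,
    truth: GroundTruth,
    layout: ArrayLayout,
    config: SimulationConfig,
) -> SpotTable:
    """Render one sample's scan from layout, truth and noise model.

    Background spots: ``MFI = s * (B(x, y) + eps)``; truly seropositive
    antigens add ``signal_fold * 5 * background_noise_sd`` inside the
    bracket, i.e. they sit ``signal_fold`` times the calling threshold
    above local background in expectation. Positive controls are rendered
    bright (10x the 5-SD margin). MFIs are clipped at zero.
    """
    rng = _sample_rng(config, sample.sample_id)
    lf = layout.frame
    x = lf["x"].to_numpy(float)
    y = lf["y"].to_numpy(float)
    base = background_field(x, y, config)
    eps = rng.normal(0.0, config.background_noise_sd, size=len(lf))
    s = float(np.exp(rng.normal(0.0, config.serum_scale_sd)))

    margin = 5.0 * config.background_noise_sd
    signal = np.zeros(len(lf))
    positive = truth.seropositive.get(sample.sample_id, frozenset())
    is_ag = (lf["role"] == SpotRole.ANTIGEN.value).to_numpy()
    hit = is_ag & lf["antigen"].isin(positive).to_numpy()
    signal[hit] = config.signal_fold * margin
    is_pos_ctrl = (lf["role"] == SpotRole.POSITIVE_CONTROL.value).to_numpy()
    signal[is_pos_ctrl] = 10.0 * margin

    mfi = np.clip(s * (base + signal + eps), 0.0, None)
    ok = rng.random(len(lf)) >= config.bad_spot_rate
    return SpotTable(
        sample_id=sample.sample_id,
        mfi=pd.Series(mfi, index=lf.index.copy(), name="mfi"),
        ok=pd.Series(ok, index=lf.index.copy(), name="ok"),
    )


def simulate_study(
    config: SimulationConfig,
) -> tuple[ArrayLayout, list[SampleRecord], GroundTruth, list[SpotTable]]:
    """Convenience wrapper: layout + cohort + one spot table per sample."""
    layout = make_layout(config)
    records, truth = simulate_cohort(config)
    tables = [simulate_spot_table(r, truth, layout, config) for r in records]
    return layout, records, truth, tables
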