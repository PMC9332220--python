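"""Domain types and file IO for autoantibody protein microarrays.

The array is a printed grid of protein spots organised in blocks. Each
antigen is printed in one or more replicate spots; negative controls
(printed PCR mixture without DNA template) anchor background estimation,
and positive controls (EBV VCA p18) verify the assay. One serum sample is
incubated per slide and quantified as a median fluorescence intensity
(MFI) per spot.

File formats
------------
Spot tables are tab-delimited text with a header row carrying at least
the columns ``Block, Row, Column, Name, ID, X, Y, F_Median, Flags`` — the
subset of a GenePix GPR results file that matters downstream. Extra
columns are ignored. ``Name`` holds the antigen symbol, or ``NEG`` /
``POS-VCA`` for controls; negative ``Flags`` values mark a spot as bad.
Cohort tables are CSV with columns ``sample_id,class,age,sex`` and an
optional ``pdac_stage``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NEG_NAME = "NEG"
POS_NAME = "POS-VCA"

SPOT_COLUMNS = ["Block", "Row", "Column", "Name", "ID", "X", "Y", "F_Median", "Flags"]


class ArrayFormatError(ValueError):
    """A spot file does not follow the expected tab-delimited dialect."""


class ArrayIntegrityError(ValueError):
    """A spot table is inconsistent with its array layout."""


class CohortValidationError(ValueError):
    """A cohort table contains invalid records."""


class SpotRole(str, enum.Enum):
    ANTIGEN = "antigen"
    NEGATIVE_CONTROL = "negative_control"
    POSITIVE_CONTROL = "positive_control"


class DiseaseClass(str, enum.Enum):
    """Closed set of disease classes; PDAC substage is carried separately."""

    CO = "Co"
    IPMN_LG = "IPMN-LG"
    IPMN_HG = "IPMN-HG"
    IPMN_CA = "IPMN-CA"
    PDAC = "PDAC"


#: Fixed class order used for reporting and argmax tie-breaking.
CLASS_ORDER = [c.value for c in DiseaseClass]

#: Low-risk / high-risk IPMN dichotomy used for surgical decision support.
IPMN_LR_CLASSES = [DiseaseClass.IPMN_LG.value]
IPMN_HR_CLASSES = [DiseaseClass.IPMN_HG.value, DiseaseClass.IPMN_CA.value]


@dataclass(frozen=True)
class SpotDef:
    """One printed spot: grid address, planar position (µm) and role."""

    spot_id: str
    block: int
    row: int
    col: int
    x: float
    y: float
    role: SpotRole
    antigen: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ArrayIntegrityError(f"spot {self.spot_id}: non-finite coordinates")
        if self.x < 0 or self.y < 0:
            raise ArrayIntegrityError(f"spot {self.spot_id}: negative coordinates")
        if (self.role is SpotRole.ANTIGEN) != bool(self.antigen):
            raise ArrayIntegrityError(
                f"spot {self.spot_id}: role {self.role.value!r} inconsistent with "
                f"antigen name {self.antigen!r}"
            )

    @property
    def name(self) -> str:
        """The Name column entry: antigen symbol or control token."""
        if self.role is SpotRole.ANTIGEN:
            return self.antigen
        return NEG_NAME if self.role is SpotRole.NEGATIVE_CONTROL else POS_NAME


@dataclass
class ArrayLayout:
    """Geometry and identity of every spot on the array design.

    ``block_pitch`` is the centre-to-centre distance between adjacent
    blocks in coordinate units; the default background-estimation radius
    is half of it.
    """

    spots: list[SpotDef]
    n_blocks: int
    block_pitch: float | None = None
    _frame: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        addresses = [(s.block, s.row, s.col) for s in self.spots]
        if len(set(addresses)) != len(addresses):
            raise ArrayIntegrityError("duplicate (block, row, col) address in layout")
        ids = [s.spot_id for s in self.spots]
        if len(set(ids)) != len(ids):
            raise ArrayIntegrityError("duplicate spot_id in layout")
        coords = [(s.x, s.y) for s in self.spots]
        if len(set(coords)) != len(coords):
            raise ArrayIntegrityError("duplicate spot coordinates in layout")

    @property
    def frame(self) -> pd.DataFrame:
        """Spots as a DataFrame indexed by spot_id."""
        if self._frame is None:
            self._frame = pd.DataFrame(
                {
                    "block": [s.block for s in self.spots],
                    "row": [s.row for s in self.spots],
                    "col": [s.col for s in self.spots],
                    "x": [s.x for s in self.spots],
                    "y": [s.y for s in self.spots],
                    "role": [s.role.value for s in self.spots],
                    "antigen": [s.antigen for s in self.spots],
                    "name": [s.name for s in self.spots],
                },
                index=pd.Index([s.spot_id for s in self.spots], name="spot_id"),
            )
        return self._frame

    @property
    def antigens(self) -> list[str]:
        """Distinct antigen names in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.spots:
            if s.role is SpotRole.ANTIGEN:
                seen.setdefault(s.antigen, None)
        return list(seen)

    def spot_ids(self, role: SpotRole | None = None) -> list[str]:
        return [s.spot_id for s in self.spots if role is None or s.role is role]

    @property
    def default_radius(self) -> float:
        if self.block_pitch is None:
            raise ArrayIntegrityError(
                "layout has no block_pitch; pass an explicit radius"
            )
        return self.block_pitch / 2.0


@dataclass
class SpotTable:
    """Per-sample spot measurements: MFI and ok/bad flag keyed by spot_id."""

    sample_id: str
    mfi: pd.Series  # float, index spot_id
    ok: pd.Series  # bool, index spot_id

    def validate(self, layout: ArrayLayout) -> None:
        if len(self.mfi) == 0:
            raise ArrayIntegrityError(f"sample {self.sample_id}: empty spot table")
        layout_ids = set(layout.frame.index)
        table_ids = set(self.mfi.index)
        missing = layout_ids - table_ids
        if missing:
            raise ArrayIntegrityError(
                f"sample {self.sample_id}: {len(missing)} layout spots missing "
                f"(e.g. {sorted(missing)[:3]})"
            )
        extra = table_ids - layout_ids
        if extra:
            raise ArrayIntegrityError(
                f"sample {self.sample_id}: {len(extra)} spots not in layout "
                f"(e.g. {sorted(extra)[:3]})"
            )
        if not np.isfinite(self.mfi.to_numpy()).all() or (self.mfi < 0).any():
            raise ArrayIntegrityError(
                f"sample {self.sample_id}: MFIs must be finite and non-negative"
            )


@dataclass(frozen=True)
class SampleRecord:
    """One serum donor: disease class, age in years, sex."""

    sample_id: str
    disease_class: DiseaseClass
    age: float
    sex: str  # "M" or "F"
    pdac_stage: str | None = None  # "T1"/"T2" for PDAC samples

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise CohortValidationError(
                f"sample {self.sample_id}: age must be positive, got {self.age}"
            )
        if self.sex not in ("M", "F"):
            raise CohortValidationError(
                f"sample {self.sample_id}: sex must be 'M' or 'F', got {self.sex!r}"
            )


def cohort_frame(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame indexed by sample_id."""
    return pd.DataFrame(
        {
            "class": [s.disease_class.value for s in samples],
            "age": [s.age for s in samples],
            "sex": [s.sex for s in samples],
            "pdac_stage": [s.pdac_stage for s in samples],
        },
        index=pd.Index([s.sample_id for s in samples], name="sample_id"),
    )


# ---------------------------------------------------------------------------
# Spot-table IO (GPR-subset dialect)
# ---------------------------------------------------------------------------


def read_spot_table(
    path: str | Path, layout: ArrayLayout, sample_id: str | None = None
) -> SpotTable:
    """Read one sample's tab-delimited spot file against a layout.

    The sample id defaults to the filename stem. Rows are matched to
    layout spots by (Block, Row, Column); an address absent from the
    layout, a duplicated address, or a layout spot without a row is an
    integrity error. ``Flags`` < 0 marks a spot bad.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - normalise to format error
        raise ArrayFormatError(f"{path}: cannot parse as tab-delimited text: {exc}")
    missing_cols = [c for c in SPOT_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ArrayFormatError(f"{path}: missing required column(s) {missing_cols}")

    for col in ("Block", "Row", "Column", "Flags"):
        try:
            raw[col] = pd.to_numeric(raw[col], errors="raise").astype(int)
        except (ValueError, TypeError) as exc:
            raise ArrayFormatError(f"{path}: non-numeric value in column {col}: {exc}")
    try:
        # Python's float() is exactly repr-round-trippable, unlike the
        # pandas csv float parser in its default precision mode.
        raw["F_Median"] = [float(v) for v in raw["F_Median"]]
    except (ValueError, TypeError) as exc:
        raise ArrayFormatError(f"{path}: non-numeric MFI in F_Median: {exc}")

    addr = list(zip(raw["Block"], raw["Row"], raw["Column"]))
    if len(set(addr)) != len(addr):
        raise ArrayIntegrityError(f"{path}: duplicate spot address")
    lf = layout.frame
    layout_addr = {
        (b, r, c): sid
        for sid, b, r, c in zip(lf.index, lf["block"], lf["row"], lf["col"])
    }
    unknown = [a for a in addr if a not in layout_addr]
    if unknown:
        raise ArrayIntegrityError(
            f"{path}: {len(unknown)} row(s) with addresses absent from layout "
            f"(e.g. {unknown[:3]})"
        )
    spot_ids = [layout_addr[a] for a in addr]
    mfi = pd.Series(raw["F_Median"].to_numpy(), index=spot_ids, name="mfi")
    ok = pd.Series(raw["Flags"].to_numpy() >= 0, index=spot_ids, name="ok")
    table = SpotTable(sample_id=sample_id or path.stem, mfi=mfi, ok=ok)
    table.validate(layout)
    return table


def write_spot_table(table: SpotTable, layout: ArrayLayout, path: str | Path) -> Path:
    """Write a spot table in the GPR-subset dialect; inverse of read_spot_table.

    MFIs are serialised via ``repr`` so the round trip is bit-exact.
    """
    table.validate(layout)
    path = Path(path)
    lf = layout.frame
    rows = []
    for sid in lf.index:
        rows.append(
            {
                "Block": lf.at[sid, "block"],
                "Row": lf.at[sid, "row"],
                "Column": lf.at[sid, "col"],
                "Name": lf.at[sid, "name"],
                "ID": sid,
                "X": repr(float(lf.at[sid, "x"])),
                "Y": repr(float(lf.at[sid, "y"])),
                "F_Median": repr(float(table.mfi.loc[sid])),
                "Flags": 0 if bool(table.ok.loc[sid]) else -100,
            }
        )
    pd.DataFrame(rows, columns=SPOT_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Cohort IO
# ---------------------------------------------------------------------------

_VALID_CLASSES = {c.value for c in DiseaseClass}


def read_cohort(path: str | Path) -> list[SampleRecord]:
    """Read a cohort CSV, validating disease classes, ages and sex codes."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = ["sample_id", "class", "age", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing column(s) {missing}")

    problems: list[str] = []
    records: list[SampleRecord] = []
    for i, row in df.iterrows():
        label = row["class"]
        if label not in _VALID_CLASSES:
            problems.append(f"row {i}: unknown class {label!r}")
            continue
        try:
            age = float(row["age"])
        except (TypeError, ValueError):
            problems.append(f"row {i}: non-numeric age {row['age']!r}")
            continue
        stage = row.get("pdac_stage")
        if isinstance(stage, float) and math.isnan(stage):
            stage = None
        if stage is not None and not isinstance(stage, str):
            stage = str(stage)
        if stage == "" or (isinstance(stage, str) and stage.lower() == "nan"):
            stage = None
        try:
            records.append(
                SampleRecord(
                    sample_id=str(row["sample_id"]),
                    disease_class=DiseaseClass(label),
                    age=age,
                    sex=str(row["sex"]),
                    pdac_stage=stage,
                )
            )
        except CohortValidationError as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise CohortValidationError(f"{path}: invalid cohort rows:\n" + "\n".join(problems))
    return records


def write_cohort(samples: Sequence[SampleRecord], path: str | Path) -> Path:
    path = Path(path)
    df = cohort_frame(samples).reset_index()
    df.to_csv(path, index=False)
    return path
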