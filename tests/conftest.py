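import numpy as np
import pandas as pd
import pytest

from aabarray import SimulationConfig, make_layout, simulate_cohort, simulate_spot_table
from aabarray.arrays import ArrayLayout, SpotDef, SpotRole, SpotTable


def tiny_sim_config(**overrides) -> SimulationConfig:
    """A small but structurally complete study design for fast tests."""
    base = dict(
        seed=11,
        class_sizes={"Co": 6, "IPMN-LG": 8, "IPMN-HG": 7, "IPMN-CA": 5, "PDAC": 9},
        n_antigens=24,
        neg_controls=32,
        pos_controls=4,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_config():
    return tiny_sim_config()


@pytest.fixture(scope="session")
def tiny_layout(tiny_config):
    return make_layout(tiny_config)


@pytest.fixture(scope="session")
def tiny_study(tiny_config, tiny_layout):
    records, truth = simulate_cohort(tiny_config)
    tables = [simulate_spot_table(r, truth, tiny_layout, tiny_config) for r in records]
    return records, truth, tables


def manual_layout(antigen_spots, neg_spots, pos_spots=(), n_blocks=1, block_pitch=None):
    """Build a layout from explicit (name, x, y) antigen and (x, y) control lists."""
    spots = []
    for i, (name, x, y) in enumerate(antigen_spots):
        spots.append(
            SpotDef(
                spot_id=f"A{i}", block=1, row=1, col=i + 1, x=x, y=y,
                role=SpotRole.ANTIGEN, antigen=name,
            )
        )
    for j, (x, y) in enumerate(neg_spots):
        spots.append(
            SpotDef(
                spot_id=f"N{j}", block=1, row=2, col=j + 1, x=x, y=y,
                role=SpotRole.NEGATIVE_CONTROL,
            )
        )
    for k, (x, y) in enumerate(pos_spots):
        spots.append(
            SpotDef(
                spot_id=f"P{k}", block=1, row=3, col=k + 1, x=x, y=y,
                role=SpotRole.POSITIVE_CONTROL,
            )
        )
    return ArrayLayout(spots=spots, n_blocks=n_blocks, block_pitch=block_pitch)


def table_for(layout, values, sample_id="S1", bad=()):
    """SpotTable from a spot_id -> MFI mapping; unlisted controls get 0."""
    idx = layout.frame.index
    mfi = pd.Series([float(values.get(sid, 0.0)) for sid in idx], index=idx)
    ok = pd.Series([sid not in set(bad) for sid in idx], index=idx)
    return SpotTable(sample_id=sample_id, mfi=mfi, ok=ok)
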