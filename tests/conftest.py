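"""Shared fixtures: toy profiles and a small error-free simulated run."""

import numpy as np
import pandas as pd
import pytest

from riboratio import (
    SimScenario,
    build_paired_profile,
    run_scenario,
)
from riboratio.units import CountTable


def make_count_table(data: dict, method: str = "ZOTU") -> CountTable:
    """CountTable from {(sample, pool): {unit: count}} nested dicts."""
    frame = pd.DataFrame(data).fillna(0).astype(int)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["sample", "pool"])
    totals = frame.sum(axis=0)
    return CountTable(frame, totals * 0, totals, method)


@pytest.fixture
def toy_table() -> CountTable:
    """Three units: abundant shared, rare shared, rRNA-only phantom."""
    return make_count_table({
        ("S1", "rDNA"): {"U1": 90, "U2": 10, "U3": 0},
        ("S1", "rRNA"): {"U1": 50, "U2": 25, "U3": 25},
    })


@pytest.fixture
def toy_profile(toy_table):
    return build_paired_profile(toy_table, "S1")


@pytest.fixture(scope="session")
def clean_run():
    """Error-free simulated community + ZOTU pipeline result (30 taxa)."""
    scenario = SimScenario(
        n_taxa=30, depth_rdna=20_000, depth_rrna=20_000,
        sub_error_rate=0.0, rt_error_rate=0.0, seed=7,
    )
    community, result = run_scenario(scenario, method="ZOTU")
    return scenario, community, result


def unit_truth_map(community, units):
    """unit_id -> taxon_id via exact representative match (None if spurious)."""
    seq_to_taxon = dict(zip(community.references, community.taxon_ids))
    return {u.unit_id: seq_to_taxon.get(u.representative) for u in units}
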