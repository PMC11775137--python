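"""Shared fixtures: small synthetic datasets and toy tables."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import sedarange as sr

# the acceptance script's brute-force oracles double as test oracles
sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "scripts"))


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at the reference conditions (seed 1)."""
    return sr.generate_dataset(sr.SimParams(rng_seed=1))


@pytest.fixture(scope="session")
def default_run(default_dataset):
    """Rarefied resample set and slice summaries at full defaults."""
    table, lakes, traits, truth = default_dataset
    cfg = sr.RunConfig(rng_seed=1)
    rs = sr.rarefy_dataset(table, cfg)
    summaries = sr.slice_range_summaries(rs, lakes, cfg)
    return cfg, rs, summaries


@pytest.fixture(scope="session")
def small_run(default_dataset):
    """Same dataset rarefied with 20 iterations, for cheaper unit tests."""
    table, lakes, traits, truth = default_dataset
    cfg = sr.RunConfig(rng_seed=1, n_iterations=20)
    rs = sr.rarefy_dataset(table, cfg)
    summaries = sr.slice_range_summaries(rs, lakes, cfg)
    return cfg, rs, summaries


@pytest.fixture()
def toy_registry():
    return sr.LakeRegistry(pd.DataFrame({
        "lake_id": [f"L{i}" for i in range(1, 8)],
        "lon": [150.0, 152.0, 155.0, 158.0, 160.0, 163.0, 165.0],
        "lat": [65.0, 67.5, 64.0, 68.0, 66.0, 63.5, 67.0],
    }))


def make_occurrence(rows, registry=None, slice_width=1000):
    """Rows of (lake, slice, taxon, family, reads) → validated table."""
    df = pd.DataFrame(rows, columns=["lake_id", "slice_index", "taxon_id",
                                     "family", "reads"])
    return sr.io.validate_occurrences(df, registry, slice_width)


@pytest.fixture()
def fig_toy_table():
    """Four taxa A–D spread over lakes in time-slice 1 (worked example)."""
    rows = [
        ("L1", 1, "A", "Poaceae", 10),
        ("L2", 1, "A", "Poaceae", 5),
        ("L3", 1, "B", "Cyperaceae", 7),
        ("L4", 1, "C", "Salicaceae", 3),
        ("L5", 1, "C", "Salicaceae", 2),
        ("L6", 1, "C", "Salicaceae", 9),
        ("L7", 1, "D", "Betulaceae", 1),
    ]
    return make_occurrence(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
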