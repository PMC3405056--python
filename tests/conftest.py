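"""Shared fixtures: small models/trees and the session-wide benchmark run."""

from __future__ import annotations

import numpy as np
import pytest

from caviarid.market_fixture import (FIXTURE_SURVEY_CONFIG,
                                     benchmark_reference_db,
                                     encode_benchmark_survey)
from caviarid.phylo import PhyloTree
from caviarid.simulate import simulate_alignment
from caviarid.substitution import GTRModel, jukes_cantor
from caviarid.workflow import run_survey


@pytest.fixture(scope="session")
def jc_model() -> GTRModel:
    return jukes_cantor()


@pytest.fixture(scope="session")
def gtr_model() -> GTRModel:
    return GTRModel(freqs=(0.3, 0.2, 0.2, 0.3), rates=(1, 4, 1, 1, 4, 1),
                    alpha=0.5)


@pytest.fixture(scope="session")
def quartet_tree() -> PhyloTree:
    return PhyloTree.from_newick(
        "((A:0.10,B:0.20):0.05,(C:0.10,D:0.30):0.07);")


@pytest.fixture(scope="session")
def quartet_alignment(quartet_tree, gtr_model):
    return simulate_alignment(quartet_tree, gtr_model, 200, 42)


@pytest.fixture(scope="session")
def ref_db():
    """The synthetic reference panel behind the benchmark survey."""
    return benchmark_reference_db()


@pytest.fixture(scope="session")
def benchmark(ref_db):
    """(lots, expected) of the encoded 92-tin market survey."""
    return encode_benchmark_survey(ref_db)


@pytest.fixture(scope="session")
def benchmark_results(ref_db, benchmark):
    lots, _ = benchmark
    return run_survey(lots, ref_db, FIXTURE_SURVEY_CONFIG)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231114)
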