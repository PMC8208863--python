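"""Shared fixtures: synthetic bundles, pipeline runs and toy graphs."""

import pytest

from cernet.cli import pipeline_paths, run_pipeline, write_simulation
from cernet.network import CompetingTriplet, build_graph
from cernet.synthetic import SimulationConfig, simulate_expression


def tiny_config(**overrides) -> SimulationConfig:
    """A fast, fully structured simulation for CLI and smoke tests."""
    base = dict(n_case=6, n_control=6, n_lnc=12, n_mi=6, n_m=20, n_triplets=4,
                n_terms=8, n_enriched=2, n_decoy_interactions=10, seed=11)
    base.update(overrides)
    return SimulationConfig(**base)


def toy_triplets():
    """One shared miRNA serving two lncRNAs and two mRNAs (star-ish toy)."""
    return [
        CompetingTriplet("L1", "mu1", "M1", 0.995, -0.9, -0.9),
        CompetingTriplet("L1", "mu1", "M2", 0.995, -0.9, -0.9),
        CompetingTriplet("L2", "mu1", "M1", 0.995, -0.9, -0.9),
        CompetingTriplet("L2", "mu2", "M3", 0.995, -0.9, -0.9),
    ]


@pytest.fixture(scope="session")
def default_sim():
    """Default-regime expression matrix + ground truth (seed 1)."""
    cfg = SimulationConfig(seed=1)
    matrix, truth = simulate_expression(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def pipeline_once(tmp_path_factory):
    """One full synthetic run at the default regime (seed 1)."""
    root = tmp_path_factory.mktemp("pipeline_a")
    sim = SimulationConfig(seed=1)
    write_simulation(sim, root / "in")
    cfg = pipeline_paths(root / "in", root / "out", seed=1)
    summary = run_pipeline(cfg)
    return sim, root, summary


@pytest.fixture(scope="session")
def pipeline_twice(tmp_path_factory, pipeline_once):
    """A byte-level replicate of the same run for determinism checks."""
    root = tmp_path_factory.mktemp("pipeline_b")
    sim = SimulationConfig(seed=1)
    write_simulation(sim, root / "in")
    cfg = pipeline_paths(root / "in", root / "out", seed=1)
    summary = run_pipeline(cfg)
    return sim, root, summary


@pytest.fixture()
def toy_graph():
    return build_graph(toy_triplets(),
                       fold_changes={"L1": 2.5, "mu1": -2.1, "M1": 3.0})
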