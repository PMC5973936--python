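"""Shared simulation fixtures.

Everything is generated programmatically at test time; the heavier
simulated experiments are session-scoped so detection runs once.
"""

import dataclasses

import pandas as pd
import pytest

from circdynamics.detect import GenomeIndex, detect_experiment
from circdynamics.quantify import quantify_experiment
from circdynamics.simulate import SimConfig, run_simulation


@pytest.fixture(scope="session")
def small_sim():
    """Compact experiment: 6 genes, 8 exonic + 2 planted circles."""
    cfg = SimConfig(seed=42, n_genes=6, n_circ=8, depth_per_sample=4000,
                    n_up=2, n_down=2, contig_length=20_000)
    bundle, truth, reads = run_simulation(cfg)
    return cfg, bundle, truth, reads


@pytest.fixture(scope="session")
def small_detected(small_sim):
    cfg, bundle, truth, reads = small_sim
    index = GenomeIndex(bundle)
    det = detect_experiment(reads, bundle, truth.samples, index=index)
    return cfg, bundle, truth, reads, index, det


@pytest.fixture(scope="session")
def small_expression(small_detected):
    cfg, bundle, truth, reads, index, det = small_detected
    expr = quantify_experiment(det, bundle, index)
    samples = pd.DataFrame([dataclasses.asdict(s) for s in truth.samples])
    return expr, samples


@pytest.fixture(scope="session")
def default_sim_detected():
    """The default study-scale simulation: 100 kb, 20 genes, 30 circles,
    10^4 pairs in each of the six samples."""
    cfg = SimConfig(seed=42)
    bundle, truth, reads = run_simulation(cfg)
    index = GenomeIndex(bundle)
    det = detect_experiment(reads, bundle, truth.samples, index=index)
    return cfg, bundle, truth, reads, index, det


@pytest.fixture(scope="session")
def default_expression(default_sim_detected):
    cfg, bundle, truth, reads, index, det = default_sim_detected
    expr = quantify_experiment(det, bundle, index)
    samples = pd.DataFrame([dataclasses.asdict(s) for s in truth.samples])
    return expr, samples


@pytest.fixture(scope="session")
def enrichment_sim_detected():
    """Deep simulation for the RNase R survival model: high junction
    coverage, no planted regulation, error-free reads."""
    cfg = SimConfig(seed=9, n_genes=10, n_circ=10, depth_per_sample=40_000,
                    n_up=0, n_down=0, n_antisense_circ=0,
                    n_intergenic_circ=0, error_rate=0.0,
                    circ_fraction_model="constant", circ_fraction=0.5,
                    circ_exon_count_dist={1: 1.0},
                    linear_mu=6.4, linear_sigma=0.3,
                    contig_length=50_000)
    bundle, truth, reads = run_simulation(cfg)
    index = GenomeIndex(bundle)
    det = detect_experiment(reads, bundle, truth.samples, index=index)
    return cfg, bundle, truth, reads, index, det
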