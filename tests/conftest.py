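"""Shared fixtures: small simulated data sets built once per session."""

import pytest

from plastcomp.core import AnalysisConfig
from plastcomp.simulate import SimParams, evolve, generate_ancestor

SMALL = dict(genome_length=40_000, n_cds=40, n_trna=9, ir_length=2_000)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_sim():
    """A 40 kb five-taxon simulation with indels, seed 11."""
    params = SimParams(seed=11, **SMALL)
    ancestor, annotation = generate_ancestor(params)
    leaves, truth = evolve(ancestor, annotation, params)
    return params, ancestor, annotation, leaves, truth


@pytest.fixture(scope="session")
def default_sim():
    """A full-scale (130 kb) five-taxon simulation, seed 1."""
    params = SimParams(seed=1)
    ancestor, annotation = generate_ancestor(params)
    leaves, truth = evolve(ancestor, annotation, params)
    return params, ancestor, annotation, leaves, truth
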