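"""Shared fixtures: small matrix builders and module-scoped simulations."""

from __future__ import annotations

import numpy as np
import pytest

import chromphylo as cp
from chromphylo import hematopoiesis as hp
from chromphylo.data import AccessibilityMatrix, CellType, GenomicInterval


def make_matrix(values, cells) -> AccessibilityMatrix:
    """Build a matrix from a (n_sites, n_cells) 0/1 array and cell names."""
    values = np.asarray(values, dtype=np.uint8)
    if values.ndim == 1:
        values = values[None, :]
    sites = [GenomicInterval("chrT", i * 10, i * 10 + 5, f"chrT:{i * 10}-{i * 10 + 5}")
             for i in range(values.shape[0])]
    return AccessibilityMatrix(sites, [CellType(c) for c in cells], values)


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def mixed_sim():
    """Default-mix simulation on the standard hierarchy (shared, read-only)."""
    cfg = cp.SimulationConfig(n_sites=1500, seed=42)
    matrix, truth = cp.simulate_matrix(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def updown_sim():
    """Homoplasy-free UP/DOWN-only simulation on the fully resolved tree."""
    cfg = cp.SimulationConfig(
        tree=hp.RESOLVED_DIFFERENTIATION_NEWICK,
        unobserved_nodes=hp.UNOBSERVED_RESOLVED,
        n_sites=3000,
        class_mix={"UP": 0.5, "DOWN": 0.5},
        seed=7,
    )
    matrix, truth = cp.simulate_matrix(cfg)
    return cfg, matrix, truth
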