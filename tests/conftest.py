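"""Shared fixtures: synthetic backbones and abstract-graph networks."""

from __future__ import annotations

import numpy as np
import pytest

from pcnkit.network import ContactNetwork
from pcnkit.structure import Residue, Structure
from pcnkit import synth


def network_from_edges(n: int, edges) -> ContactNetwork:
    """Wrap an abstract undirected graph (0-based edges) as a ContactNetwork
    so the metric and community code can run on arbitrary topologies."""
    edges = list(edges)
    a = np.zeros((n, n), dtype=np.int8)
    for u, v in edges:
        a[u, v] = a[v, u] = 1
    d = np.where(a == 1, 1.0, 100.0)
    np.fill_diagonal(d, 0.0)
    residues = tuple(
        Residue(index=k + 1, author_number=k + 1, name="ALA", ca=[0.0, 0.0, 100.0 * k])
        for k in range(n)
    )
    st = Structure(id=f"graph{n}", residues=residues)
    contacts = frozenset((min(u, v) + 1, max(u, v) + 1) for u, v in edges)
    return ContactNetwork(structure=st, cutoff=7.0, adjacency=a, distances=d,
                          contacts=contacts)


def random_gnp_edges(n: int, p: float, rng: np.random.Generator):
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((i, j))
    return edges


@pytest.fixture
def helix10() -> Structure:
    return synth.make_ideal_helix(10)


@pytest.fixture
def two_helix_far() -> Structure:
    """Two 16-residue helices 30 A apart: no inter-helix contacts."""
    return synth.two_helix_fixture(16, 16, separation=30.0)


@pytest.fixture
def two_helix_near() -> Structure:
    """Two 16-residue helices 11 A apart: close enough that single-residue
    moves can inject inter-helix contacts without side effects."""
    return synth.two_helix_fixture(16, 16, separation=11.0)


@pytest.fixture
def mixed_chain() -> Structure:
    """Helix-coil-strand-coil-helix chain, the standard compact fixture."""
    spec = synth.SyntheticSpec(
        n_residues=40,
        segments=(("helix", 12), ("coil", 6), ("strand", 8), ("coil", 4),
                  ("helix", 10)),
        seed=7,
        noise_sd=0.15,
    )
    return synth.make_structure(spec)
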