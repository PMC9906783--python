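"""Shared fixtures: synthetic datasets, stub ligands and random graphs."""

from __future__ import annotations

import numpy as np
import pytest

from irphos.core import AtomNode, LigandLibrary, LigandRecord, MolecularGraph
from irphos.synthetic import SyntheticConfig, gen_ligand_library, make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """12 x 6 combinatorial synthetic dataset with default trends."""
    return make_dataset(SyntheticConfig(n_cn=12, n_nn=6), seed=42)


@pytest.fixture(scope="session")
def hls_library():
    """A 60 CN + 23 NN library mirroring the experimental set's shape."""
    return gen_ligand_library(60, 23, seed=11)


@pytest.fixture(scope="session")
def toy_complex(small_dataset):
    return small_dataset.complexes[0]


# ---------------------------------------------------------------------------
# cheap hand-built ligands (no RDKit) for combinatorial / counting tests


def make_stub_cn(ligand_id: str, n_extra_h: int = 0) -> LigandRecord:
    """Minimal protonated CN ligand: C(-H,-H)-N(-H) plus optional extra Hs."""
    atoms = [AtomNode("C"), AtomNode("N"), AtomNode("H"), AtomNode("H"), AtomNode("H")]
    bonds = [(0, 1), (0, 2), (0, 3), (1, 4)]
    for k in range(n_extra_h):
        atoms.append(AtomNode("H"))
        bonds.append((1, 5 + k))
    return LigandRecord(
        ligand_id=ligand_id,
        role="CN",
        graph=MolecularGraph(atoms, bonds),
        coordinating_atoms=(0, 1),
    )


def make_stub_nn(ligand_id: str, n_extra_h: int = 0) -> LigandRecord:
    """Minimal NN ligand: H-N-N-H plus optional extra Hs."""
    atoms = [AtomNode("N"), AtomNode("N"), AtomNode("H"), AtomNode("H")]
    bonds = [(0, 1), (0, 2), (1, 3)]
    for k in range(n_extra_h):
        atoms.append(AtomNode("H"))
        bonds.append((1, 4 + k))
    return LigandRecord(
        ligand_id=ligand_id,
        role="NN",
        graph=MolecularGraph(atoms, bonds),
        coordinating_atoms=(0, 1),
    )


def stub_library(n_cn: int, n_nn: int, prefix: str = "") -> LigandLibrary:
    return LigandLibrary(
        cn_ligands=[make_stub_cn(f"{prefix}CN{i+1}") for i in range(n_cn)],
        nn_ligands=[make_stub_nn(f"{prefix}NN{i+1}") for i in range(n_nn)],
    )


def random_graph(rng: np.random.Generator, max_atoms: int = 8) -> MolecularGraph:
    """Random connected graph (spanning tree + extra edges) over common elements."""
    n = int(rng.integers(2, max_atoms + 1))
    elements = rng.choice(["H", "C", "N", "O", "F", "S", "Cl"], size=n)
    bonds = {(int(rng.integers(0, i)), i) for i in range(1, n)}
    for _ in range(int(rng.integers(0, n))):
        i, j = int(rng.integers(0, n)), int(rng.integers(0, n))
        if i != j:
            bonds.add((min(i, j), max(i, j)))
    coords = rng.normal(size=(n, 3)) * 2.0
    return MolecularGraph([AtomNode(e) for e in elements], bonds, coordinates=coords)
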