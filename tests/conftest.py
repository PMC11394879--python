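"""Shared fixtures: small deterministic structures and networks."""

import numpy as np
import pytest

import mcdpa as m
from mcdpa.structure_io import Atom, MolecularStructure, NodeSet


@pytest.fixture(scope="session")
def pocket_cage():
    return m.make_pocket_cage(m.FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def ligand_cage():
    return m.make_ligand_in_pocket(m.FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def two_chain():
    return m.make_two_chain_complex(
        m.FixtureSpec(kind="two_chain_complex", n_nodes=150, seed=0),
        ligand_site="interface")


def random_connected_nodes(n_nodes: int, rng: np.random.Generator,
                           box: float = 8.0) -> NodeSet:
    """Random point cloud guaranteed connected at the default cutoff."""
    coords = rng.uniform(-box / 2, box / 2, size=(n_nodes, 3))
    return NodeSet(labels=[f"A:GLY{i+1}" for i in range(n_nodes)],
                   coords=coords, source_chain=["A"] * n_nodes,
                   scheme="calpha", res_seq=list(range(1, n_nodes + 1)))


def structure_from_coords(coords, chain_id="A", start=1) -> MolecularStructure:
    atoms = [
        Atom(name="CA", element="C", chain_id=chain_id, res_name="GLY",
             res_seq=start + i, icode="", coords=np.asarray(c, float),
             record_kind="polymer")
        for i, c in enumerate(coords)
    ]
    return MolecularStructure(atoms=atoms, name="test")
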