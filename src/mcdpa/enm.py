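"""Anisotropic elastic network models and their Hessian machinery.

Nodes within a contact cutoff are joined by Hookean springs of force constant
gamma; a two-protein complex adds cross-interface springs of force constant
gamma_AB, the adjustable coupling V_AB = 1/2 sum gamma_AB (r_ij - r_ij0)^2
between interface node pairs.  All springs are built at their equilibrium
length, so the input conformation is the energy minimum and the harmonic
conformational distribution is a zero-mean Gaussian on internal coordinates
with precision matrix equal to the Hessian restricted to non-rigid motions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure_io import NodeSet

DEFAULT_CUTOFF = 13.0  # Angstrom, CA-level contact distance
DEFAULT_GAMMA = 1.0

#: relative magnitude below which an eigenvalue counts as a rigid mode
RIGID_TOL_REL = 1e-8


class ConnectivityError(ValueError):
    """Network is not a single connected component."""


class ModelError(RuntimeError):
    """Hessian does not have the expected rigid-mode structure."""


@dataclass
class ElasticNetwork:
    nodes: NodeSet
    spring_index: np.ndarray      # (S, 2) int, i < j
    rest_lengths: np.ndarray      # (S,)
    force_constants: np.ndarray   # (S,)
    gamma: float = DEFAULT_GAMMA
    gamma_AB: float | None = None
    cutoff: float = DEFAULT_CUTOFF

    @property
    def n_nodes(self) -> int:
        return self.nodes.n_nodes

    @property
    def n_springs(self) -> int:
        return len(self.spring_index)


@dataclass
class HessianBundle:
    """Dense Hessian with its rigid-mode-free eigensystem."""

    hessian: np.ndarray           # (3N, 3N)
    nonrigid_basis: np.ndarray    # (3N, 3N-6), orthonormal columns
    eigenvalues: np.ndarray       # (3N-6,), ascending, all > 0
    log_pseudodet: float
    coords: np.ndarray = field(default=None, repr=False)  # node coords, for rigid checks

    @property
    def n_dof(self) -> int:
        return self.hessian.shape[0]


def _check_connected(n_nodes: int, spring_index: np.ndarray) -> None:
    if len(spring_index) == 0:
        raise ConnectivityError("network has no springs")
    data = np.ones(len(spring_index))
    adj = coo_matrix((data, (spring_index[:, 0], spring_index[:, 1])),
                     shape=(n_nodes, n_nodes))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp != 1:
        sizes = np.bincount(labels)
        raise ConnectivityError(
            f"network splits into {n_comp} components (sizes {sizes.tolist()})"
        )


def _pairs_within(coords: np.ndarray, cutoff: float) -> np.ndarray:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def build_network(
    nodes: NodeSet,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
    chain_groups: list[set[str]] | None = None,
    require_connected: bool = True,
) -> ElasticNetwork:
    """Connect all node pairs within ``cutoff`` by springs of constant ``gamma``.

    With ``chain_groups`` given, springs are restricted to node pairs within
    the same group (the intra-protein networks of a complex, before
    :func:`couple_chains` adds the interface term).
    """
    if nodes.n_nodes < 2:
        raise ValueError("need at least 2 nodes to build a network")
    pairs = _pairs_within(nodes.coords, cutoff)

    if chain_groups is not None:
        group_of = {}
        for gi, group in enumerate(chain_groups):
            for c in group:
                group_of[c] = gi
        sc = nodes.source_chain
        keep = np.array(
            [group_of.get(sc[i]) == group_of.get(sc[j]) and group_of.get(sc[i]) is not None
             for i, j in pairs],
            dtype=bool,
        ) if len(pairs) else np.zeros(0, bool)
        pairs = pairs[keep]

    rest = np.linalg.norm(nodes.coords[pairs[:, 0]] - nodes.coords[pairs[:, 1]], axis=1) \
        if len(pairs) else np.zeros(0)
    fc = np.full(len(pairs), float(gamma))
    if require_connected and chain_groups is None:
        _check_connected(nodes.n_nodes, pairs)
    return ElasticNetwork(nodes=nodes, spring_index=pairs, rest_lengths=rest,
                          force_constants=fc, gamma=gamma, cutoff=cutoff)


def couple_chains(
    network: ElasticNetwork,
    chains_A: set[str],
    chains_B: set[str],
    gamma_AB: float | None = None,
    cutoff_AB: float | None = None,
) -> ElasticNetwork:
    """Add cross-interface springs of constant ``gamma_AB`` between chain groups.

    With ``gamma_AB`` equal to the intra-protein gamma the coupled network is
    identical to building one network over the union of chains.  A zero
    ``gamma_AB`` emits no cross springs at all (the decoupled limit: the
    Hessian is block-diagonal over the monomers).
    """
    if gamma_AB is None:
        gamma_AB = network.gamma
    if cutoff_AB is None:
        cutoff_AB = network.cutoff

    sc = network.nodes.source_chain
    known = chains_A | chains_B
    if not set(sc) <= known:
        raise ValueError(
            f"nodes carry chains {sorted(set(sc) - known)} outside chains_A/chains_B"
        )

    if gamma_AB == 0.0:
        return ElasticNetwork(
            nodes=network.nodes, spring_index=network.spring_index.copy(),
            rest_lengths=network.rest_lengths.copy(),
            force_constants=network.force_constants.copy(),
            gamma=network.gamma, gamma_AB=0.0, cutoff=network.cutoff)

    pairs = _pairs_within(network.nodes.coords, cutoff_AB)
    in_A = np.array([c in chains_A for c in sc])
    cross = pairs[in_A[pairs[:, 0]] != in_A[pairs[:, 1]]] if len(pairs) else pairs

    if len(cross) == 0:
        import logging
        logging.getLogger(__name__).warning(
            "couple_chains: no cross-interface contacts within %.1f A "
            "(complex is dynamically uncoupled)", cutoff_AB)

    existing = {tuple(p) for p in network.spring_index}
    new_pairs = [tuple(p) for p in cross if tuple(p) not in existing]
    all_idx = np.array(sorted(existing | set(new_pairs)), dtype=int).reshape(-1, 2)

    coords = network.nodes.coords
    rest = np.linalg.norm(coords[all_idx[:, 0]] - coords[all_idx[:, 1]], axis=1)
    fc_map = {tuple(p): fc for p, fc in zip(map(tuple, network.spring_index),
                                            network.force_constants)}
    fc = np.array([fc_map.get(tuple(p), gamma_AB) for p in all_idx])
    return ElasticNetwork(nodes=network.nodes, spring_index=all_idx, rest_lengths=rest,
                          force_constants=fc, gamma=network.gamma, gamma_AB=gamma_AB,
                          cutoff=network.cutoff)


# ---------------------------------------------------------------------------
# Hessian


def hessian_matrix(network: ElasticNetwork) -> np.ndarray:
    """Dense 3N x 3N second-derivative matrix of the spring energy.

    Each spring (i, j) contributes -gamma d d^T on the (i, j) off-diagonal
    block (d the unit bond vector) and +gamma d d^T on both diagonal blocks,
    so every 3x3 diagonal block equals minus the sum of its row's
    off-diagonal blocks (translational sum rule).
    """
    n = network.n_nodes
    H = np.zeros((3 * n, 3 * n))
    coords = network.nodes.coords
    for (i, j), fc in zip(network.spring_index, network.force_constants):
        d = coords[j] - coords[i]
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ModelError(f"coincident nodes {i}, {j}")
        d = d / norm
        block = fc * np.outer(d, d)
        H[3*i:3*i+3, 3*j:3*j+3] -= block
        H[3*j:3*j+3, 3*i:3*i+3] -= block
        H[3*i:3*i+3, 3*i:3*i+3] += block
        H[3*j:3*j+3, 3*j:3*j+3] += block
    return H


def rigid_mode_generators(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N x 6) of rigid translations/rotations about the centroid."""
    n = len(coords)
    c = coords - coords.mean(axis=0)
    gens = np.zeros((3 * n, 6))
    for k in range(3):
        gens[k::3, k] = 1.0
    axes = np.eye(3)
    for k in range(3):
        cross = np.cross(np.broadcast_to(axes[k], (n, 3)), c)
        gens[:, 3 + k] = cross.ravel()
    q, r = np.linalg.qr(gens)
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1.0)
    return q[:, keep]


def assemble_hessian(network: ElasticNetwork, rigid_tol_rel: float = RIGID_TOL_REL) -> HessianBundle:
    """Eigendecompose the network Hessian and split off the six rigid modes.

    Exactly six near-zero eigenvalues must be present (a connected 3-D
    network), and the corresponding eigenvectors must overlap the analytic
    translation/rotation generators; anything else indicates degenerate
    geometry or a disconnected network and raises :class:`ModelError`.
    """
    _check_connected(network.n_nodes, network.spring_index)
    H = hessian_matrix(network)
    evals, evecs = np.linalg.eigh(H)
    tol = rigid_tol_rel * max(evals[-1], 1e-30)
    n_rigid = int(np.sum(np.abs(evals) < tol))
    gens = rigid_mode_generators(network.nodes.coords)
    # 6 rigid modes for generic 3-D geometry; collinear node sets (e.g. a
    # single spring) have only 5 independent translation/rotation generators
    n_expected = gens.shape[1]
    if n_rigid != n_expected:
        raise ModelError(
            f"expected {n_expected} rigid modes, found {n_rigid} "
            "(degenerate geometry or disconnected network)"
        )
    rigid_vecs = evecs[:, :n_rigid]
    # every numeric rigid mode must lie in the span of the analytic generators
    overlap = np.linalg.norm(gens.T @ rigid_vecs, axis=0)
    if np.any(overlap < 0.99):
        raise ModelError(
            f"rigid modes deviate from translation/rotation generators "
            f"(min overlap {overlap.min():.4f})"
        )
    nz = evals[n_rigid:]
    if np.any(nz <= 0):
        raise ModelError("non-rigid spectrum contains non-positive eigenvalues")
    return HessianBundle(
        hessian=H,
        nonrigid_basis=evecs[:, n_rigid:],
        eigenvalues=nz,
        log_pseudodet=float(np.log(nz).sum()),
        coords=network.nodes.coords.copy(),
    )


def quadratic_form_solve(bundle: HessianBundle, vectors: np.ndarray) -> np.ndarray:
    """Apply the Moore-Penrose pseudo-inverse H+ via the non-rigid eigenbasis.

    Input vectors (3N,) or (3N, k) are projected onto the non-rigid subspace,
    scaled by 1/lambda and reconstructed; the result is orthogonal to the
    rigid modes.
    """
    v = np.asarray(vectors, dtype=float)
    single = v.ndim == 1
    if single:
        v = v[:, None]
    w = bundle.nonrigid_basis.T @ v
    out = bundle.nonrigid_basis @ (w / bundle.eigenvalues[:, None])
    return out[:, 0] if single else out
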