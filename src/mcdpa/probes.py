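"""Randomly distributed multi-layer test points covering the protein surface.

Candidate points are drawn on spheres of each layer offset around every node;
a candidate survives only if its nearest-node distance stays within a band of
the layer offset (which rejects points buried inside the body) and if it keeps
a minimum spacing to previously accepted points (greedy Poisson-disk thinning
in seeded candidate order, so a probe set is a pure function of structure,
parameters and seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import NodeSet

DEFAULT_LAYER_OFFSETS = (4.0, 6.0)   # Angstrom
DEFAULT_TARGET_SPACING = 2.0         # Angstrom
LAYER_TOL = 0.5                      # acceptance band around the layer offset
DEFAULT_CANDIDATES_PER_NODE = 40


class ProbeGenerationError(RuntimeError):
    """No probe point survived the surface band test."""


@dataclass
class ProbeSet:
    coords: np.ndarray          # (P, 3)
    layer_offsets: np.ndarray   # (P,) per-point generating offset
    ids: np.ndarray             # (P,) int
    seed: int
    generation_params: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.coords)


def generate_probes(
    nodes: NodeSet,
    layer_offsets: tuple[float, ...] = DEFAULT_LAYER_OFFSETS,
    target_spacing: float = DEFAULT_TARGET_SPACING,
    seed: int = 0,
    candidates_per_node: int = DEFAULT_CANDIDATES_PER_NODE,
    tol: float = LAYER_TOL,
) -> ProbeSet:
    """Generate surface test points on the given layers around the node cloud."""
    if nodes.n_nodes < 1:
        raise ValueError("need at least one node")
    rng = np.random.default_rng(seed)
    tree = cKDTree(nodes.coords)

    kept: list[np.ndarray] = []
    kept_layers: list[float] = []
    spacing2 = target_spacing**2

    for offset in layer_offsets:
        # seeded directions for all nodes of this layer, then greedy thinning
        dirs = rng.normal(size=(nodes.n_nodes, candidates_per_node, 3))
        dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
        cands = nodes.coords[:, None, :] + offset * dirs
        cands = cands.reshape(-1, 3)
        d_near, _ = tree.query(cands)
        ok = np.abs(d_near - offset) <= tol
        for c in cands[ok]:
            if kept:
                arr = np.asarray(kept)
                if np.min(((arr - c) ** 2).sum(axis=1)) < spacing2:
                    continue
            kept.append(c)
            kept_layers.append(offset)

    if not kept:
        raise ProbeGenerationError(
            "no probe point survived the surface band test (pathological geometry)"
        )
    coords = np.asarray(kept)
    return ProbeSet(
        coords=coords,
        layer_offsets=np.asarray(kept_layers),
        ids=np.arange(len(coords)),
        seed=seed,
        generation_params={
            "layer_offsets": list(layer_offsets),
            "target_spacing": target_spacing,
            "candidates_per_node": candidates_per_node,
            "tol": tol,
        },
    )


def _exposed_mask(nodes: NodeSet, probe_offset: float, tol: float,
                  n_directions: int = 64, seed: int = 0) -> np.ndarray:
    """A node is surface-exposed if some direction at probe_offset passes the band test."""
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_directions, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    tree = cKDTree(nodes.coords)
    exposed = np.zeros(nodes.n_nodes, dtype=bool)
    for i, c in enumerate(nodes.coords):
        cand = c + probe_offset * dirs
        d_near, _ = tree.query(cand)
        exposed[i] = np.any(np.abs(d_near - probe_offset) <= tol)
    return exposed


def coverage_report(probes: ProbeSet, nodes: NodeSet, warn_below: float = 0.9) -> dict:
    """Fraction of surface-exposed nodes with at least one nearby probe.

    Buried nodes (no direction at the smallest layer offset passes the band
    test) are excluded from the denominator.  Used as a QC gate: a low value
    means the probe layers failed to cover the whole surface.
    """
    offsets = probes.generation_params.get("layer_offsets", [DEFAULT_LAYER_OFFSETS[0]])
    tol = probes.generation_params.get("tol", LAYER_TOL)
    reach = max(offsets) + tol

    exposed = _exposed_mask(nodes, min(offsets), tol)
    tree = cKDTree(probes.coords)
    d_probe, _ = tree.query(nodes.coords)
    covered = d_probe <= reach

    n_exposed = int(exposed.sum())
    n_cov = int((covered & exposed).sum())
    frac = n_cov / n_exposed if n_exposed else 0.0
    report = {
        "n_nodes": nodes.n_nodes,
        "n_exposed": n_exposed,
        "n_buried": nodes.n_nodes - n_exposed,
        "n_covered": n_cov,
        "coverage": frac,
        "warning": frac < warn_below,
    }
    return report


def probes_to_pdb(probes: ProbeSet, dx_values: np.ndarray | None = None) -> str:
    """Render probes as dummy HETATM records (one chain per layer) for viewing.

    D_x values, when given, are written into the B-factor column so molecular
    viewers can color the surface by perturbation strength.
    """
    lines = []
    layers = sorted(set(probes.layer_offsets.tolist()))
    chain_of = {off: chr(ord("A") + k) for k, off in enumerate(layers)}
    for i, (c, off) in enumerate(zip(probes.coords, probes.layer_offsets)):
        b = 0.0 if dx_values is None else float(dx_values[i])
        serial = (i + 1) % 100000
        lines.append(
            f"HETATM{serial:5d}  X   PRB {chain_of[off]}{(i % 9999) + 1:4d}    "
            f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}{1.0:6.2f}{b:6.2f}           X"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
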