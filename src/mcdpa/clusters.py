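"""Grouping high-D_x probes into ranked, labeled predicted binding regions.

The top fraction of the D_x profile is kept and grouped by single-linkage
connected components; surviving components become clusters sorted by their
mean perturbation value and labeled, in descending order, as chains O, P, Q,
... (primed labels O', P', Q' for predictions made on a protein-protein
complex rather than a monomer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from . import enm as _enm
from . import perturbation as _pert
from . import probes as _probes
from .perturbation import PerturbationProfile
from .probes import ProbeSet
from .structure_io import MolecularStructure, coarse_grain

DEFAULT_TOP_FRACTION = 0.10
DEFAULT_LINKAGE_CUTOFF = 3.5   # Angstrom, harmonized with the overlap r_cutoff
DEFAULT_MIN_CLUSTER_SIZE = 5


@dataclass
class Cluster:
    label: str
    member_ids: np.ndarray      # probe ids
    coords: np.ndarray          # (n_C, 3)
    dx_values: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.member_ids)

    @property
    def mean_dx(self) -> float:
        return float(self.dx_values.mean())

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    provenance: str = "monomer"    # "monomer" | "complex"
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        means = [c.mean_dx for c in self.clusters]
        if any(means[i] < means[i + 1] - 1e-12 for i in range(len(means) - 1)):
            raise ValueError("clusters must be sorted by descending mean D_x")
        labels = [c.label for c in self.clusters]
        if len(set(labels)) != len(labels):
            raise ValueError("cluster labels must be unique")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> list[str]:
        return [c.label for c in self.clusters]


def _label_sequence(n: int, primed: bool) -> list[str]:
    """O, P, ..., Z, then OA, OB, ... ; complex predictions get a prime mark."""
    base = [chr(c) for c in range(ord("O"), ord("Z") + 1)]
    labels = []
    i = 0
    while len(labels) < n:
        if i < len(base):
            labels.append(base[i])
        else:
            j = i - len(base)
            labels.append("O" + chr(ord("A") + j % 26) * (1 + j // 26))
        i += 1
    if primed:
        labels = [lab + "'" for lab in labels]
    return labels


def select_high_dx(
    profile: PerturbationProfile,
    top_fraction: float = DEFAULT_TOP_FRACTION,
) -> np.ndarray:
    """Indices of probes at or above the (1 - top_fraction) D_x quantile.

    The threshold is the k-th largest value with k = ceil(top_fraction * P);
    ties at the threshold are all included, so the selection is deterministic.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    dx = profile.dx_values
    if np.all(dx == 0):
        import logging
        logging.getLogger(__name__).warning("select_high_dx: all-zero profile")
        return np.zeros(0, dtype=int)
    k = max(1, int(np.ceil(top_fraction * len(dx))))
    threshold = np.sort(dx)[::-1][k - 1]
    return np.nonzero(dx >= threshold)[0]


def cluster(
    coords: np.ndarray,
    dx_values: np.ndarray,
    probe_ids: np.ndarray | None = None,
    linkage_cutoff: float = DEFAULT_LINKAGE_CUTOFF,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    provenance: str = "monomer",
) -> ClusterSet:
    """Single-linkage components of the selected probes, ranked by mean D_x.

    Components smaller than ``min_cluster_size`` are discarded.  Ties in mean
    D_x break toward the larger cluster, then the lexicographically smaller
    centroid, so labeling never depends on probe order.
    """
    coords = np.asarray(coords, dtype=float)
    dx_values = np.asarray(dx_values, dtype=float)
    if probe_ids is None:
        probe_ids = np.arange(len(coords))

    if len(coords) == 0:
        import logging
        logging.getLogger(__name__).warning("cluster: no points to cluster")
        return ClusterSet(clusters=[], provenance=provenance)

    tree = cKDTree(coords)
    pairs = tree.query_pairs(linkage_cutoff, output_type="ndarray")
    n = len(coords)
    if len(pairs):
        adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    _, comp = connected_components(adj, directed=False)

    raw = []
    for label in np.unique(comp):
        idx = np.nonzero(comp == label)[0]
        if len(idx) < min_cluster_size:
            continue
        raw.append((coords[idx], dx_values[idx], probe_ids[idx]))

    if not raw:
        import logging
        logging.getLogger(__name__).warning("cluster: no component reached min size %d",
                                            min_cluster_size)
        return ClusterSet(clusters=[], provenance=provenance)

    def sort_key(item):
        c, dx, _ = item
        centroid = c.mean(axis=0)
        return (-dx.mean(), -len(dx), tuple(np.round(centroid, 6)))

    raw.sort(key=sort_key)
    labels = _label_sequence(len(raw), primed=(provenance == "complex"))
    clusters = [
        Cluster(label=lab, member_ids=pid, coords=c, dx_values=dx)
        for lab, (c, dx, pid) in zip(labels, raw)
    ]
    return ClusterSet(clusters=clusters, provenance=provenance,
                      config={"linkage_cutoff": linkage_cutoff,
                              "min_cluster_size": min_cluster_size})


def predict_regions(
    structure: MolecularStructure,
    chain_ids: list[str] | None = None,
    chain_groups: list[set[str]] | None = None,
    *,
    scheme: str = "calpha",
    cutoff: float = _enm.DEFAULT_CUTOFF,
    gamma: float = _enm.DEFAULT_GAMMA,
    gamma_AB: float | None = None,
    layer_offsets: tuple[float, ...] = _probes.DEFAULT_LAYER_OFFSETS,
    target_spacing: float = _probes.DEFAULT_TARGET_SPACING,
    seed: int = 0,
    gamma_s: float | None = None,
    r_int: float = _pert.DEFAULT_R_INT,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    linkage_cutoff: float = DEFAULT_LINKAGE_CUTOFF,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> tuple[ClusterSet, ProbeSet, PerturbationProfile]:
    """End-to-end binding-region prediction for a structure.

    ``chain_groups`` splits a complex into its constituent proteins: intra-
    group springs get ``gamma``, cross-group springs ``gamma_AB`` (default:
    equal to gamma).  A zero ``gamma_AB`` decouples the groups entirely; each
    group is then scored as an independent network (probes are still generated
    on the union so that a shared seed yields group-wise identical points).
    """
    from .structure_io import select_chains

    if chain_ids is not None:
        structure = select_chains(structure, chain_ids)
    nodes = coarse_grain(structure, scheme)

    multi = chain_groups is not None and len(chain_groups) > 1
    provenance = "complex" if multi else "monomer"
    pconf = _pert.PerturbationConfig(gamma_s=gamma_s, r_int=r_int)

    if multi and gamma_AB == 0.0:
        # decoupled limit: each chain group is an independent prediction run,
        # so the result is the union of the single-chain predictions
        all_coords, all_layers, all_dx, all_counts = [], [], [], []
        sel_coords, sel_dx = [], []
        for group in chain_groups:
            gidx = np.array([i for i, c in enumerate(nodes.source_chain) if c in group])
            sub = _subset_nodes(nodes, gidx)
            sub_probes = _probes.generate_probes(sub, layer_offsets, target_spacing, seed)
            net = _enm.build_network(sub, cutoff, gamma)
            sub_profile = _pert.score_all(net, sub_probes, pconf)
            sub_sel = select_high_dx(sub_profile, top_fraction)
            all_coords.append(sub_probes.coords)
            all_layers.append(sub_probes.layer_offsets)
            all_dx.append(sub_profile.dx_values)
            all_counts.append(sub_profile.attached_node_counts)
            sel_coords.append(sub_probes.coords[sub_sel])
            sel_dx.append(sub_profile.dx_values[sub_sel])
        coords = np.concatenate(all_coords)
        probes = ProbeSet(
            coords=coords,
            layer_offsets=np.concatenate(all_layers),
            ids=np.arange(len(coords)), seed=seed,
            generation_params={"layer_offsets": list(layer_offsets),
                               "target_spacing": target_spacing,
                               "decoupled_groups": True},
        )
        profile = _pert.PerturbationProfile(
            probe_ids=probes.ids.copy(), dx_values=np.concatenate(all_dx),
            attached_node_counts=np.concatenate(all_counts), config=pconf)
        cset = cluster(np.concatenate(sel_coords), np.concatenate(sel_dx), None,
                       linkage_cutoff, min_cluster_size, provenance)
        cset.config.update({"seed": seed, "gamma_AB": 0.0, "decoupled": True})
        return cset, probes, profile

    probes = _probes.generate_probes(nodes, layer_offsets, target_spacing, seed)

    if multi:
        net = _enm.build_network(nodes, cutoff, gamma, chain_groups=chain_groups)
        groups = list(chain_groups)
        merged = set(groups[0])
        for g in groups[1:]:
            net = _enm.couple_chains(net, merged, set(g), gamma_AB, cutoff)
            merged |= set(g)
    else:
        net = _enm.build_network(nodes, cutoff, gamma)
    profile = _pert.score_all(net, probes, pconf)

    sel = select_high_dx(profile, top_fraction)
    cset = cluster(probes.coords[sel], profile.dx_values[sel], probes.ids[sel],
                   linkage_cutoff, min_cluster_size, provenance)
    cset.config.update({
        "seed": seed, "scheme": scheme, "cutoff": cutoff, "gamma": gamma,
        "gamma_AB": gamma_AB, "gamma_s": gamma_s, "r_int": r_int,
        "layer_offsets": list(layer_offsets), "target_spacing": target_spacing,
        "top_fraction": top_fraction, "kl_direction": pconf.kl_direction,
    })
    return cset, probes, profile


def _subset_nodes(nodes, idx):
    from .structure_io import NodeSet
    return NodeSet(
        labels=[nodes.labels[i] for i in idx],
        coords=nodes.coords[idx],
        source_chain=[nodes.source_chain[i] for i in idx],
        scheme=nodes.scheme,
        res_seq=[nodes.res_seq[i] for i in idx],
    )


def clusters_to_pdb(cset: ClusterSet) -> str:
    """Clusters as dummy HETATM records, one chain per cluster, D_x as B-factor."""
    lines = []
    serial = 1
    for cl in cset.clusters:
        chain = cl.label.rstrip("'")[0]  # viewers need one-char chain ids
        for k, (c, dx) in enumerate(zip(cl.coords, cl.dx_values)):
            lines.append(
                f"HETATM{serial % 100000:5d}  X   CLU {chain}{(k % 9999) + 1:4d}    "
                f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}{1.0:6.2f}{min(dx, 999.99):6.2f}           X"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
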