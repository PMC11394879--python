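"""Scoring predictions against ligands and classifying PPI-induced changes.

Precision and recall follow the overlap-set definitions: with prediction
cluster C and ligand atom set L,

    c = { s in C : d(s, L) < r_cutoff },   P = |c| / |C|
    l = { l in L : d(l, C) < r_cutoff },   R = |l| / |L|

with r_cutoff defaulting to 3.5 A and strict inequality.  The same overlap
machinery, applied cluster-vs-cluster after superposing the shared protein,
drives the change taxonomy between monomer-based and complex-based
predictions (unchanged / shifted / created / vanished / split / merged), and
ligand inventories of a structure pair are classified analogously
(unchanged / shifted / disappeared / new ligand / fused / split, with the
1 A ARMSD guideline separating unchanged from shifted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .clusters import Cluster, ClusterSet
from .structure_io import (ARMSDResult, LigandAtoms, MolecularStructure,
                           RigidTransform, compute_armsd)

DEFAULT_R_CUTOFF = 3.5        # Angstrom
DEFAULT_LINK_THRESHOLD = 0.2  # overlap fraction creating a correspondence link
DEFAULT_STRONG_THRESHOLD = 0.5  # both-way overlap calling a cluster unchanged
LIGAND_MATCH_DISTANCE = 8.0   # max centroid distance pairing ligands across structures
ARMSD_UNCHANGED_THRESHOLD = 1.0  # Angstrom

CLUSTER_CHANGE_KINDS = ("unchanged", "shifted", "created", "vanished", "split", "merged")
LIGAND_CHANGE_KINDS = ("unchanged", "shifted", "disappeared", "new_ligand", "fused", "split")


@dataclass
class EvalResult:
    precision: float
    recall: float
    n_overlap_points: int     # |c|
    n_covered_ligand_atoms: int  # |l|
    r_cutoff: float = DEFAULT_R_CUTOFF
    cluster_label: str = ""
    ligand_id: str = ""
    hit: bool = False         # >= 1 ligand atom within r_cutoff


@dataclass
class ClusterChange:
    kind: str
    sources: list[str] = field(default_factory=list)   # monomer cluster labels
    targets: list[str] = field(default_factory=list)   # complex cluster labels

    def __post_init__(self) -> None:
        if self.kind not in CLUSTER_CHANGE_KINDS:
            raise ValueError(f"unknown cluster-change kind {self.kind!r}")
        if self.kind == "created" and self.sources:
            raise ValueError("created change must have empty sources")
        if self.kind == "vanished" and self.targets:
            raise ValueError("vanished change must have empty targets")
        if self.kind == "split" and not (len(self.sources) == 1 and len(self.targets) >= 2):
            raise ValueError("split requires 1 source and >= 2 targets")
        if self.kind == "merged" and not (len(self.sources) >= 2 and len(self.targets) == 1):
            raise ValueError("merged requires >= 2 sources and 1 target")


@dataclass
class LigandChange:
    category: str
    monomer_ligands: list[str] = field(default_factory=list)
    complex_ligands: list[str] = field(default_factory=list)
    armsd: ARMSDResult | None = None

    def __post_init__(self) -> None:
        if self.category not in LIGAND_CHANGE_KINDS:
            raise ValueError(f"unknown ligand-change category {self.category!r}")
        if self.category in ("unchanged", "shifted") and self.armsd is None:
            raise ValueError(f"{self.category} requires an ARMSD")


@dataclass
class PairRecord:
    """A monomer structure A-L1 paired with a complex structure B-A-L2."""

    monomer: MolecularStructure
    complex: MolecularStructure
    transform: RigidTransform          # complex frame -> monomer frame
    monomer_ligands: list[LigandAtoms] = field(default_factory=list)
    complex_ligands: list[LigandAtoms] = field(default_factory=list)


# ---------------------------------------------------------------------------
# precision / recall


def precision_recall(
    cluster: Cluster, ligand: LigandAtoms, r_cutoff: float = DEFAULT_R_CUTOFF
) -> EvalResult:
    """Overlap precision/recall of one cluster against one ligand."""
    if cluster.n_points == 0:
        raise ValueError("precision undefined for an empty cluster")
    if r_cutoff <= 0:
        raise ValueError("r_cutoff must be > 0")
    D = cdist(cluster.coords, ligand.coords_array())
    c = int(np.sum(D.min(axis=1) < r_cutoff))
    l = int(np.sum(D.min(axis=0) < r_cutoff))
    return EvalResult(
        precision=c / cluster.n_points,
        recall=l / ligand.n_atoms,
        n_overlap_points=c,
        n_covered_ligand_atoms=l,
        r_cutoff=r_cutoff,
        cluster_label=cluster.label,
        ligand_id=ligand.ligand_id,
        hit=l >= 1,
    )


def best_region_report(
    cset: ClusterSet,
    ligands: list[LigandAtoms],
    r_cutoff: float = DEFAULT_R_CUTOFF,
) -> list[EvalResult]:
    """Per ligand, the cluster with maximal recall (ties: precision, then label)."""
    report = []
    for lig in ligands:
        best: EvalResult | None = None
        for cl in cset.clusters:
            res = precision_recall(cl, lig, r_cutoff)
            if best is None:
                best = res
                continue
            a, b = (res.recall, res.precision), (best.recall, best.precision)
            if a > b or (a == b and _label_rank(res.cluster_label) < _label_rank(best.cluster_label)):
                best = res
        if best is None:
            best = EvalResult(precision=0.0, recall=0.0, n_overlap_points=0,
                              n_covered_ligand_atoms=0, r_cutoff=r_cutoff,
                              ligand_id=lig.ligand_id, hit=False)
        report.append(best)
    return report


def _label_rank(label: str) -> tuple[int, str]:
    # label order: O < P < ... < Z < OA < OB ...
    core = label.rstrip("'")
    return (len(core), core)


# ---------------------------------------------------------------------------
# cluster-set comparison (PPI-induced changes in predicted regions)


def _overlap_fraction(coords_a: np.ndarray, coords_b: np.ndarray, r_cutoff: float) -> float:
    """Fraction of points in A within r_cutoff of any point of B (strict <)."""
    D = cdist(coords_a, coords_b)
    return float(np.mean(D.min(axis=1) < r_cutoff))


def compare_cluster_sets(
    mono: ClusterSet,
    complexed: ClusterSet,
    transform: RigidTransform | None = None,
    r_cutoff: float = DEFAULT_R_CUTOFF,
    link_threshold: float = DEFAULT_LINK_THRESHOLD,
    strong_threshold: float = DEFAULT_STRONG_THRESHOLD,
) -> list[ClusterChange]:
    """Classify how monomer-based clusters map onto complex-based clusters.

    ``transform`` maps the monomer frame onto the complex frame (identity if
    the predictions already share a frame).  For every cluster pair (C, C')
    the two overlap fractions |c|/|C| and |c'|/|C'| are computed; a link
    exists when either reaches ``link_threshold``.  Link-graph components are
    decomposed greedily by descending overlap into star-shaped groups and
    classified: isolated mono cluster -> vanished, isolated complex cluster
    -> created, 1-1 with both fractions >= ``strong_threshold`` -> unchanged,
    1-1 below -> shifted, 1-many -> split, many-1 -> merged.
    """
    if transform is None:
        transform = RigidTransform.identity()
    if transform.fit_rmsd > 10.0:
        import logging
        logging.getLogger(__name__).warning(
            "compare_cluster_sets: superposition fit RMSD %.1f A exceeds sanity bound",
            transform.fit_rmsd)

    mono_coords = [transform.apply(c.coords) for c in mono.clusters]
    cplx_coords = [c.coords for c in complexed.clusters]

    links = []  # (strength, i_mono, j_complex, frac_mono, frac_cplx)
    for i, mc in enumerate(mono_coords):
        for j, cc in enumerate(cplx_coords):
            f_m = _overlap_fraction(mc, cc, r_cutoff)
            f_c = _overlap_fraction(cc, mc, r_cutoff)
            if max(f_m, f_c) >= link_threshold:
                links.append((max(f_m, f_c), i, j, f_m, f_c))
    links.sort(key=lambda t: (-t[0], t[1], t[2]))

    # greedy star decomposition: each accepted link joins a group that stays
    # 1-1, 1-many or many-1
    group_of_mono: dict[int, int] = {}
    group_of_cplx: dict[int, int] = {}
    groups: list[dict] = []
    for strength, i, j, f_m, f_c in links:
        gi = group_of_mono.get(i)
        gj = group_of_cplx.get(j)
        if gi is None and gj is None:
            groups.append({"mono": {i}, "cplx": {j}, "links": [(i, j, f_m, f_c)]})
            group_of_mono[i] = group_of_cplx[j] = len(groups) - 1
        elif gi is not None and gj is None:
            g = groups[gi]
            if len(g["cplx"]) >= 1 and len(g["mono"]) > 1:
                continue  # would create many-many
            g["cplx"].add(j)
            g["links"].append((i, j, f_m, f_c))
            group_of_cplx[j] = gi
        elif gi is None and gj is not None:
            g = groups[gj]
            if len(g["mono"]) >= 1 and len(g["cplx"]) > 1:
                continue
            g["mono"].add(i)
            g["links"].append((i, j, f_m, f_c))
            group_of_mono[i] = gj
        else:
            continue  # both already grouped; dropping keeps groups star-shaped

    changes: list[ClusterChange] = []
    for g in groups:
        src = sorted(mono.clusters[i].label for i in g["mono"])
        tgt = sorted(complexed.clusters[j].label for j in g["cplx"])
        if len(src) == 1 and len(tgt) == 1:
            (_, _, f_m, f_c) = g["links"][0]
            kind = "unchanged" if min(f_m, f_c) >= strong_threshold else "shifted"
        elif len(src) == 1:
            kind = "split"
        else:
            kind = "merged"
        changes.append(ClusterChange(kind=kind, sources=src, targets=tgt))

    for i, cl in enumerate(mono.clusters):
        if i not in group_of_mono:
            changes.append(ClusterChange(kind="vanished", sources=[cl.label]))
    for j, cl in enumerate(complexed.clusters):
        if j not in group_of_cplx:
            changes.append(ClusterChange(kind="created", targets=[cl.label]))
    return changes


def change_summary(changes: list[ClusterChange]) -> dict[str, int]:
    counts = {k: 0 for k in CLUSTER_CHANGE_KINDS}
    for ch in changes:
        counts[ch.kind] += 1
    return counts


# ---------------------------------------------------------------------------
# ligand-change classification


def classify_ligand_change(
    pair: PairRecord,
    match_distance: float = LIGAND_MATCH_DISTANCE,
    armsd_threshold: float = ARMSD_UNCHANGED_THRESHOLD,
) -> list[LigandChange]:
    """Classify every ligand of an A-L1 / B-A-L2 pair into the six categories.

    Ligands are matched across the pair by shared residue name and pocket
    proximity (centroids within ``match_distance`` after superposing the
    shared protein).  Matched 1-1 groups with equal composition classify by
    ARMSD against the 1 A guideline; one-sided ligands are disappeared /
    new-ligand; entity- or residue-count asymmetries are fused (toward the
    complex oligomer) or split.
    """
    if not pair.monomer_ligands and not pair.complex_ligands:
        raise ValueError("no ligands on either side of the pair")

    t = pair.transform
    mono = pair.monomer_ligands
    cplx = pair.complex_ligands
    mono_cent = [l.center_of_mass() for l in mono]
    cplx_cent = [t.apply(l.center_of_mass()[None, :])[0] for l in cplx]

    # bipartite match graph: shared residue name + centroid proximity
    edges = []
    for i, ml in enumerate(mono):
        for j, cl in enumerate(cplx):
            if set(ml.residue_names) & set(cl.residue_names):
                d = float(np.linalg.norm(mono_cent[i] - cplx_cent[j]))
                if d <= match_distance:
                    edges.append((d, i, j))
    edges.sort()

    # connected components of the match graph
    parent: dict[tuple, tuple] = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    nodes = [("m", i) for i in range(len(mono))] + [("c", j) for j in range(len(cplx))]
    for x in nodes:
        parent[x] = x
    for _, i, j in edges:
        ri, rj = find(("m", i)), find(("c", j))
        if ri != rj:
            parent[rj] = ri

    comps: dict[tuple, dict] = {}
    for x in nodes:
        comps.setdefault(find(x), {"m": [], "c": []})[x[0]].append(x[1])

    changes: list[LigandChange] = []
    for comp in comps.values():
        m_ids = [mono[i].ligand_id for i in comp["m"]]
        c_ids = [cplx[j].ligand_id for j in comp["c"]]
        nm, nc = len(comp["m"]), len(comp["c"])
        if nc == 0:
            changes.append(LigandChange("disappeared", monomer_ligands=m_ids))
            continue
        if nm == 0:
            changes.append(LigandChange("new_ligand", complex_ligands=c_ids))
            continue
        m_res = sum(mono[i].n_residues for i in comp["m"])
        c_res = sum(cplx[j].n_residues for j in comp["c"])
        if nm > nc or (nm == nc == 1 and c_res > m_res):
            changes.append(LigandChange("fused", monomer_ligands=m_ids,
                                        complex_ligands=c_ids))
            continue
        if nc > nm or (nm == nc == 1 and m_res > c_res):
            changes.append(LigandChange("split", monomer_ligands=m_ids,
                                        complex_ligands=c_ids))
            continue
        ml, cl = mono[comp["m"][0]], cplx[comp["c"][0]]
        try:
            armsd = compute_armsd(ml, cl, t, mode="atom_match")
        except ValueError:
            armsd = compute_armsd(ml, cl, t, mode="center_of_mass")
        cat = "unchanged" if armsd.value < armsd_threshold else "shifted"
        changes.append(LigandChange(cat, monomer_ligands=m_ids,
                                    complex_ligands=c_ids, armsd=armsd))
    return changes


# ---------------------------------------------------------------------------
# reports


def report_tsv(rows: list[dict]) -> str:
    """Table-style TSV report (category, structures, ligands, ARMSD, P/R columns)."""
    cols = ["category", "A_L1", "L1", "B_A_L2", "L2", "ARMSD",
            "L1_precision", "L1_recall", "L2_precision", "L2_recall"]
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(_fmt(row.get(c)) for c in cols))
    return "\n".join(lines) + "\n"


def _fmt(v) -> str:
    if v is None:
        return "-"
    if isinstance(v, float):
        return f"{v:.2f}"
    return str(v)
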