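"""Reading PDB structures, chain selection, ligand extraction, coarse-graining,
superposition and ligand ARMSD.

The structural bookkeeping here supports comparing how the same protein A binds
a ligand alone (A-L1) and inside a protein-protein complex (B-A-L2): the shared
protein is superposed between the two structures and the carried ligands are
compared atom-by-atom (ARMSD) in the common frame.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

#: residue names treated as water
WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: common monoatomic ions excluded from ligand extraction by default
ION_RESIDUES = frozenset(
    {"NA", "K", "CL", "MG", "ZN", "CA", "MN", "FE", "FE2", "CO", "NI", "CU",
     "CD", "HG", "IOD", "BR", "F", "LI", "RB", "CS", "SR", "BA", "CS1"}
)

DEFAULT_LIGAND_EXCLUDE = WATER_RESIDUES | ION_RESIDUES

#: inter-residue heavy-atom distance below which two hetero residues of the
#: same chain are considered covalently linked (glycosidic/phosphodiester range)
OLIGOMER_BOND_THRESHOLD = 1.9


class StructureError(ValueError):
    """Raised for unusable or empty structural input."""


class DegenerateFitError(ValueError):
    """Raised when a rigid-body fit is underdetermined (too few or collinear points)."""


@dataclass(frozen=True)
class Atom:
    """One resolved atom of a parsed structure."""

    name: str
    element: str
    chain_id: str
    res_name: str
    res_seq: int
    icode: str
    coords: np.ndarray  # shape (3,), Angstrom
    record_kind: str  # "polymer" | "hetero"
    altloc: str = ""
    occupancy: float = 1.0
    is_water: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)


@dataclass
class MolecularStructure:
    """Parsed atoms of one model of a structure."""

    atoms: list[Atom]
    name: str = ""
    n_skipped_lines: int = 0

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"structure {self.name!r} contains no atoms")
        for a in self.atoms:
            if not np.all(np.isfinite(a.coords)):
                raise StructureError(f"non-finite coordinates on atom {a.name}")

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class LigandAtoms:
    """A bound hetero entity: one hetero residue or a covalently linked oligomer.

    ``atoms`` keeps (atom_name, element, coords, res_name, res_index) where
    res_index enumerates the member residues of an oligomer in file order.
    """

    ligand_id: str
    atoms: list[tuple[str, str, np.ndarray, str, int]]
    residue_names: list[str] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    def coords_array(self) -> np.ndarray:
        return np.array([a[2] for a in self.atoms], dtype=float)

    def center_of_mass(self) -> np.ndarray:
        weights = np.array([gemmi.Element(a[1]).weight for a in self.atoms])
        coords = self.coords_array()
        return (coords * weights[:, None]).sum(axis=0) / weights.sum()


@dataclass
class NodeSet:
    """Coarse-grained nodes used to build elastic networks."""

    labels: list[str]
    coords: np.ndarray  # (N, 3)
    source_chain: list[str]
    scheme: str  # "calpha" | "heavy_atom"
    res_seq: list[int] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


@dataclass
class RigidTransform:
    """Proper rigid-body transform x -> R x + t."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    fit_rmsd: float

    def __post_init__(self) -> None:
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-8:
            raise ValueError(f"rotation is not proper (det={det})")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation, self.fit_rmsd)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 0.0)


@dataclass
class ARMSDResult:
    """Ligand ARMSD between two superposed structures."""

    value: float
    n_matched_atoms: int
    mode: str  # "atom_match" | "center_of_mass"
    unmatched_atoms: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# parsing


def _line_is_malformed(line: str) -> bool:
    if not line.startswith(("ATOM", "HETATM")):
        return False
    if len(line) < 54:
        return True
    try:
        float(line[30:38])
        float(line[38:46])
        float(line[46:54])
        int(line[22:26])
    except ValueError:
        return True
    return False


def read_pdb(source) -> MolecularStructure:
    """Parse PDB text into a :class:`MolecularStructure`.

    Accepts a path or an open text stream.  Only the first MODEL is kept.
    Alternate locations are resolved to the highest-occupancy conformer
    (ties: first in file).  Waters are retained but flagged.  Malformed
    ATOM/HETATM lines are skipped with a logged warning count.
    """
    if hasattr(source, "read"):
        text = source.read()
        name = getattr(source, "name", "<stream>")
    else:
        path = Path(source)
        if not path.exists():
            raise StructureError(f"cannot read PDB source: {path}")
        text = path.read_text()
        name = path.stem

    lines = text.splitlines()
    kept_lines = []
    n_skipped = 0
    for line in lines:
        if _line_is_malformed(line):
            n_skipped += 1
        else:
            kept_lines.append(line)
    if n_skipped:
        logger.warning("read_pdb(%s): skipped %d malformed record line(s)", name, n_skipped)

    try:
        st = gemmi.read_pdb_string("\n".join(kept_lines) + "\n")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"unreadable PDB source {name!r}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no model found in {name!r}")

    model = st[0]
    # altloc resolution: group by (chain, seqid, icode, atom name)
    best: dict[tuple, tuple[int, Atom]] = {}
    order = 0
    for chain in model:
        for res in chain:
            kind = "hetero" if res.het_flag == "H" else "polymer"
            water = res.name in WATER_RESIDUES
            for at in res:
                coords = np.array([at.pos.x, at.pos.y, at.pos.z])
                atom = Atom(
                    name=at.name,
                    element=at.element.name,
                    chain_id=chain.name,
                    res_name=res.name,
                    res_seq=res.seqid.num,
                    icode=(res.seqid.icode or " ").strip(),
                    coords=coords,
                    record_kind=kind,
                    altloc=(at.altloc or "").strip(),
                    occupancy=at.occ,
                    is_water=water,
                )
                key = (chain.name, res.seqid.num, atom.icode, res.name, at.name)
                prev = best.get(key)
                if prev is None or atom.occupancy > prev[1].occupancy + 1e-12:
                    best[key] = (order if prev is None else prev[0], atom)
                order += 1

    atoms = [a for _, a in sorted(best.values(), key=lambda t: t[0])]
    if not any(True for a in atoms):
        raise StructureError(f"zero atom records in {name!r}")
    return MolecularStructure(atoms=atoms, name=name, n_skipped_lines=n_skipped)


def select_chains(structure: MolecularStructure, chain_ids: Sequence[str]) -> MolecularStructure:
    """Restrict a structure to the requested chains (hetero records included)."""
    available = set(structure.chain_ids)
    missing = [c for c in chain_ids if c not in available]
    if missing:
        raise LookupError(
            f"unknown chain id(s) {missing}; available chains: {sorted(available)}"
        )
    wanted = set(chain_ids)
    atoms = [a for a in structure.atoms if a.chain_id in wanted]
    return MolecularStructure(atoms=atoms, name=structure.name,
                              n_skipped_lines=structure.n_skipped_lines)


# ---------------------------------------------------------------------------
# ligands


def extract_ligands(
    structure: MolecularStructure,
    exclude: Iterable[str] = DEFAULT_LIGAND_EXCLUDE,
    bond_threshold: float = OLIGOMER_BOND_THRESHOLD,
) -> list[LigandAtoms]:
    """Group hetero residues into bound ligand entities.

    Waters and common monoatomic ions are excluded.  Hetero residues of the
    same chain whose closest inter-residue atom distance is below
    ``bond_threshold`` are merged into one oligomeric ligand (the poly-NAG
    case: glycosidic links sit near 1.4 A).
    """
    exclude = set(exclude)
    residues: dict[tuple, list[Atom]] = {}
    for a in structure.atoms:
        if a.record_kind != "hetero" or a.is_water or a.res_name in exclude:
            continue
        residues.setdefault((a.chain_id, a.res_seq, a.icode, a.res_name), []).append(a)

    keys = list(residues)
    if not keys:
        return []

    # union-find merge of covalently linked same-chain hetero residues
    parent = list(range(len(keys)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(keys)):
        ci = np.array([a.coords for a in residues[keys[i]]])
        for j in range(i + 1, len(keys)):
            if keys[i][0] != keys[j][0]:
                continue
            cj = np.array([a.coords for a in residues[keys[j]]])
            d2 = ((ci[:, None, :] - cj[None, :, :]) ** 2).sum(-1)
            if d2.min() < bond_threshold**2:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(len(keys)):
        groups.setdefault(find(i), []).append(i)

    ligands = []
    for root in sorted(groups):
        members = sorted(groups[root])
        atoms: list[tuple[str, str, np.ndarray, str, int]] = []
        res_names = []
        id_parts = []
        for res_index, ki in enumerate(members):
            chain, seq, icode, rname = keys[ki]
            res_names.append(rname)
            id_parts.append(f"{rname}_{chain}{seq}{icode}".rstrip())
            for a in residues[keys[ki]]:
                atoms.append((a.name, a.element, a.coords, rname, res_index))
        ligands.append(LigandAtoms(ligand_id="+".join(id_parts), atoms=atoms,
                                   residue_names=res_names))
    return ligands


# ---------------------------------------------------------------------------
# coarse-graining


def coarse_grain(structure: MolecularStructure, scheme: str = "calpha") -> NodeSet:
    """Reduce polymer atoms to ENM nodes.

    ``calpha`` keeps one node per residue at its CA position (residues without
    a CA are dropped with a warning); ``heavy_atom`` keeps every non-hydrogen
    polymer atom.
    """
    if scheme not in ("calpha", "heavy_atom"):
        raise ValueError(f"unknown coarse-graining scheme {scheme!r}")

    labels: list[str] = []
    coords: list[np.ndarray] = []
    chains: list[str] = []
    seqs: list[int] = []

    if scheme == "calpha":
        seen: dict[tuple, bool] = {}
        for a in structure.atoms:
            if a.record_kind != "polymer":
                continue
            seen.setdefault(a.residue_key, False)
            if a.name == "CA" and not seen[a.residue_key]:
                seen[a.residue_key] = True
                labels.append(f"{a.chain_id}:{a.res_name}{a.res_seq}{a.icode}".rstrip())
                coords.append(a.coords)
                chains.append(a.chain_id)
                seqs.append(a.res_seq)
        n_missing = sum(1 for v in seen.values() if not v)
        if n_missing:
            logger.warning("coarse_grain: dropped %d residue(s) without a CA atom", n_missing)
    else:
        for a in structure.atoms:
            if a.record_kind != "polymer" or a.element == "H":
                continue
            labels.append(f"{a.chain_id}:{a.res_name}{a.res_seq}{a.icode}:{a.name}".rstrip())
            coords.append(a.coords)
            chains.append(a.chain_id)
            seqs.append(a.res_seq)

    if not labels:
        raise StructureError("coarse-graining produced zero nodes (no polymer atoms?)")
    return NodeSet(labels=labels, coords=np.array(coords), source_chain=chains,
                   scheme=scheme, res_seq=seqs)


# ---------------------------------------------------------------------------
# superposition


def build_residue_correspondence(mobile: NodeSet, reference: NodeSet) -> list[tuple[int, int]]:
    """Match nodes of two CA node sets by residue number, chain-agnostic.

    Intended for the shared protein of an A-L1 / B-A-L2 pair after chain
    selection; residue numbers appearing more than once on either side are
    dropped to keep the correspondence unambiguous.
    """
    def unique_map(ns: NodeSet) -> dict[int, int]:
        counts: dict[int, int] = {}
        for s in ns.res_seq:
            counts[s] = counts.get(s, 0) + 1
        return {s: i for i, s in enumerate(ns.res_seq) if counts[s] == 1}

    mob = unique_map(mobile)
    ref = unique_map(reference)
    return [(mob[s], ref[s]) for s in sorted(set(mob) & set(ref))]


def superpose(
    mobile: NodeSet,
    reference: NodeSet,
    correspondence: list[tuple[int, int]] | None = None,
) -> RigidTransform:
    """Least-squares proper rigid fit (Kabsch) of mobile onto reference.

    ``correspondence`` is a list of (mobile_index, reference_index) pairs;
    when omitted it is built by matching residue numbers.
    """
    if correspondence is None:
        correspondence = build_residue_correspondence(mobile, reference)
    if len(correspondence) < 3:
        raise DegenerateFitError(
            f"need >= 3 correspondence pairs, got {len(correspondence)}"
        )
    mi = np.array([p[0] for p in correspondence])
    ri = np.array([p[1] for p in correspondence])
    mob = mobile.coords[mi]
    ref = reference.coords[ri]

    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    mob0 = mob - mob_c
    ref0 = ref - ref_c

    sv = np.linalg.svd(mob0, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateFitError("correspondence points are collinear")

    rot, rssd = Rotation.align_vectors(ref0, mob0)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    rmsd = float(rssd) / np.sqrt(len(correspondence))
    return RigidTransform(rotation=R, translation=t, fit_rmsd=rmsd)


# ---------------------------------------------------------------------------
# ARMSD


def _match_atoms(
    ligand_1: LigandAtoms, ligand_2: LigandAtoms
) -> tuple[list[tuple[int, int]], list[str]]:
    """Pair atoms by atom name, residue-by-residue for oligomers."""

    def by_residue(lig: LigandAtoms) -> dict[int, list[tuple[int, str, str]]]:
        out: dict[int, list[tuple[int, str, str]]] = {}
        for idx, (name, _el, _c, rname, ri) in enumerate(lig.atoms):
            out.setdefault(ri, []).append((idx, name, rname))
        return out

    r1 = by_residue(ligand_1)
    r2 = by_residue(ligand_2)

    # pair member residues of equal residue name in file order
    res_pairs: list[tuple[int, int]] = []
    used2: set[int] = set()
    for i1 in sorted(r1):
        name1 = r1[i1][0][2]
        for i2 in sorted(r2):
            if i2 in used2:
                continue
            if r2[i2][0][2] == name1:
                res_pairs.append((i1, i2))
                used2.add(i2)
                break

    pairs: list[tuple[int, int]] = []
    unmatched: list[str] = []
    matched1: set[int] = set()
    matched2: set[int] = set()
    for i1, i2 in res_pairs:
        names2 = {name: idx for idx, name, _ in r2[i2]}
        for idx1, name, _ in r1[i1]:
            if name in names2:
                pairs.append((idx1, names2[name]))
                matched1.add(idx1)
                matched2.add(names2[name])
    for idx, (name, _el, _c, rname, _ri) in enumerate(ligand_1.atoms):
        if idx not in matched1:
            unmatched.append(f"{rname}:{name} (ligand 1)")
    for idx, (name, _el, _c, rname, _ri) in enumerate(ligand_2.atoms):
        if idx not in matched2:
            unmatched.append(f"{rname}:{name} (ligand 2)")
    return pairs, unmatched


def compute_armsd(
    ligand_1: LigandAtoms,
    ligand_2: LigandAtoms,
    transform: RigidTransform | None = None,
    mode: str = "atom_match",
) -> ARMSDResult:
    """Ligand ARMSD after superposing the shared protein.

    ``transform`` maps the frame of ligand_2's parent structure onto
    ligand_1's (identity if omitted).  In ``atom_match`` mode atoms are
    paired by atom name (residue-wise for oligomers); atoms without a
    counterpart are excluded and listed.  In ``center_of_mass`` mode, for
    chemically different ligands, the value is the distance between the
    transformed mass centroids.
    """
    if transform is None:
        transform = RigidTransform.identity()

    if mode == "center_of_mass":
        c1 = ligand_1.center_of_mass()
        c2 = transform.apply(ligand_2.center_of_mass()[None, :])[0]
        return ARMSDResult(value=float(np.linalg.norm(c1 - c2)),
                           n_matched_atoms=0, mode=mode)

    if mode != "atom_match":
        raise ValueError(f"unknown ARMSD mode {mode!r}")

    pairs, unmatched = _match_atoms(ligand_1, ligand_2)
    if not pairs:
        raise ValueError(
            "no atom-name correspondence between ligands "
            f"{ligand_1.ligand_id!r} and {ligand_2.ligand_id!r}; "
            "consider mode='center_of_mass'"
        )
    c1 = ligand_1.coords_array()[[p[0] for p in pairs]]
    c2 = transform.apply(ligand_2.coords_array()[[p[1] for p in pairs]])
    value = float(np.sqrt(((c1 - c2) ** 2).sum(axis=1).mean()))
    return ARMSDResult(value=value, n_matched_atoms=len(pairs), mode=mode,
                       unmatched_atoms=unmatched)
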