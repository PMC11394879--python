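"""Deterministic toy structures with known geometry.

Synthetic CA-only pseudo-proteins — convex shells, shells with a concave
pocket, two-shell complexes with a defined interface, optionally with a
planted hetero ligand — written as valid PDB together with machine-readable
ground truth (pocket center, interface pair count, ligand site).  These are
the no-download substrate for testing every pipeline stage: the pocket cage
embodies the deep/narrow/distinct binding cavity the method is meant to find,
at the same coarse-grained resolution (one pseudo-residue per node, ~5-6 A
spacing) the elastic network operates on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .structure_io import Atom, MolecularStructure


@dataclass
class FixtureSpec:
    kind: str = "pocket_cage"   # shell | pocket_cage | two_chain_complex | ligand_in_pocket
    n_nodes: int = 300          # target node count of the solid body
    radius: float = 16.0        # outer radius, A
    pocket_depth: float = 8.0   # pocket depth below the surface, A
    pocket_radius: float = 5.0  # radius of the carved cavity, A
    interface_gap: float = 5.0  # closest surface-surface approach, A
    shell_spacing: float = 4.0  # radial shell spacing, A (~CA-CA density)
    jitter: float = 0.25        # positional noise, A
    seed: int = 0


@dataclass
class Fixture:
    structure: MolecularStructure
    ground_truth: dict = field(default_factory=dict)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit directions (golden-angle spiral)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _solid_ball_coords(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform solid ball: concentric Fibonacci shells plus a center node.

    Node counts per shell scale with surface area so the body has roughly
    constant density; a filled interior is what makes the surface band test
    meaningful (buried candidate points are rejected, as for a real protein).
    """
    radii = []
    r = spec.radius
    while r > spec.shell_spacing / 2:
        radii.append(r)
        r -= spec.shell_spacing
    weights = np.array([rr**2 for rr in radii])
    counts = np.maximum(4, np.round((spec.n_nodes - 1) * weights / weights.sum()).astype(int))
    parts = [np.zeros((1, 3))]
    for rr, cnt in zip(radii, counts):
        parts.append(_fibonacci_sphere(int(cnt)) * rr)
    coords = np.concatenate(parts)
    coords += rng.normal(scale=spec.jitter, size=coords.shape)
    return coords


def _atoms_from_coords(coords: np.ndarray, chain_id: str, start_seq: int = 1) -> list[Atom]:
    return [
        Atom(name="CA", element="C", chain_id=chain_id, res_name="GLY",
             res_seq=start_seq + i, icode="", coords=np.asarray(c, dtype=float),
             record_kind="polymer")
        for i, c in enumerate(coords)
    ]


def make_pocket_cage(spec: FixtureSpec | None = None) -> Fixture:
    """Solid pseudo-protein ball with a deep, narrow pocket carved along +z.

    The cavity is a sphere of ``pocket_radius`` centered on the axis so that
    its bottom sits ``pocket_depth`` below the surface and its mouth opens
    through it; nodes inside the cavity are removed.  The cavity center is
    returned as ground truth (where a ligand would sit).  ``pocket_depth`` 0
    yields a plain convex body.
    """
    spec = spec or FixtureSpec()
    if spec.n_nodes < 40:
        raise ValueError("pocket cage needs n_nodes >= 40")
    if spec.pocket_depth > spec.radius:
        raise ValueError("pocket depth exceeds body radius (infeasible geometry)")
    rng = np.random.default_rng(spec.seed)
    coords = _solid_ball_coords(spec, rng)

    gt: dict = {"kind": "pocket_cage", "radius": spec.radius, "seed": spec.seed}
    if spec.pocket_depth > 0:
        cavity_center = np.array(
            [0.0, 0.0, spec.radius - spec.pocket_depth + spec.pocket_radius])
        keep = np.linalg.norm(coords - cavity_center, axis=1) > spec.pocket_radius
        coords = coords[keep]
        gt.update({
            "pocket_center": cavity_center.tolist(),
            "pocket_axis": [0.0, 0.0, 1.0],
            "pocket_depth": spec.pocket_depth,
            "pocket_radius": spec.pocket_radius,
        })

    structure = MolecularStructure(atoms=_atoms_from_coords(coords, "A"),
                                   name=f"pocket_cage_seed{spec.seed}")
    return Fixture(structure=structure, ground_truth=gt)


def make_shell(spec: FixtureSpec | None = None) -> Fixture:
    spec = spec or FixtureSpec(kind="shell")
    plain = FixtureSpec(**{**spec.__dict__, "pocket_depth": 0.0, "kind": "shell"})
    fx = make_pocket_cage(plain)
    fx.ground_truth["kind"] = "shell"
    return fx


#: a small rigid pseudo-ligand (tetrahedron + center), ~2 A bond lengths
_LIGAND_TEMPLATE = np.array([
    [0.0, 0.0, 0.0],
    [1.6, 1.6, 1.6],
    [1.6, -1.6, -1.6],
    [-1.6, 1.6, -1.6],
    [-1.6, -1.6, 1.6],
]) * 0.8


def _ligand_atoms(site: np.ndarray, chain_id: str, res_name: str = "LIG",
                  res_seq: int = 900) -> list[Atom]:
    names = ["C1", "C2", "C3", "C4", "C5"]
    return [
        Atom(name=n, element="C", chain_id=chain_id, res_name=res_name,
             res_seq=res_seq, icode="", coords=site + d, record_kind="hetero")
        for n, d in zip(names, _LIGAND_TEMPLATE)
    ]


def make_ligand_in_pocket(spec: FixtureSpec | None = None) -> Fixture:
    """Pocket cage with a hetero pseudo-ligand planted at the pocket center."""
    spec = spec or FixtureSpec(kind="ligand_in_pocket")
    fx = make_pocket_cage(spec)
    site = np.array(fx.ground_truth["pocket_center"])
    atoms = fx.structure.atoms + _ligand_atoms(site, "A")
    fx.structure = MolecularStructure(atoms=atoms, name=fx.structure.name + "_lig")
    fx.ground_truth["ligand_site"] = site.tolist()
    fx.ground_truth["kind"] = "ligand_in_pocket"
    return fx


def make_two_chain_complex(
    spec: FixtureSpec | None = None,
    enm_cutoff: float = 13.0,
    ligand_site: str | None = None,
) -> Fixture:
    """Two pseudo-protein shells (chains A, B) meeting at a contact patch.

    Shell centers sit ``2 * radius + interface_gap`` apart along x, so the
    facing caps form the interface; the gap must stay within the ENM cutoff
    for cross-chain springs to exist.  ``ligand_site`` plants a hetero ligand
    at the interface midpoint ("interface") or on the far side of chain A
    ("distal").
    """
    spec = spec or FixtureSpec(kind="two_chain_complex")
    if spec.interface_gap > enm_cutoff:
        raise ValueError(
            f"interface gap {spec.interface_gap} A exceeds ENM cutoff {enm_cutoff} A: "
            "no interface contacts"
        )
    rng = np.random.default_rng(spec.seed)
    coords_a = _solid_ball_coords(spec, rng)
    coords_b = _solid_ball_coords(spec, rng) + np.array(
        [2 * spec.radius + spec.interface_gap, 0.0, 0.0])

    atoms = _atoms_from_coords(coords_a, "A") + _atoms_from_coords(coords_b, "B")

    # ground truth: cross pairs within the cutoff by brute-force scan
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=-1)
    n_cross = int((d <= enm_cutoff).sum())

    gt = {"kind": "two_chain_complex", "n_cross_pairs": n_cross,
          "interface_gap": spec.interface_gap, "seed": spec.seed}

    if ligand_site is not None:
        if ligand_site == "interface":
            site = np.array([spec.radius + spec.interface_gap / 2.0, 0.0, 0.0])
        elif ligand_site == "distal":
            site = np.array([-spec.radius - 4.0, 0.0, 0.0])
        else:
            raise ValueError(f"unknown ligand_site {ligand_site!r}")
        atoms = atoms + _ligand_atoms(site, "A")
        gt["ligand_site"] = site.tolist()

    structure = MolecularStructure(atoms=atoms, name=f"two_chain_seed{spec.seed}")
    return Fixture(structure=structure, ground_truth=gt)


def make_fixture(spec: FixtureSpec) -> Fixture:
    makers = {
        "shell": make_shell,
        "pocket_cage": make_pocket_cage,
        "ligand_in_pocket": make_ligand_in_pocket,
        "two_chain_complex": make_two_chain_complex,
    }
    if spec.kind not in makers:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    return makers[spec.kind](spec)


# ---------------------------------------------------------------------------
# PDB output


def structure_to_pdb_string(structure: MolecularStructure) -> str:
    """Serialize to fixed-column PDB via gemmi (single model, 3-decimal coords)."""
    st = gemmi.Structure()
    st.name = structure.name or "mcdpa"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    current_res: dict[str, tuple] = {}
    for a in structure.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        chain = chains[a.chain_id]
        key = (a.res_seq, a.icode, a.res_name)
        if current_res.get(a.chain_id) != key:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, a.icode or " ")
            res.het_flag = "H" if a.record_kind == "hetero" else "A"
            chain.add_residue(res)
            current_res[a.chain_id] = key
        res = chain[len(chain) - 1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.coords)
        at.occ = a.occupancy
        at.b_iso = 0.0
        if a.altloc:
            at.altloc = a.altloc
        res.add_atom(at)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def write_pdb(structure: MolecularStructure, path) -> Path:
    """Write a structure as PDB; round-trips through read_pdb to 1e-3 A."""
    path = Path(path)
    try:
        path.write_text(structure_to_pdb_string(structure))
    except OSError as exc:
        raise OSError(f"cannot write PDB to {path}: {exc}") from exc
    return path


def write_fixture(fixture: Fixture, pdb_path) -> tuple[Path, Path]:
    """Write fixture PDB plus its JSON ground-truth sidecar."""
    pdb_path = Path(pdb_path)
    write_pdb(fixture.structure, pdb_path)
    json_path = pdb_path.with_suffix(".json")
    json_path.write_text(json.dumps(fixture.ground_truth, indent=2, sort_keys=True) + "\n")
    return pdb_path, json_path
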