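"""Precision/recall formulas, cluster-set comparison and the two change taxonomies."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import mcdpa as m
from mcdpa.clusters import Cluster, ClusterSet
from mcdpa.evaluation import (ClusterChange, LigandChange, PairRecord,
                              best_region_report, change_summary,
                              classify_ligand_change, compare_cluster_sets,
                              precision_recall)
from mcdpa.structure_io import LigandAtoms, RigidTransform


def cluster_of(coords, label="O", dx=None):
    coords = np.asarray(coords, float)
    dx = np.ones(len(coords)) if dx is None else np.asarray(dx, float)
    return Cluster(label=label, member_ids=np.arange(len(coords)),
                   coords=coords, dx_values=dx)


def ligand_of(coords, res_name="LIG", n_res=1):
    coords = np.asarray(coords, float)
    per = max(1, len(coords) // n_res)
    atoms = [(f"C{i+1}", "C", c, res_name, min(i // per, n_res - 1))
             for i, c in enumerate(coords)]
    return LigandAtoms(ligand_id=f"{res_name}_A1", atoms=atoms,
                       residue_names=[res_name] * n_res)


def cluster_set(clusters, provenance="monomer"):
    ordered = sorted(clusters, key=lambda c: -c.mean_dx)
    return ClusterSet(clusters=ordered, provenance=provenance)


class TestPrecisionRecall:
    def test_perfect_overlap(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        res = precision_recall(cluster_of(pts), ligand_of(pts + 0.5))
        assert res.precision == 1.0 and res.recall == 1.0 and res.hit

    def test_distant_zero(self):
        res = precision_recall(cluster_of([[0.0, 0, 0]]),
                               ligand_of([[50.0, 0, 0]]))
        assert res.precision == 0.0 and res.recall == 0.0 and not res.hit

    def test_strict_inequality_at_cutoff(self):
        res = precision_recall(cluster_of([[0.0, 0, 0]]),
                               ligand_of([[3.5, 0, 0]]), r_cutoff=3.5)
        assert res.precision == 0.0  # d == r_cutoff does not count

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(50)
        for _ in range(100):
            C = rng.uniform(0, 15, size=(rng.integers(3, 30), 3))
            L = rng.uniform(0, 15, size=(rng.integers(2, 25), 3))
            r = rng.uniform(1.0, 6.0)
            res = precision_recall(cluster_of(C), ligand_of(L), r)
            c = sum(1 for s in C if min(np.linalg.norm(s - l) for l in L) < r)
            l = sum(1 for x in L if min(np.linalg.norm(x - s) for s in C) < r)
            assert res.precision == pytest.approx(c / len(C))
            assert res.recall == pytest.approx(l / len(L))

    def test_monotone_in_r_cutoff(self):
        rng = np.random.default_rng(51)
        C = rng.uniform(0, 10, size=(15, 3))
        L = rng.uniform(0, 10, size=(10, 3))
        last_p, last_r = -1.0, -1.0
        for r in (1.0, 2.0, 3.5, 5.0, 8.0):
            res = precision_recall(cluster_of(C), ligand_of(L), r)
            assert res.precision >= last_p and res.recall >= last_r
            last_p, last_r = res.precision, res.recall

    def test_empty_cluster_rejected(self):
        empty = Cluster(label="O", member_ids=np.array([], int),
                        coords=np.zeros((0, 3)), dx_values=np.array([]))
        with pytest.raises(ValueError, match="empty"):
            precision_recall(empty, ligand_of([[0.0, 0, 0]]))


class TestBestRegionReport:
    def test_single_pair_equals_precision_recall(self):
        C = np.array([[0.0, 0, 0], [1, 0, 0]])
        L = np.array([[0.5, 0, 0]])
        cs = cluster_set([cluster_of(C)])
        rep = best_region_report(cs, [ligand_of(L)])
        direct = precision_recall(cs.clusters[0], ligand_of(L))
        assert rep[0].precision == direct.precision
        assert rep[0].recall == direct.recall

    def test_overlapping_cluster_selected(self):
        near = cluster_of([[0.0, 0, 0]] * 5, label="P", dx=np.ones(5))
        far = cluster_of([[40.0, 0, 0]] * 5, label="O", dx=np.full(5, 2.0))
        cs = cluster_set([near, far])
        rep = best_region_report(cs, [ligand_of([[1.0, 0, 0]])])
        assert rep[0].cluster_label == "P"
        assert rep[0].hit

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(52)
        clusters = [cluster_of(rng.uniform(0, 20, size=(6, 3)), label=lab)
                    for lab in ("O", "P", "Q")]
        ligands = [ligand_of(rng.uniform(0, 20, size=(5, 3))) for _ in range(2)]
        cs = cluster_set(clusters)
        rep = best_region_report(cs, ligands)
        for lig, got in zip(ligands, rep):
            best = max((precision_recall(cl, lig) for cl in cs.clusters),
                       key=lambda r: (r.recall, r.precision))
            assert (got.recall, got.precision) == (best.recall, best.precision)

    def test_empty_cluster_set_all_miss(self):
        rep = best_region_report(ClusterSet(clusters=[]), [ligand_of([[0.0, 0, 0]])])
        assert rep[0].recall == 0.0 and not rep[0].hit


def blob(center, n=8, seed=0, spread=1.0):
    rng = np.random.default_rng(seed)
    return np.asarray(center, float) + rng.normal(scale=spread, size=(n, 3))


class TestCompareClusterSets:
    def test_identical_sets_unchanged(self):
        pts = blob([0, 0, 0])
        mono = cluster_set([cluster_of(pts, "O")])
        cplx = cluster_set([cluster_of(pts, "O'")], provenance="complex")
        changes = compare_cluster_sets(mono, cplx)
        assert [c.kind for c in changes] == ["unchanged"]

    def test_disjoint_sets_vanished_and_created(self):
        mono = cluster_set([cluster_of(blob([0, 0, 0]), "O")])
        cplx = cluster_set([cluster_of(blob([60, 0, 0]), "O'")], provenance="complex")
        kinds = sorted(c.kind for c in compare_cluster_sets(mono, cplx))
        assert kinds == ["created", "vanished"]

    def test_one_to_two_split(self):
        src = np.vstack([blob([0, 0, 0], seed=1), blob([8, 0, 0], seed=2)])
        mono = cluster_set([cluster_of(src, "O")])
        cplx = cluster_set(
            [cluster_of(blob([0, 0, 0], seed=3), "O'", dx=np.full(8, 2.0)),
             cluster_of(blob([8, 0, 0], seed=4), "P'")], provenance="complex")
        changes = compare_cluster_sets(mono, cplx)
        assert [c.kind for c in changes] == ["split"]
        assert changes[0].sources == ["O"]
        assert sorted(changes[0].targets) == ["O'", "P'"]

    def test_two_to_one_merged(self):
        mono = cluster_set([cluster_of(blob([0, 0, 0], seed=5), "O", dx=np.full(8, 2.0)),
                            cluster_of(blob([8, 0, 0], seed=6), "P")])
        tgt = np.vstack([blob([0, 0, 0], seed=7), blob([8, 0, 0], seed=8)])
        cplx = cluster_set([cluster_of(tgt, "O'")], provenance="complex")
        changes = compare_cluster_sets(mono, cplx)
        assert [c.kind for c in changes] == ["merged"]

    def test_weak_one_to_one_is_shifted(self):
        # small overlap: clusters meet at the edge only
        mono = cluster_set([cluster_of(np.array([[float(x), 0, 0] for x in range(8)]), "O")])
        cplx = cluster_set([cluster_of(np.array([[float(x) + 8.0, 0, 0] for x in range(8)]), "O'")],
                           provenance="complex")
        changes = compare_cluster_sets(mono, cplx)
        assert [c.kind for c in changes] == ["shifted"]

    def test_every_cluster_in_exactly_one_change(self):
        rng = np.random.default_rng(53)
        mono = cluster_set([cluster_of(blob(c, seed=i), lab)
                            for i, (c, lab) in enumerate(
                                [([0, 0, 0], "O"), ([15, 0, 0], "P"), ([40, 0, 0], "Q")])])
        cplx = cluster_set([cluster_of(blob(c, seed=10 + i), lab)
                            for i, (c, lab) in enumerate(
                                [([0, 0, 0], "O'"), ([70, 0, 0], "P'")])], provenance="complex")
        changes = compare_cluster_sets(mono, cplx)
        src = [s for c in changes for s in c.sources]
        tgt = [t for c in changes for t in c.targets]
        assert sorted(src) == ["O", "P", "Q"]
        assert sorted(tgt) == ["O'", "P'"]

    def test_invariant_to_relabeling_and_rigid_transform(self):
        rng = np.random.default_rng(54)
        mono_pts = [blob([0, 0, 0], seed=20), blob([25, 0, 0], seed=21)]
        cplx_pts = [blob([0, 0, 0], seed=22)]
        R = Rotation.random(rng=np.random.default_rng(55)).as_matrix()
        shift = np.array([7.0, -3.0, 11.0])

        mono1 = cluster_set([cluster_of(mono_pts[0], "O", dx=np.full(8, 2.0)),
                             cluster_of(mono_pts[1], "P")])
        cplx1 = cluster_set([cluster_of(cplx_pts[0], "O'")], provenance="complex")
        kinds1 = sorted(c.kind for c in compare_cluster_sets(mono1, cplx1))

        # relabel (swap dx ranks) and rigidly move both sets together
        mono2 = cluster_set([cluster_of(mono_pts[0] @ R.T + shift, "P"),
                             cluster_of(mono_pts[1] @ R.T + shift, "O", dx=np.full(8, 2.0))])
        cplx2 = cluster_set([cluster_of(cplx_pts[0] @ R.T + shift, "O'")],
                            provenance="complex")
        kinds2 = sorted(c.kind for c in compare_cluster_sets(mono2, cplx2))
        assert kinds1 == kinds2

    def test_taxonomy_counts(self):
        changes = [ClusterChange("unchanged", ["O"], ["O'"]),
                   ClusterChange("created", [], ["P'"]),
                   ClusterChange("created", [], ["Q'"])]
        counts = change_summary(changes)
        assert counts["created"] == 2 and counts["unchanged"] == 1


def make_pair(mono_ligs, cplx_ligs):
    import mcdpa.fixtures as fx
    base = fx.make_pocket_cage(m.FixtureSpec(seed=1, n_nodes=60, radius=10.0,
                                             pocket_depth=0.0))
    return PairRecord(monomer=base.structure, complex=base.structure,
                      transform=RigidTransform.identity(),
                      monomer_ligands=mono_ligs, complex_ligands=cplx_ligs)


class TestLigandChange:
    def test_unchanged_small_armsd(self):
        l1 = ligand_of(blob([0, 0, 0], seed=30, spread=2.0))
        l2 = ligand_of(np.asarray(l1.coords_array()) + 0.3)
        ch = classify_ligand_change(make_pair([l1], [l2]))
        assert [c.category for c in ch] == ["unchanged"]
        assert ch[0].armsd.value < 1.0

    def test_shifted_large_armsd(self):
        l1 = ligand_of(blob([0, 0, 0], seed=31, spread=2.0))
        l2 = ligand_of(np.asarray(l1.coords_array()) + np.array([3.0, 0, 0]))
        ch = classify_ligand_change(make_pair([l1], [l2]))
        assert [c.category for c in ch] == ["shifted"]
        assert ch[0].armsd.value == pytest.approx(3.0)

    def test_disappeared(self):
        l1 = ligand_of(blob([0, 0, 0], seed=32))
        ch = classify_ligand_change(make_pair([l1], []))
        assert [c.category for c in ch] == ["disappeared"]

    def test_new_ligand(self):
        l2 = ligand_of(blob([0, 0, 0], seed=33))
        ch = classify_ligand_change(make_pair([], [l2]))
        assert [c.category for c in ch] == ["new_ligand"]

    def test_fused_monomer_to_oligomer(self):
        # one NAG in the monomer, linked tri-NAG at the same site in the complex
        l1 = ligand_of(np.array([[0.0, 0, 0], [1.0, 0, 0]]), res_name="NAG")
        tri = ligand_of(np.array([[0.0, 0, 0], [1.4, 0, 0], [2.8, 0, 0]]),
                        res_name="NAG", n_res=3)
        ch = classify_ligand_change(make_pair([l1], [tri]))
        assert [c.category for c in ch] == ["fused"]

    def test_split_oligomer_to_monomer(self):
        tri = ligand_of(np.array([[0.0, 0, 0], [1.4, 0, 0], [2.8, 0, 0]]),
                        res_name="NAG", n_res=3)
        l2 = ligand_of(np.array([[0.0, 0, 0], [1.0, 0, 0]]), res_name="NAG")
        ch = classify_ligand_change(make_pair([tri], [l2]))
        assert [c.category for c in ch] == ["split"]

    def test_mixed_inventory(self):
        kept = ligand_of(blob([0, 0, 0], seed=34), res_name="ATP")
        kept2 = ligand_of(np.asarray(kept.coords_array()) + 0.2, res_name="ATP")
        lost = ligand_of(blob([30, 0, 0], seed=35), res_name="LAC")
        ch = classify_ligand_change(make_pair([kept, lost], [kept2]))
        cats = sorted(c.category for c in ch)
        assert cats == ["disappeared", "unchanged"]

    def test_no_ligands_error(self):
        with pytest.raises(ValueError, match="no ligands"):
            classify_ligand_change(make_pair([], []))
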