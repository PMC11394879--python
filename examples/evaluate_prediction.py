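"""Score a predicted binding region against a bound ligand.

Precision is the fraction of cluster probes within r_cutoff (3.5 A) of the
ligand; recall is the fraction of ligand atoms within r_cutoff of the
cluster.
"""

import mcdpa as m
from mcdpa.evaluation import best_region_report

fx = m.make_ligand_in_pocket(m.FixtureSpec(seed=0))
ligands = m.extract_ligands(fx.structure)
print(f"planted ligand: {ligands[0].ligand_id} with {ligands[0].n_atoms} atoms")

clusters, _, _ = m.predict_regions(fx.structure, seed=0)
for res in best_region_report(clusters, ligands):
    print(f"best region for {res.ligand_id}: cluster {res.cluster_label}, "
          f"precision {res.precision:.2f}, recall {res.recall:.2f}, "
          f"hit={res.hit}")
# precision < 1 is expected: a cluster wraps the whole pocket mouth while
# the ligand occupies its center; recall near 1 means the ligand is fully
# covered by the predicted region.
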