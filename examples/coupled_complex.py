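"""Predict binding regions on a two-protein complex and vary the PPI strength.

The inter-chain force constant gamma_AB couples the two proteins' dynamics.
gamma_AB = gamma treats interface contacts like intra-protein ones (the
default); gamma_AB = 0 decouples the chains entirely, reproducing the
single-chain predictions.
"""

import numpy as np

import mcdpa as m

fx = m.make_two_chain_complex(
    m.FixtureSpec(kind="two_chain_complex", n_nodes=150, seed=0),
    ligand_site="interface")
print(f"two-chain complex: {fx.structure.n_atoms} atoms, "
      f"{fx.ground_truth['n_cross_pairs']} interface contact pairs")

for gamma_AB in (None, 0.5, 0.0):  # None -> equal to gamma
    label = "gamma" if gamma_AB is None else f"{gamma_AB:g}"
    cs, probes, prof = m.predict_regions(
        fx.structure, chain_groups=[{"A"}, {"B"}], gamma_AB=gamma_AB, seed=0)
    tops = ", ".join(f"{c.label}({c.n_points}p, {c.mean_dx:.3f})"
                     for c in cs.clusters[:3])
    print(f"gamma_AB = {label:>5s}: {cs.n_clusters} clusters; top: {tops}")
# Primed labels (O', P', ...) mark complex-based predictions.  Weakening the
# interface coupling changes which regions perturb the joint ensemble most,
# and gamma_AB = 0 falls back to the union of the monomer predictions.
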