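# mcdpa

Multi-chain dynamics-perturbation analysis (mcDPA): prediction of
small-molecule binding regions on proteins and protein–protein complexes
from coarse-grained elastic-network dynamics, and quantification of how a
protein–protein interaction (PPI) reshapes ligand binding.

## Who this is for

Structural bioinformaticians studying ligand–protein interactions in the
context of protein–protein complexes: where does a small molecule bind a
protein *A* alone, where does it bind once *A* is part of a complex *B–A*,
and how do the two answers differ (pocket kept, shifted, destroyed,
created, fused or split)?

## The method

A structure is coarse-grained to one node per residue (CA) and turned into
an anisotropic elastic network: every node pair within a cutoff (13 Å) is
connected by a Hookean spring of force constant γ built at its equilibrium
length.  A complex adds an interface term

    V_AB = ½ Σ_{i∈A, j∈B} γ_AB (r_ij − r_ij⁰)²

over cross-interface node pairs; γ_AB = γ by default (interface contacts as
stiff as intra-protein ones) and is an adjustable knob for PPI strength.

The harmonic conformational ensemble is the zero-mean Gaussian with
precision matrix equal to the Hessian **H** restricted to internal
(non-rigid) motions.  Surface *test points* are sampled on layers (4 and
6 Å) around the body; each probe *s*, held fixed, attaches springs (γ_s) to
all nodes within r_int = 6 Å, adding a low-rank increment ΔH.  The probe's
*dynamic perturbation value* is the Kullback–Leibler divergence of the
perturbed ensemble from the native one,

    D_x = ½ [ tr(H H′⁻¹) − r + ln(det H′ / det H) ],   H′ = H + ΔH,  r = 3N − 6,

evaluated on the non-rigid subspace (equivalently ½ Σ_i [ln(1+g_i) −
g_i/(1+g_i)] over the eigenvalues g_i of the m×m core BᵀH⁺B).  Probes in
deep, narrow pockets engage many nodes and perturb the ensemble most, so
the top decile of D_x, grouped by single-linkage clustering (3.5 Å),
predicts the binding regions — labeled O, P, Q, … by descending mean D_x
(primed labels O′, P′, … for complex-based predictions).

Predictions are scored against a bound ligand L with overlap precision and
recall at r_cutoff = 3.5 Å (P = |c|/|C|, R = |l|/|L|); monomer- and
complex-based cluster sets are compared the same way after superposing the
shared protein (Kabsch), yielding a six-way cluster-change taxonomy, and
ligand inventories are classified six ways with ligand ARMSD (1 Å
guideline separating unchanged from shifted poses).

## Worked example

```sh
python examples/predict_pocket.py
```

builds a solid pseudo-protein (292 residues) with a pocket carved 8 Å deep
and prints:

```
structure: 292 pseudo-residues, 944 surface probes
D_x (nats): min 0.0000  median 0.0017  max 0.0083

predicted binding regions (descending mean D_x):
  cluster O:  15 probes, mean D_x 0.0060, centroid [ 0.4  0.9 13.3], 1.0 A from the true pocket center
  cluster P:   6 probes, mean D_x 0.0048, centroid [-11.4   9.2  12.1], 14.7 A from the true pocket center
```

Cluster O — the strongest perturbation region — sits 1 Å from the known
cavity center: the dynamics of the network alone localize the pocket.
Other examples cover complex prediction under varying γ_AB
(`coupled_complex.py`), precision/recall scoring
(`evaluate_prediction.py`), the PPI change taxonomies
(`ppi_induced_changes.py`) and ligand ARMSD (`ligand_armsd.py`).

The same pipeline is scriptable from a shell:

```sh
mcdpa fixture --kind ligand_in_pocket -o lig.pdb
mcdpa predict lig.pdb --chains A --seed 1 -o pred     # writes pred.pdb + pred.json
mcdpa evaluate pred.pdb lig.pdb
mcdpa armsd monomer.pdb complex.pdb --shared-chain A:X
mcdpa compare pred_mono.pdb pred_cplx.pdb monomer.pdb complex.pdb --shared-chain A:X
```

For real structures, `scripts/fetch_benchmark.py` (network required)
downloads example monomer/complex pairs and
`examples/benchmark_pairs.py` reports their ligand ARMSD table; the
library itself never downloads.

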