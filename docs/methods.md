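# Methods

## Model

mcdpa models a protein (or a protein–protein complex) as an anisotropic
elastic network over coarse-grained nodes.  Two coarse-graining schemes
exist: `calpha` (one node per residue at its CA position; the default and
the resolution every default parameter is calibrated for) and `heavy_atom`
(all non-hydrogen polymer atoms, for small systems).  Nodes closer than a
contact cutoff are joined by springs built at their current separation, so
the input conformation is the exact energy minimum: the harmonic ensemble
is a zero-mean Gaussian over displacements whose precision matrix is the
Hessian of the spring energy.  For a complex, intra-protein springs carry
the force constant γ and cross-interface springs carry γ_AB
(V_AB = ½ Σ γ_AB (r_ij − r_ij⁰)²); with γ_AB = γ the coupled network is
*identical* to one built over the union of chains, a contract the tests
enforce exactly, and γ_AB is exposed as the knob for PPI strength.

Assumptions worth stating: harmonic dynamics about a single minimum (no
anharmonicity, no conformational switching); uniform spring constants (no
distance weighting, no sequence specificity); a rigid input structure
(the method asks what the *given* geometry's dynamics imply, it does not
relax or dock).

## Probe perturbation and D_x

Surface test points are sampled on spherical layers (default offsets 4 and
6 Å) around every node; a candidate survives only if its nearest-node
distance stays within ±0.5 Å of its layer offset — which rejects points
buried inside the body — and if it keeps ≥ 2 Å to previously accepted
points (greedy Poisson-disk thinning in seeded candidate order).  The probe
set is therefore a pure function of structure, parameters and seed, and
regeneration is bit-identical.

A probe is held fixed in space (it adds no degrees of freedom) and attaches
springs of constant γ_s, at equilibrium length, to every node within
r_int = 6 Å.  Because the springs are at equilibrium the perturbation
shifts no mean; it adds a positive semidefinite, rank-m increment
ΔH = Σ_k γ_s d̂_k d̂_kᵀ (one 3×3 diagonal block per attached node k, d̂_k the
probe→node unit vector).  The probe's dynamic perturbation value is the KL
divergence of the perturbed from the native ensemble, restricted to the
non-rigid subspace:

    D_x = ½ [ tr(H̃ H̃′⁻¹) − r + ln(det H̃′ / det H̃) ]

with H̃, H̃′ the two Hessians projected off the rigid modes and r the
internal dimension.  The direction — perturbed relative to native — is
fixed project-wide and recorded in output metadata; it measures the change
the probe *induces* in the native ensemble.  Writing G = BᵀH⁺B (ΔH = BBᵀ,
H⁺ the pseudo-inverse) the divergence reduces to
½ Σ_i [ln(1+g_i) − g_i/(1+g_i)] over the eigenvalues g_i ≥ 0 of the m×m
core G, which is the production path (one shared eigendecomposition of H,
then an m×m problem per probe).  A dense evaluation of the projected
formula is kept alongside and the two must agree to 1e-8 relative; a
Monte-Carlo estimate from samples of the two Gaussians serves as a third,
formula-independent oracle in the tests.

Temperature is set to 1 throughout: the KL divergence of two zero-mean
Gaussians with precision matrices βH and βH′ is β-independent, so D_x
depends only on force-constant *ratios* (γ_s/γ, γ_AB/γ).  The tests assert
this invariance under joint rescaling to 1e-8.

Zero-mode handling: both matrices are projected onto the *unperturbed*
network's non-rigid subspace, even though ΔH formally breaks translational
invariance.  This keeps every divergence finite and comparable across
probes.  Generic 3-D geometry has exactly 6 rigid modes; collinear node
sets (a single spring) have 5, and the assembly routine derives the
expected count from the rank of the analytic translation/rotation
generators and asserts the spectrum matches — a silent miscount would
corrupt every pseudo-determinant downstream.

## Prediction and evaluation

Probes in the top decile of D_x (threshold = k-th largest value,
k = ⌈0.1·P⌉, ties included — deterministic and scale-free under the γ
invariance) are grouped by single-linkage connected components at 3.5 Å,
the same spatial scale as the overlap cutoff below; components under 5
points are discarded as noise.  Clusters are ranked by mean D_x and
labeled O, P, Q, … (complex-based predictions get primed labels); ties
break toward the larger cluster, then the lexicographically smaller
centroid, so labeling is permutation-stable.

Precision/recall against a ligand L uses strict inequality at
r_cutoff = 3.5 Å: P is the fraction of cluster points with distance to L
below the cutoff, R the fraction of ligand atoms with distance to the
cluster below it.  Per-ligand reports pick the cluster maximizing recall
(ties: precision, then label order), plus a hit flag (≥ 1 ligand atom
covered).

Monomer- vs complex-based cluster sets are compared after superposing the
shared protein: overlap fractions are computed both ways for every pair,
a link exists when either fraction reaches 0.2, and link-graph components
are decomposed greedily (descending overlap, keeping groups star-shaped)
into unchanged (1–1, both fractions ≥ 0.5), shifted (1–1 below),
split (1–many), merged (many–1), vanished and created.  The 0.2/0.5
thresholds are configuration: the taxonomy itself is qualitative and no
numeric rule accompanies it, so 0.5 mirrors the ≥ 50 % overlap convention
used for prediction hits and 0.2 is a deliberately permissive link floor.
Ligand inventories are classified analogously: entities matched by shared
residue name and centroid proximity (≤ 8 Å after superposition), 1–1
matches classified by ARMSD against the 1 Å guideline, one-sided entities
as disappeared/new, and entity- or residue-count asymmetries as fused
(toward the complex oligomer) or split.

Ligand ARMSD pairs atoms by PDB atom name (residue-wise within matched
oligomer members); unmatched atoms are excluded and listed.  For
chemically different ligands in the same pocket a center-of-mass mode
reports the distance between mass centroids instead.  Superposition is a
proper Kabsch fit (no reflections) on CA nodes matched by residue number
of the shared chain; duplicate residue numbers are dropped from the
correspondence.

## Structure I/O conventions

PDB parsing and writing go through gemmi.  Only the first model is read;
alternate locations resolve to the highest occupancy (ties: first in
file); waters are kept but flagged; malformed ATOM/HETATM lines are
skipped with a logged count.  Ligand extraction drops waters and common
monoatomic ions, then merges covalently linked hetero residues of one
chain (closest inter-residue atom distance < 1.9 Å, covering glycosidic
and phosphodiester links without bridging packing contacts) into one
oligomeric entity — the poly-NAG case.

## Synthetic fixtures

The toy structures are CA-only pseudo-proteins: chemistry is irrelevant to
the dynamics core, so residues are all glycine.  The pocket cage is a
*solid* quasi-uniform ball (concentric Fibonacci-spiral shells 4 Å apart —
about CA–CA density — ~300 nodes, radius 16 Å, 0.25 Å seeded jitter) with
the pocket carved as a 5 Å spherical void whose bottom lies 8 Å below the
surface and whose mouth opens through it.  A filled interior is essential:
the surface band test can only reject buried probe candidates if the body
has an interior, as a real protein does.  The two-chain complex is two
such balls (chains A and B) with facing caps a configurable gap apart
(default 5 Å, well inside the 13 Å cutoff, giving tens of interface
pairs), optionally with a small planted hetero ligand at the interface or
at a distal site.  Ground truth (cavity center, interface pair count,
ligand site) travels as a JSON sidecar.

What the fixtures emulate: a deep, narrow, distinct cavity versus convex
surface at realistic node density, and a defined protein–protein
interface.  What they do not: real packing heterogeneity, surface
roughness, chain connectivity constraints, side-chain chemistry and
flexible loops.  Passing tests therefore demonstrate that the *mechanism*
(pocket geometry → many probe contacts → large ensemble perturbation)
works and that every formula is implemented correctly — not that
prediction accuracy on real proteins matches any benchmark figure.

## Numerical choices

- Dense eigendecomposition of the 3N×3N Hessian, reused across all probes
  of a structure; practical to roughly 3N ≈ 6000.  Per-probe work is an
  m×m eigenproblem (m = 3·attached nodes at most, typically ≤ ~30).
- Rigid-mode threshold: 1e-8 relative to the largest eigenvalue, with the
  expected count asserted (see above) and a ≥ 0.99 overlap check against
  analytic generators.
- Low-rank core eigenvalues are clipped at 0 before the KL sum (they are
  non-negative analytically; clipping removes −1e-16 round-off).
- Degenerate inputs fail loudly: disconnected networks, mirror-only
  superpositions, collinear correspondences, empty clusters in
  precision, and zero-atom structures all raise typed errors.
- The γ_AB = 0 limit decouples the chains, which would leave a single
  joint network with 12 rigid modes; prediction therefore runs each chain
  group as its own connected network and merges the resulting cluster
  sets — exactly the union of single-chain predictions under a shared
  seed, which the tests assert coordinate-exactly.

## Problem sizes

Default runs use ~300-node fixtures (~900 internal modes, ~1000 probes),
chosen so a full prediction completes in about a second and the whole
validation battery (including ten-seed discrimination runs and 2×10⁵-sample
Monte-Carlo KL checks) in well under a minute — ample for the toy-scale
regime where the oracles are exact.  Larger real structures run with the
same code path; only the dense eigendecomposition bounds practical size.

## Known limitations

- Uniform-γ harmonic dynamics cannot capture chemistry-specific binding
  (the known weakness on shallow, wide carbohydrate sites applies here
  too: such regions perturb the ensemble weakly).
- The probe is fixed in space; a mobile probe (3 extra degrees of
  freedom) is a plausible variant not recoverable from the method
  description and out of scope.
- Residue-number correspondence for superposition assumes consistent
  numbering of the shared protein across the two structures; no sequence
  alignment is attempted.
- Single-model PDB input only; no mmCIF, no symmetry expansion.
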