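# Methods

## The model

`rotamrf` treats side-chain assignment as marginal inference in a pairwise
Markov random field. The backbone is observed; each residue *i* is a discrete
random variable X_i ranging over the candidate rotamers that the input
backbone-dependent library lists for the residue's amino acid at its (φ, ψ)
bin. The joint distribution is the normalized product of vertex potentials
ψ_i(x_i) = exp(−E_i(x_i)/k_BT) and edge potentials
ψ_ij(x_i, x_j) = exp(−E_ij(x_i, x_j)/k_BT) over the edges of a residue
interaction graph. The deliverable is the set of per-residue marginals, not a
jointly consistent packing: thresholding each marginal to its top rotamer may
contain atomic clashes, by design — the intended consumer is a global search
algorithm that takes the re-ranked library as its prior.

### Interaction graph

Vertices are residues; an edge joins *i* and *j* when the minimum distance
over all Cα/Cβ/carbonyl-O cross-pairs is strictly below the contact threshold
(default 10 Å). Glycine contributes only Cα and O (no Cβ exists; a virtual-Cβ
variant was considered and rejected to keep the rule a function of observed
atoms only). Strictness at the boundary is deliberate and tested, so results
are reproducible to the last edge. Topology never depends on rotamers.

### Energies

* **Prior term.** k_d · ln(p(r_imax)/p(r_ij)) with k_d = 3.0: zero for the
  bin's most probable rotamer and increasing as the prior falls, giving
  well-populated rotamers an energetic head start. Priors are floored at 1e-6
  before the logarithm so zero-probability records stay finite; the floor is
  far below any prior that affects ranking.
* **Repulsive clash term.** The piecewise-linear approximation of the
  repulsive flank of the Lennard-Jones 12-6 potential: with r_ab = r_a + r_b,
  the energy is 0 for d ≥ r_ab, E_max = 10 for d ≤ k_sc·r_ab (k_sc = 0.8254),
  and linear between. Interaction radii are element-class defaults
  (C 1.60, N 1.30, O 1.30, S 1.70 Å) shipped in
  `src/rotamrf/data/atom_radii.tsv` and overridable through `EnergyParams`;
  the vertex term scores a rotamer's side-chain atoms against every graph
  neighbour's N/Cα/C/O/Cβ frame (Cβ counted as pseudo-backbone, as common
  SCWRL practice), the edge term scores side chain against side chain.
  1–2/1–3 bonded pairs never arise because intra-residue pairs are not
  scored.
* **Hydrogen-bond term.** A deliberately simple side-chain-mediated reward:
  for each donor/acceptor heavy-atom pair (standard donor and acceptor sets
  per amino acid), a Gaussian well of depth `weight` (default −2.0 kcal/mol)
  around `distance_opt` (2.8 Å, width 0.3 Å), gated by requiring the
  antecedent–donor–acceptor angle to exceed 90°. Backbone–backbone hydrogen
  bonds are omitted: the backbone is fixed, so they would add the same
  constant to every state and cannot move a marginal. The term is pluggable
  and can be disabled (`--no-hbond`); a full orientation-dependent polynomial
  model could be substituted behind the same interface.
* **Temperature.** k_BT = 0.6 kcal/mol converts energies to potentials.
  Within each vertex vector and edge matrix, energies are shifted by their
  minimum before exponentiation. This is a pure rescaling of the potential —
  marginals are provably invariant (and the invariance is tested end-to-end)
  — and prevents exp(−E/k_BT) from underflowing when many atom pairs clash.

### Side-chain construction

The library stores χ means, not coordinates, so candidate side chains are
rebuilt by sequential internal-coordinate (NeRF) placement: each heavy atom
is positioned from three previously placed atoms using an ideal bond length,
bond angle, and a torsion that is either a χ angle, a fixed offset from a χ
shared-axis partner (branch atoms such as ASP OD2 or VAL CG2), or an absolute
ideal torsion (ring closures). The numeric table
(`src/rotamrf/data/sidechain_geometry.tsv`) was measured once from Chemical
Component Dictionary ideal residue templates by
`scripts/make_geometry_table.py` and is versioned in the repository; the
construction round-trips χ to well below 1e-4° for every residue type.
Hydrogens are never built; all terms operate on heavy atoms.

## Inference

All four algorithms share the conventions: messages/beliefs normalized to
sum to 1 after every update, asynchronous sweeps in a fixed (input) order by
default with an optional seeded random permutation, uniform message
initialization by default with a seeded random option, convergence declared
when the L∞ change of all beliefs between successive sweeps drops below the
tolerance (default 1e-6), and an iteration cap of 100 sweeps. Hitting the cap
is a reported state (`converged=False` plus the residual trace), never an
error. Optional damping in [0, 1) is available as a safeguard for
oscillation and is off by default.

* **LBP** — standard sum-product: m_ij(x_j) ∝ Σ_xi ψ_i ψ_ij Π_{k∈N(i)∖j}
  m_ki; belief b_i ∝ ψ_i Π_k m_ki. Exact on trees (verified against the
  enumeration oracle to 1e-8 over hundreds of random tree models).
* **Mean field** — coordinate ascent on the fully factorized approximation,
  b_i ∝ ψ_i exp(Σ_j Σ_xj b_j(x_j) ln ψ_ij); exact when the graph has no
  edges.
* **TRBP** — tree-reweighted sum-product with edge-appearance probabilities
  ρ_ij: edge potentials enter as ψ_ij^{1/ρ_ij}, incoming messages as
  m_ki^{ρ_ki}, and the reverse message divides as m_ji^{1−ρ_ij}. ρ is
  computed exactly per connected component via the matrix-tree theorem —
  the fraction of spanning trees containing an edge equals its effective
  resistance, read off the Laplacian pseudoinverse — and equals 1 on bridges
  and trees. With all ρ = 1 the update is algebraically identical to LBP,
  and the implementation reproduces this to below 1e-10 on every fixture.
* **GBP** — the region construction is the one genuinely open design choice,
  and the smallest enrichment beyond the Bethe approximation was chosen:
  every triangle of the interaction graph becomes one outer region (factor)
  over its three vertices, holding the product of those of its edge
  potentials not already claimed by an earlier triangle; leftover edges stay
  pairwise factors. Each edge potential enters exactly one factor, so the
  counting of every vertex and edge is exact and the factorization is an
  exact rewrite of the pairwise model. Standard factor-graph sum-product then
  runs on these regions. On triangle-free graphs this reduces to the
  Bethe/LBP factorization; on a single triangle the factor graph is acyclic
  and the result exact. Triangle tensors scale as (states)³, which is
  memory-heavy for residues with very large candidate lists.
* **Exact oracle** — materializes the joint tensor (refusing above 10⁷
  configurations), the only place the normalizer Z is computed. It serves as
  the test oracle for all approximate algorithms and is never used in the
  pipeline.

## Output

Re-ranking sorts each residue's candidates by marginal probability with a
stable sort, so exact ties preserve the prior order; the protein-dependent
library is written in the input dialect plus a leading residue-index column,
with a header recording algorithm, convergence, parameters and a parameter
hash. Identical configuration and seed give byte-identical output.

## Evaluation

A predicted χ is correct when its wrap-around distance to the true angle is
strictly under 40°; χ1+2 requires both χ1 and χ2 correct, and so on
cumulatively. ALA/GLY are excluded; overall rows are residue-weighted. The
ranking metrics are the mean 1-based rank of the first correct rotamer
(residues with no correct rotamer anywhere are excluded and counted
separately) and the mean probability mass on correct rotamers within the top
k entries. True χ angles are measured from the full-atom PDB with the same
dihedral routine used everywhere else. 180°-symmetric end groups (ASP χ2,
GLU χ3, PHE/TYR χ2, ARG χ4) are *not* folded by default — folding materially
changes accuracies, so it is an explicit opt-in flag that is reported in the
output.

## Synthetic data

The fixture generators target correctness, not PDB realism:

* **Backbones** are ideal-geometry chains (helix φ=−57°, ψ=−47°; extended
  φ=−139°, ψ=135°; or helix plus seeded Gaussian coordinate noise,
  σ = 0.05 Å by default). They have no loops, no chain breaks, no altlocs,
  and uniform secondary structure, so parsing edge cases are exercised by
  dedicated mutated fixtures instead.
* **Libraries** draw per-bin priors from a symmetric Dirichlet
  (concentration 5 — moderately peaked, like real bins) and χ means near the
  canonical −60°/60°/180° classes with 8° jitter, χ1 classes distinct within
  a bin.
* **Ground-truth bundles** place every side chain on a known library rotamer:
  either the top-prior rotamer (then a prior-preserving pipeline must score
  100 %) or the rotamer minimizing the backbone-clash vertex energy (then
  clash-aware inference can beat the raw priors, and measurably does). This
  gives the evaluation metrics known optima.

Passing on these fixtures demonstrates the machinery is self-consistent —
planted rotamers are recovered, oracles agree, reductions hold — but says
nothing quantitative about accuracy on experimental structures, which
depends on real rotamer statistics, dense packing, long-range contacts and
library quality. Full-scale runs on user-supplied PDBs and Dunbrack
2002/2010 files are supported (a 150-residue chain builds in ~1 s on one
CPU) but are not benchmarked here; no published accuracy figure is asserted
by the test suite.

## Problem sizes and numerical choices

The shipped checks use 20-residue fixture proteins (20 per benchmark batch),
100 random tree models of 3–8 vertices and 2–4 states, and enumeration-sized
toy graphs; these sizes make every oracle comparison exact and keep the whole
suite in seconds. Tolerances: BP convergence 1e-6 (tests tighten to 1e-12
when comparing fixed points), tree-oracle agreement 1e-8, TRBP→LBP reduction
1e-10, probability normalization 1e-9. Ties in ranking break toward the
prior order; bin lookup is nearest-bin with angular wrap-around (no
interpolation, keeping the bin's top prior well-defined); termini with
undefined φ/ψ fall back to the amino acid's marginal over all bins and are
flagged.

## Known limitations

* No attractive Lennard-Jones, solvation, electrostatics, or disulfide term
  (CYS pairs are scored like any other residue).
* The hydrogen-bond surrogate is distance/angle-gated only; it ignores
  hybridization-dependent orientation preferences.
* PRO ring closure is not enforced when rebuilding side chains (χ1/χ2 are
  placed from ideal geometry; the Cδ–N bond is not re-checked).
* The 2010 library's continuous/non-rotameric χ densities are ignored beyond
  means and probabilities.
* Single model, standard residues only; ligands and nucleic acids are
  skipped.
* ω is computed and reported but consumed by nothing downstream.
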