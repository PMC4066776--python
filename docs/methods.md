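# Methods

This note documents the models and procedures implemented in
`dockconsensus`, the defaults they ship with, what the synthetic data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## The consensus-docking procedure

The pipeline re-enacts an integrative docking analysis in which a complex
is modelled by several independent sampling/scoring methods and the
agreement between them is used as the reliability signal.

**Rigid-body track.** For each scoring method the `top_n` best-scored
decoys (default 1000) are clustered on their mutual ligand RMSD with the
greedy largest-neighborhood algorithm at a 7.5 Å cutoff. A decoy's
neighbors are all decoys within the cutoff (inclusive); at every step the
remaining decoy with the most remaining neighbors is extracted together
with those neighbors as the next cluster. Ties in neighbor count go to the
lowest decoy index, which makes the procedure deterministic and
order-stable. Cluster order is extraction order; sizes are usually but not
necessarily non-increasing, and nothing downstream assumes they are.

**Guided track.** Emulating a restraint-guided protocol whose refined
ensemble is much smaller, the best `refine_n` decoys (default 200) are
clustered on mutual interface RMSD at 3.0 Å. The interface zone is
asymmetric between two decoys (each defines its own zone), so the two
directed values are averaged; a pair with no interface anywhere receives
an infinite sentinel and simply never becomes a neighbor.

**Representatives and the triad filter.** Each cluster's representative is
its best-scoring member (ties: earliest member). Every representative is
then tested against the triad constraint: at least `min_required` of the
named triad residues (default: the acidic triad E235/D243/E265 with
2-of-3) must have a heavy atom within 5.0 Å of the partner. Both 2-of-3
and 3-of-3 verdicts are reported because the source analysis states the
constraint without a count. A run in which no representative passes is a
named outcome, not an error.

**Cross-method consensus.** All representative pairs across two methods
are compared by direction-averaged interface RMSD; pairs within the
consensus threshold (default 3.0 Å, matching the guided clustering
threshold) are reported ranked by combined cluster size, then mean cluster
rank, then RMSD. Only representatives are compared — mirroring the
original representative-versus-best-model comparison — and the top pair's
representative is handed to interface characterization.

**Interface characterization.** Buried area per residue is
SASA(isolated partner) − SASA(in complex), clipped at zero; anchors are
the top-k residues by buried area per partner. Salt bridges are
carboxylate-oxygen / guanidinium-amino-nitrogen pairs (Asp OD1/OD2,
Glu OE1/OE2 vs Lys NZ, Arg NH1/NH2/NE) within 4.0 Å; histidine is treated
as neutral throughout. Apolar contacts are C–C and C–S cross-pairs within
4.5 Å. With no hydrogens, hydrogen bonds are reported only as
donor/acceptor heavy-atom candidates (N/O–N/O within 3.5 Å, no angular
term). For a two-chain (homodimeric) receptor, the second-site clash test
superposes monomer A onto monomer B, applies that transform to the ligand
pose and counts heavy-atom pairs closer than 2.5 Å to the receptor or the
first ligand; more than 50 such pairs (configurable) is reported as a
clash — the situation that argues for a 2:1 stoichiometry.

## Geometry conventions

- Ligand RMSD defaults to ligand CA atoms after a receptor CA fit;
  interface RMSD defaults to backbone (N, CA, C, O) atoms of the 10 Å
  heavy-atom interface zone defined on the reference. The atom sets for
  the rigid-body track are a convention, not a published prescription, so
  both are configurable; on the synthetic suite the CA and backbone
  presets track each other closely because the partners are rigid.
- Superposition uses the SVD-based least-squares fit with the reflection
  correction, so a proper rotation is always returned; mirror-image
  inputs keep a positive residual instead of being "solved" by a flip.
- SASA is Shrake–Rupley with element-based van der Waals radii, probe
  1.4 Å, 960 quadrature points (≈2% accuracy on an isolated sphere, ~1%
  rotational variation). Relative accessibility divides per-residue area
  by Gly-X-Gly extended-state reference values. All distance-based
  operations use heavy atoms only; hydrogens, if present in the input,
  are carried but ignored.

## Restraints

Each active residue defines one ambiguous restraint whose effective
distance to the union of active and passive residues of the partner is
`(Σ pairs d⁻⁶)^(−1/6)` over heavy-atom pairs — a soft minimum, always at
or below the closest single pair. The satisfaction cutoff defaults to
3.0 Å on heavy atoms: the common hydrogen-inclusive 2 Å convention is not
applicable because hydrogens are out of scope here. Passive residues are
the solvent-accessible neighbors of active residues (relative
accessibility ≥ 0.40 within 6.5 Å by default; both values are package
choices, configurable). Random discard removes ⌊fraction × n_active⌋
active restraints (default 50%), uniformly and deterministically per
seed; passive residues define targets, not restraints, and are never
discarded. The published DprA/RecA active and passive lists ship as
module constants and as the pipeline defaults.

## Conservation

Per-column conservation is the Jensen–Shannon divergence (base-2)
between the column's amino-acid distribution (gaps excluded; columns more
than 50% gapped are masked) and a background distribution, divided by the
largest divergence any invariant column can achieve against that
background. The default background is uniform: under it the scale is
exactly calibrated — every invariant column scores 1 and a column
indistinguishable from uniform scores 0 — which is what the test suite
and patch thresholds rely on. Robinson–Robinson natural frequencies are
available through the same parameter for analyses that prefer an
abundance-weighted notion of surprise; scores then remain in [0, 1] but
invariant columns of common residues score slightly below 1. This
internal score replaces phylogeny-aware rate estimation (a deliberate
substitution; only ordinal statements — which positions are most
conserved — are ever asserted). Sequences are unweighted by default, as
for alignments pre-filtered to a 35–90% identity band; inverse-redundancy
weighting was considered and left out as out of proportion for that
input class.

Surface patches are detected by selecting exposed residues (relative
accessibility ≥ 0.25 by default) that pass a conservation threshold or
carry the requested charge (D/E acidic, K/R basic), then single-linkage
clustering their side-chain tip atoms (fixed tip table, CB fallback,
CA for glycine) at an 8 Å linkage cutoff.

## The synthetic data generator

The generator exists so that every stage of the pipeline — including the
end-to-end consensus recovery — can be tested against planted ground
truth with no external structures.

**Toy complex.** Two rigid α-helical poly-alanine partners face each
other 12 Å apart; the receptor is doubled into an exact two-fold
homodimer by default. An acidic triad (Glu/Asp/Glu at positions 8/15/19)
pairs with a basic triad (Arg/Arg/Lys) on the ligand, and a Met/Phe
anchor pair sits between them at position 12. Side-chain geometry is
deliberately idealised rather than chemical: planted side chains are laid
along the inter-CB axis with the contact atoms placed exactly —
salt-bridge oxygens and nitrogens at 3.2 Å (carboxylates bidentate, so
each planted pair carries two short bridges and survives near-native
pose jitter), the Phe ring as a flat hexagon leaning into the Met arm
with a minimum C–C distance of 3.75 Å. Both helices bow away from each
other towards their termini (quadratic, 4 Å at the ends) so that a
~2 Å-error pose cannot plunge a terminal residue into the partner and
out-bury the anchor. The builder audits itself: if any cross-partner
atom pair falls below the planted-contact floor, construction fails
rather than emit a geometry whose ground truth is wrong. What this toy
does **not** emulate: side-chain flexibility, realistic packing,
electrostatics, or any energetics — passing tests demonstrate the
pipeline's bookkeeping and geometric contracts, not docking accuracy on
real proteins.

**Decoy ladder.** Poses mix a rotation about the ligand centroid with a
translation; because the rotation is centroid-centred the two
contributions add exactly in quadrature, so each rung's requested
ligand-CA RMSD is realised essentially exactly (the rotation angle is
solved by bisection; if a rung exceeds the reachable rotational RMSD the
budget moves to translation). Background poses combine a uniform random
rotation with a translation onto a 30 Å shell. True pose errors are
returned separately from the decoy set and never leak into pipeline
inputs.

**Scores.** A pseudo-method score is
`c · z(true error) + (1 − c) · ε` with `ε` standard normal and `c` the
correlation strength; at the study setting `c = 0.8` two methods' top-50
sets overlap far above the hypergeometric expectation, while `c = 0`
gives rank correlation ≈ 0.

**MSAs.** A random query is copied with exact per-sequence substitution
counts on non-conserved positions; per-sequence divergence levels are
drawn so that realised pairwise identities stay inside the requested band
(default 0.35–0.90 for 99 sequences). Planted conserved columns are
invariant and therefore score exactly 1.

## Validation scale and determinism

The end-to-end validation scenario uses 2000 decoys (rungs of 1, 2, 5,
10, 20 Å × 300 plus 500 random poses), two pseudo-methods at correlation
0.8, and the study defaults (top 1000 at 7.5 Å; 200 refined at 3.0 Å) —
a desk-scale stand-in for ensembles of tens of thousands, chosen so the
whole suite completes in minutes on one core; the full published scale
remains reachable by configuration. Every stochastic component takes an
explicit seed, generators are pure functions of spec + seed, and the
workflow summary serialises to byte-identical JSON across reruns.

## Known limitations

- Interface-RMSD clustering is O(n²) pairwise superpositions; the guided
  track's `refine_n` keeps this tractable, and the rigid track's mutual
  ligand RMSD exploits the shared receptor to avoid fitting entirely.
- At poses ~2 Å from the bound reference the planted salt bridges sit
  0.8 Å from the 4.0 Å detection cutoff, so individual bridges can drop
  out of the report for unlucky pose directions; the bidentate planting
  keeps at least three detectable bridges in the overwhelming majority
  of near-native representatives.
- Symmetry handling is limited to the two-chain homodimer case required
  by the second-site test; no general crystallographic symmetry.
- Homo-oligomer-aware (symmetry-corrected) RMSD is not implemented; decoy
  ensembles are assumed to be poses of a single distinguishable ligand.
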