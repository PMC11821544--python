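# Methods

## The model

`pseudocage` implements the generative geometry and analysis tooling for a
family of pseudosymmetric protein nanocages built hierarchically from C3
trimers.  The cages are class-I Goldberg polyhedra: for a lattice parameter
h (a positive integer), the triangulation number is T = h² (k = 0), and a
cage contains 20·T trimers / 60·T protein chains.  Trimers occupy the
vertices of the Goldberg polyhedron GP(h, 0) — equivalently, the centroids
of the h² small triangles obtained by subdividing each of the 20 icosahedral
faces — and every chain pairs with exactly one chain of a neighbouring
trimer across a Goldberg edge, producing a wireframe of 12 pentagonal and
10(T − 1) hexagonal pores.

The subdivision combinatorics fix the component inventory:

| component | site class | count |
|---|---|---|
| AAB heterotrimer | pentasymmetron (5 per five-fold vertex) | 60 |
| ABB heterotrimer | disymmetron (pairs across icosahedral edges) | 60(h − 2) |
| BBB homotrimer | facet, "upward" sublattice | 10(h − 2)(h − 3) |
| CCC homotrimer | facet, "downward" sublattice | 10h(h − 1) |

Inter-trimer edges that cross an icosahedral edge carry the inherited
two-fold A:A interface (60 + 30(h − 2) of them); all intra-face edges join
the two orientation colour classes of the honeycomb and carry the designed
B:C interface (30h(h − 1)).  These closed forms are validated in the test
suite against direct counts on generated layouts for h = 2..10, since the
larger-h instances are otherwise only available graphically.

## Frame and operator conventions

The icosahedral rotation group (60 proper rotations; no improper
operations — the cages are chiral) is generated by closure from a five-fold
and a two-fold generator in the "I" frame: two-fold axes along the Cartesian
axes, vertices at cyclic permutations of (0, ±1, ±φ).  Operators are ordered
deterministically (identity first, then by axis class, canonical axis
direction, and signed rotation angle) so chain naming and asymmetric-unit
extraction are bit-reproducible.  Construction tolerances are 1e-9;
membership/equality tests use 1e-6 (double-precision products accumulate
error well below 1e-12 per composition).

## Layout generation

Sites are enumerated per face in barycentric coordinates.  An "upward"
triangle indexed (i, j, k), i + j + k = h − 1, is a pentasymmetron site if
two indices are zero, a disymmetron site if exactly one is, and a BBB facet
site otherwise; "downward" triangles are CCC sites.  Facet colouring is
therefore literal triangle orientation — no separate parity rule is needed,
and the pentasymmetron/disymmetron sites provably sit on the B-coloured
sublattice.  Edges are discovered by shared subdivision-vertex keys
(coordinates rounded to 1e-6 of the unit icosahedron), which also yields the
pore census by vertex degree (5 → pentagon, 6 → hexagon) and the literal
"count steps between pentagons" estimator of h used by `infer_h`.

Sites are placed on flat facets by default, matching the picture of 20
folded triangular hexagonal lattices; `spherical=True` projects centres to
the circumsphere.  The lattice constant is the centre-to-centre spacing of
adjacent trimers within a facet (Å).  Site orientation maps local +z to the
face normal and distributes the three local arm directions (0°, 120°, 240°)
against the three neighbour azimuths with a minimal circular-mean offset.

A note on diameters: `predict_diameter` scales a calibration diameter
linearly in h (the paper-level statement).  The geometric diameter of a
flat-facet layout (twice the maximum site-centre radius) deviates from pure
linearity by a few per cent because the vertex-adjacent sites crowd the
vertex as h grows; the sphere-projected layout scales exactly.  This is why
the linear prediction is only expected to agree with published design-model
diameters to ~5%.

## Synthetic building blocks

The synthetic trimer is a deliberately minimal stand-in for a real C3
trimer: three chains of Cα/Cβ pseudo-atoms (alanine-typed), each an arm
radiating from the C3 axis with 3.8 Å residue spacing, capped by a
"contact bar" of (default 5) residues running perpendicular to the arm.
The bar is the crucial realism ingredient: it makes every inter-trimer
interface an extended, surface-like contact rather than a single point, so
contact counts vary smoothly under slide and twist and docking landscapes
are peaked.  One template arm receives seeded Gaussian jitter (σ = 0.05 Å)
and is replicated by exact 120° rotations, so backbone C3 symmetry holds to
machine precision by construction.

What the generator does *not* emulate: side chains and packing, sequence
identity (beyond residue-type labels consumed by the energy model),
backbone flexibility, and realistic interface chemistry.  Tests that pass
on these fixtures therefore validate geometry, combinatorics, bookkeeping
and algorithmic correctness — not interface designability on real
proteins.

Default conditions: the compact test trimer uses radius 3 Å, 8 residues per
chain (3 in the bar); assembled cages use a lattice constant leaving a 4 Å
heavy-atom gap between facing arm tips, which keeps every generated model
free of heavy-atom clashes at the 2.4 Å threshold (~0.8 × the sum of C/N/O
van der Waals radii).

## T = 1 parent, pentasymmetron, disymmetron

The T = 1 parent places 20 trimer copies on the three-fold axes; its radius
is solved (Brent root-finding) so the nearest inter-trimer heavy-atom
distance equals a 4 Å contact gap.  A pentasymmetron is the five trimers
nearest a five-fold vertex, relabelled AAB by geometric context: the two
chains of each trimer holding the two vertex-adjacent inter-trimer contacts
become A, the outward chain becomes B.  A disymmetron is the two trimers
flanking a two-fold edge, relabelled ABB with A at the shared contact.
Ambiguous nearest-trimer selections (angular ties below 1e-6) raise.

## Docking

The T = 4 dock has four degrees of freedom: translation along and rotation
about the pentasymmetron's five-fold axis (φ reduced mod 72°) and the
trimer's three-fold axis (mod 120°), with the two axes 37.377° apart.  The
score is a coarse contact/clash composite: number of cross-component
residue-centre (Cβ, Cα fallback) pairs within 8 Å minus 10 × the number of
heavy-atom pairs within 2.4 Å.  Pair search uses KD-trees and is exact
(tested against brute force).  The grid scan is exhaustive and
deterministic; ties break lexicographically on the DOF tuple.

A count-based composite is maximal at the tightest clash-free packing, so
the parameter-recovery experiment builds its reference cage at a 3.0 Å tip
gap — components in contact, as a dock would generate them.  Under those
conditions the generating DOFs are the strict grid optimum and are
recovered within one grid step (2 Å / 4°).  Filtering keeps configurations
whose contacts run entirely (configurable fraction) through the
pentasymmetron's unpaired B chains, the screen for productive docks.
Sequence design of the resulting B:C interface is out of scope; the dock
exposes the interface residue lists instead.

## Mutant-pair scanning

Interface contacts follow the 4 Å heavy-atom rule, each unordered residue
pair stored once in canonical order.  Two counting conventions are exposed,
since homotrimer interfaces can be counted per distinct chain pair or with
the three symmetry-related copies merged (`merged_position_pairs`).

The reference energy model is a pairwise softened steric repulsion between
residue centres: E = Σ max(0, r_a + r_b − d)², with effective radii from
mean residue volumes and same-chain pairs closer than 2 in sequence
excluded.  Mutations change only the residue's type parameters, never
coordinates — no repacking — which keeps Δscore/ΔddG exact, deterministic,
additive over disjoint supports, and oracle-checkable.  This reproduces the
disrupt-and-rescue logic (an oversized residue over-fills a tight contact;
a small partner re-opens it) but is *not* numerically comparable to
molecular-mechanics scores; published energy-unit thresholds do not
transfer, so the disruption threshold defaults to 0 and is configurable.
ΔddG is defined symmetrically with Δscore (mutant minus wild type).

The coevolution channel consumes external residue-coupling frequency
tables and proposes (i→m, j→c) pairs where the mutant/wild-type combination
is depleted (enrichment < θ_low) and a mutant/compensatory combination is
enriched (> θ_high), ranked by the enrichment ratio.  Zero expected
frequencies are skipped with a warning, or regularized with an optional
pseudocount.

## Design-vs-observed comparison

`rmsd_fixed` is the no-refit Cα r.m.s.d. of axis-aligned models;
superposition uses a standard SVD Kabsch solve with the determinant
correction (proper rotations only; collinear inputs raise).  Rigid-body
deviations report the rotation angle from the trace formula, the
translation magnitude, and its signed projection on the component's
origin direction (positive = outward).  Where a rotation sign matters it is
defined looking from outside the cage down the component axis toward the
origin.  Correspondence is harmonized before any metric: only residues
present in both models (per chain label and residue index) are compared,
and the fixed correspondence is never re-fit globally.

Comparisons against deposited cryo-EM models are a manual workflow (the
README shows the commands); they require downloading the public structures
and are not part of the automated suite.

## Numerical choices

- Construction tolerance 1e-9; membership/equality 1e-6; mmCIF/PDB
  coordinate round-trip asserted to format precision (1e-3 Å).
- Deterministic everywhere: seeded RNGs only, sorted canonical orderings,
  lexicographic tie-breaks; repeated runs are byte-identical.
- Test problem sizes: the compact 8-residue trimer and h ≤ 4 cages keep the
  full suite in a few seconds while exercising every code path; counts and
  invariants are size-exact, not approximate, so nothing is lost at this
  scale.

## Known limitations

- Class II/III (skew) Goldberg lattices, elongated lattices and
  quasi-equivalent backbone relaxation are not generated.
- ABC heterotrimers are deliberately unsupported (`relabel` raises),
  mirroring the experimentally observed failure of that route; AAB/ABB are
  the supported heterotrimer patterns.
- The steric energy model ranks clash/relief logic only; it cannot
  reproduce published Rosetta-derived counts (e.g. numbers of disrupting
  mutations), which depend on that force field.
- Flat-facet geometry treats each face as planar; real cages relax
  curvature smoothly across edges.
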