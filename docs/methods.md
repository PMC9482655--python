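# Methods

This note documents the models and procedures implemented in `istfold`,
the parameters that matter, the synthetic data the package is validated
on, and the limits of what those validations show.

## Secondary structure from hydrogen bonds

Backbone amide hydrogens are rebuilt geometrically: H sits 1.0 Å from N
along the in-plane direction opposite the bisector of C(i−1)→N(i) and
CA(i)→N(i); prolines and chain-initial residues get none. Hydrogen bonds
are scored with the Kabsch–Sander electrostatic model,

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   kcal/mol,

kept when `E < −0.5` (distances are clamped below 0.5 Å so one bad
contact cannot dominate the sum; energies clamp at −9.9). Each donor
keeps at most its two best acceptors, and donor–acceptor pairs closer
than two positions in sequence are excluded.

Labels follow the DSSP conventions: α-helix (H) from two consecutive
i→i+4 turns, 3₁₀ (G) from two consecutive i→i+3 turns, strand (E) from
parallel/antiparallel bridge patterns, priority H > E > G > coil.
Minimum segment lengths are 3 (helix) and 2 (strand), chosen so a
single-turn helix survives as a named element. Two refinements matter in
practice and follow the same paper's spirit:

* **β-bulge closure** — a single non-strand residue flanked by strand on
  both sides is relabelled E;
* **sheet edges need two bridges** — a lone bridge between two strands is
  treated as an isolated-bridge contact, not a sheet pairing. This keeps
  incidental backbone contacts (e.g. a linker running past a sheet edge)
  from merging sheets.

π-helices and bend/turn states are not assigned. Sheets are connected
components of the strand-pairing graph; strand order within a sheet
follows bridge adjacency and each adjacent pair is classified P/AP by
majority bridge type.

## Helix axes and bundle geometry

A helix axis is fitted through the centroids of sliding windows of four
consecutive Cα atoms; the global direction is the principal direction of
those local points, oriented N→C. Because a four-residue window is ~1.1
helical turns, the raw local trace wobbles slightly; curvature measures
use a once-more smoothed trace. Straightness is the cosine of half the
direction change between the first and last third of the trace — exactly
1 for a straight helix and `cos(κ/2)` (equivalently chord over path) for
a single kink of angle κ.

Crossing angle = `arccos(û_a·û_b)` on N→C directions, so "parallel"
means co-directed chains; the inter-axis distance is the minimum
distance between the finite axis segments. Orientation classifies P
below 90° and AP at or above it (the exact-90° tie goes to AP, an
arbitrary but documented choice).

A bundle candidate is any four helices (≥7 residues each) whose
axis-distance graph, thresholded at 14 Å, contains a 4-cycle. The packing
order is the angular order of helix midpoints about the shared centroid
in the plane normal to the mean axis; the hallmark alternation test asks
whether adjacent pairs around that cycle read `P-AP-P-AP` or `AP-P-AP-P`.
The 14 Å packing distance and the 60–120° perpendicularity window with a
12 Å centroid-to-terminal-third distance for the triangular face have no
published definition for this family; they are canonical four-helix
bundle values, validated on the synthetic mimics, and exposed in the
configuration.

The distortion score — mean of (a) the coefficient of variation of the
four adjacent inter-axis distances sampled at three matched heights
along the common bundle axis and (b) the mean helix non-straightness —
operationalizes "distorted, uneven packing". It is reported but is not a
hallmark criterion, since no quantitative threshold for "distorted" has
been published.

## Disulfides, CXXC motifs, and the dual-CXXC hallmark

Disulfides are CYS SG–SG pairs within 2.5 Å (typical bond 2.05 Å),
paired greedily by ascending distance with each SG used at most once;
greedy pairing is verified against brute-force maximum matching in the
tests. No χ_SS dihedral filter is applied by default because the
synthetic fixtures only position SG atoms precisely. The CXXC scan runs
on the one-letter sequence in author numbering and permits overlaps.

The dual-CXXC hallmark requires two motifs with disjoint cysteines
linked by exactly two cross-motif disulfides, one motif on a helical
segment of ≤7 residues ("small N-terminal helix"), the other within two
residues of a β-hairpin turn (adjacent antiparallel strands, connecting
loop ≤5 modelled residues). Both the straight (first–first/last–last)
and crossed pairing patterns are accepted and the observed one is
recorded, since the published description does not fix it.

## Domain partition and inter-domain bend

The helical domain is the maximal N-terminal region where sliding-window
(width 15) helix content dominates strand content, snapped to the end of
the last helical segment before the first strand-dominated window. The
sandwich domain is delimited by the packed sheet pair itself — the two
sheets whose Cα centroids lie 7–14 Å apart — running from the first
substantial strand (≥4 residues; shorter fragments place sheets but are
too jittery to set boundaries) to the C terminus. A pure window rule
cannot keep the hinge's own small sheet out of the sandwich when the
Ig-like domain contains long internal coils, which is true of this
family (the capping coil and epitope region sit between two sandwich
strands); the packed-sheet boundary solves this and is the one deviation
from a pure content-window segmentation. The hinge is whatever separates
the two domains.

The bend is the angle between the undirected principal axes of the two
domains' full Cα clouds, folded into [0°, 90°]. An alternative
SSE-core-only axis (helix residues for the bundle, strand residues for
the sandwich) is available for sensitivity checks; under coordinate
noise the full cloud is the more stable estimator, because the surviving
SSE labels are a biased subset. The Ig-like check ranks sheets inside
the sandwich by strand count, requires two sheets with centroids 7–14 Å
apart, and reports a mechanical clamp when a parallel bridge pair
involves the domain's most C-terminal strand.

## Superposition

`superpose` matches residues 1:1 by author numbering, optionally within
a selection, and solves the least-squares rigid superposition in closed
form (SVD with the usual determinant correction). Tests verify it
against an independent quaternion-grid search with local refinement.

## Conservation and surface patches

Column conservation is `1 − H/ln 20`, the normalized Shannon entropy of
the 20-amino-acid distribution in the column, gaps excluded; columns
with more than 50% gaps are flagged and unscored. This is a deliberate
simplification of phylogeny-aware (ConSurf-style) rates: it needs no
tree, is exactly reproducible, and suffices for patch-level statements.
Mapping to the structure uses ungapped position in the reference row
against an author-numbering offset.

Relative accessibility uses the Shrake–Rupley sphere-point method (960
points, 1.4 Å probe) normalized by theoretical Gly-X-Gly maxima (Tien et
al. 2013). On backbone-only synthetic models the absolute values are not
meaningful as real-protein accessibilities, but the buried/exposed
contrast is preserved and the 0.25 exposure cutoff separates core from
surface cleanly. Patches are single-linkage clusters (10 Å Cα) of
residues that are both conserved (top quartile) and exposed; patches
under 3 residues are dropped, and uniformly scored inputs yield no
patches at all (no signal, nothing stands out). If every fourth residue
qualifies by construction of the quantile rule, patch memberships on
real-scale inputs should be read as containment statements, not exact
sets.

## The synthetic data: what it emulates and what it does not

All validation structures are generated, with ground truth recorded in
sidecars:

* **Ideal helices** are built from cylindrical per-atom offsets frozen
  from an internal-coordinate chain at (φ,ψ) = (−57°,−47°) (α) or
  (−74°,−4°) (3₁₀), so i→i+4 / i→i+3 hydrogen bonds exist by
  construction. Defaults: rise 1.5 Å/residue, twist 100°/residue, Cα
  radius 2.3 Å.
* **Sheets** place ideal extended strands ((φ,ψ) = (−139°,135°)) with
  frozen rigid pair transforms optimized once for strong Kabsch–Sander
  ladders without steric overlap; antiparallel pairing uses separate
  "partner above" and "partner below" relations because the pleated
  template is not mirror-symmetric.
* **The composite IST mimic** assembles an alternating bundle (tall and
  short helices on diagonal corners so uneven lengths do not tilt the
  domain axis), a perpendicular single-turn helix, a hinge hairpin
  carrying the second CXXC motif, explicit SG placement at 2.05 Å for
  designated pairs, and an optional 4+2 sandwich whose long axis makes a
  prescribed angle with the bundle axis. The builder calibrates that
  angle against the package's own partition-and-principal-axis
  measurement on the clean build, so the constructed bend is exact under
  the package's definition. Ablation switches remove exactly one
  hallmark each.
* **The synthetic reference models** encode the published SPACA6
  ectodomain architecture (residues 27–246, helix 1′ + four bundle
  helices + 3₁₀ + capping helix, nine strands in three sheets, six
  disulfides at the published pairs, ~85 Å long axis, ~10° bend) and an
  IZUMO1-like ~50° comparator. They are constructed stand-ins, not
  experimental coordinates: author numbering, inventory and topology
  match the published description; exact secondary-structure element
  boundaries, sidechains beyond cysteine CB/SG, and real packing detail
  do not.
* **Synthetic alignments** plant invariant columns at chosen residues on
  an otherwise randomly substituted 12-row ortholog-like alignment; no
  indels are modelled.

Passing tests on these models therefore shows that the geometric
pipeline recovers known construction parameters and published inventory
claims under the stated noise; it does not substitute for validation on
deposited experimental structures, which the package reads but does not
ship.

### Noise levels and benchmark sizes

Coordinate noise is i.i.d. isotropic Gaussian per atom. On minimal
backbone-only models this degrades hydrogen-bond networks much faster
than equivalent noise on real structures, where sidechain packing
constrains the backbone. The recovery benchmarks therefore use:

* bundle orientation grid (crossing angles 0–40°, both chiralities,
  20 seeds): σ = 0.3 Å — helix-level measures are robust;
* secondary-structure element recall grid (helix lengths 8–20, hairpin
  strands 4–10, 20 seeds): σ = 0.2 Å, scored per element (an element is
  recovered when a correct-type segment covers at least half of it),
  ≥95% required;
* bend-angle recovery grid (β ∈ {0,10,30,50,70}°, 10 seeds): σ = 0.2 Å,
  within 5°;
* 40-structure classifier benchmark (20 positives varying bend and
  Ig-domain presence, 20 negatives spanning all single ablations and
  regular parallel bundles): σ = 0.1 Å, sensitivity = specificity =
  100% required. At this level the single-turn helix and hairpin-turn
  evidence that hallmarks 2 and 3 depend on remains detectable; larger
  noise erases those minimal elements themselves rather than testing the
  detectors.

All seeds are fixed; every reported number is deterministic.

## Numerical choices and degenerate inputs

* Alternate locations resolve to highest occupancy, first-listed on
  ties; only the first model of multi-model files is read; waters and
  non-polymer heteroatoms are dropped; modified polymer residues surface
  as 'X'.
* Exactly-90° crossing angles classify AP; zero-variance conservation
  yields no patches; all-helix or all-strand chains partition with a
  flag instead of an error; chains under 40 residues refuse to classify.
* Interatomic distances below 0.05 Å abort hydrogen-bond detection as
  corrupt coordinates.
* The synthetic "predicted-model agreement" number superposes a noise
  copy of the reference at σ = 0.64 Å, a level chosen once so the
  expected Cα deviation emulates the published model-versus-crystal
  scale for this ectodomain; it demonstrates the superposition pipeline
  under realistic deviation, not an independent prediction.

## Known limitations

* Hallmark thresholds (14 Å packing, 60–120° window, ≤7-residue short
  helix, ≤5-residue hairpin loop) are calibrated on canonical bundle
  geometry and the synthetic mimics, not fitted to a family-wide survey;
  they are all configuration-exposed.
* No Crick coiled-coil parameterization, knobs-into-holes analysis,
  π-helix state, or χ_SS dihedral filtering.
* Conservation scoring ignores phylogeny and substitution similarity;
  alignments are inputs, never computed.
* Classification is geometry-only: per-model confidence fields in
  predicted-structure files are ignored.
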