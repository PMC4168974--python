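# Methods

This note documents the models, conventions and numerical choices behind
`fvorient`, and what the synthetic testbed does and does not establish.

## Structure model

A variable domain is a set of residues carrying Cα and Cβ coordinates
(optionally all heavy atoms) indexed by IMGT position (1–128; insertion
codes only in the CDR3 111/112 block). IMGT numbering is consumed from a
sidecar table, never computed: renumbering is a separate, well-served tool
class (IMGT DomainGapAlign, ANARCI) and bundling one would couple this
package to germline databases. Regions follow the IMGT scheme: CDR1 27–38,
CDR2 56–65, CDR3 105–117, framework elsewhere. A residue without a Cβ
(glycine, truncated side chains) receives a virtual Cβ at its Cα, keeping
every Cβ-distance rule total; alternate locations resolve to the
highest-occupancy conformer. The VH↔Vβ / VL↔Vα equivalence is built into
the containers: every paired receptor has an H-side (VH or Vβ) and an
L-side (VL or Vα) domain, so antibodies and TCRs flow through the same
code paths.

## Superposition and frames

All rigid fits are least-squares (Kabsch via SVD) with the reflection
branch excluded; targets whose centered coordinates are rank-deficient
(collinear) are rejected rather than silently fitted. Principal axes come
from the coordinate covariance; the leading axis is oriented from the first
toward the last input point, which for a peptide read N→C makes the major
axis a directed vector and keeps docking angles above 90° meaningful.
Torsions use the four-point convention that is positive for a right-handed
rotation about the central axis.

**Coresets.** Starting from all framework positions present in ≥ 95% of an
ensemble (error if fewer than 20 qualify), members are iteratively
superposed on the evolving per-position mean; the position with the largest
positional spread (RMS deviation from the aligned mean) is dropped until
every remaining spread is ≤ 1.0 Å or the floor of 20 positions is reached.
The derived set is recorded on the result for transparency. Published
coreset lists exist for antibodies but are not redistributable, so deriving
them from the input ensemble keeps the method self-contained; on clean data
the procedure retains essentially all framework positions.

**Consensus and frames.** The consensus domain is the per-position mean Cα
after iterative superposition on the coreset (converged when the mean
shifts < 1e-4 Å; error after 100 iterations). Each domain's reference
frame is fitted through the interface positions — by default IMGT 38–50
and 87–104, the β-sheet faces forming the dimer interface, user-overridable
— as origin = centroid and e1/e2 = the two leading principal axes of those
Cαs. Signs are fixed deterministically toward structurally salient
residues: e1 toward the IMGT 104 (interface cysteine) consensus Cα, e2
toward IMGT 50.

**The six measures.** Frames are registered onto a query by coreset
superposition (≥ 20 shared positions required; a registration RMSD above
2.5 Å flags the result as unreliable rather than failing). With registered
origins O_H, O_L and in-plane vectors, C = O_H − O_L and

    dc = |C|,  HL = torsion(O_H+e1_H, O_H, O_L, O_L+e1_L),
    HC1 = ∠(C, e1_H), HC2 = ∠(C, e2_H), LC1 = ∠(−C, e1_L), LC2 = ∠(−C, e2_L).

Because the pivot axis and frames are derived from the analysis ensemble
rather than imported from the original antibody reference data (whose frame
files are not available), absolute values are internally consistent but
offset from published ABangle numbers. Comparisons *between* structures
measured with one frame system — the package's purpose — are unaffected.
Reproducing published ABangle values bit-for-bit is a non-goal.

## Orientation RMSD and clustering

The bidirectional orientation RMSD uses the intersection of framework
positions present in both structures (≥ 20 per domain; the counts appear in
the error message otherwise). Crystal structures with unmodelled framework
stretches therefore contribute fewer correspondence points; this choice is
recorded because the original protocol did not state how missing residues
were handled. Complete-linkage clustering runs on the condensed pairwise
matrix; ties in merge height resolve by index order, making labels
deterministic for a given input order. Dendrograms export as Newick with
branch lengths derived from merge heights.

## Docking angle and grafting

The docking angle is the unprojected 3D angle between the peptide's N→C
major axis and the Vα→Vβ 104–104 Cα vector, reported in [0°, 180°);
canonical iff within [40°, 85°]. No projection onto the groove plane is
applied. The Vα→Vβ direction convention is fixed so that reversed-
equivalence binders (angles > 90°) are distinguishable from canonical ones.

Grafting anchors one native domain (default the L side), aligns the decoy
onto it via shared framework Cαs, and carries the native partner domain
rigidly onto the decoy partner's aligned pose — every chain keeps its
internal geometry exactly; MHC, peptide and anchored domain are untouched.
Steric fallout is counted per residue pair, once per pair regardless of how
many atom pairs collide: with full atoms, a clash is a heavy-atom overlap of
≥ 0.4 Å of summed van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 Å;
unknown elements default to carbon) — the Molprobity-style criterion,
implemented internally so no external binary is needed; with reduced
(Cα/Cβ) models the pair clashes below 3.0 Å Cβ–Cβ. Side-chain remodelling
between graft and count is intentionally out of scope, so all-atom counts
correspond to "before side-chain rearrangement" numbers; an external
remodeller can be applied to the written grafted PDB before re-counting.
Contacts are all receptor↔MHC/peptide pairs with Cβ–Cβ < 7 Å.

## Sequence analyses

Frequencies are computed over observed positions only (gaps excluded from
numerator and denominator). Conservation uses ≥ 50% for the
domain-equivalence tally and strictly > 50% for divergent-interface
screening — both thresholds are parameters with those defaults, kept
distinct because the two analyses are conventionally stated with different
strictness. Exact two-way ties at the threshold are reported as ambiguous
(no conserved residue, with a warning). The equivalence tally counts a
position as evidence against a pairing when a cross-class pair shares a
conserved residue while the within-receptor partner conserves a different
one. Divergent interface positions are "antibody-compatible" engineering
targets when the TCR-conserved residue already occurs at ≥ 2% frequency in
the antibody background set. Sequence identity for the redundancy filter is
matches over shared observed positions of the two-domain IMGT grid — no
alignment step is needed on a common numbering — and the greedy filter
visits candidates best-resolution-first (ties by PDB id), so its output is
independent of input order. This identity differs from cd-hit's word-based
estimate, so retained-set sizes can differ from counts derived with cd-hit.

## Synthetic testbed

The generator builds two copies of a deterministic pseudo-β-sandwich
scaffold (~124 IMGT-labelled Cα/Cβ positions in ideal-geometry strands and
CDR arcs, cysteines at 23 and 104, controllable CDR3 length) and places the
H-side copy relative to the L-side copy so that the frame construction
above yields exactly the requested (HL, HC1, HC2, LC1, LC2, dc); requests
with cos²LC1 + cos²LC2 > 1, cos²HC1 + cos²HC2 > 1, or HC1/LC1 ∈ {0°, 180°}
are geometrically unreachable and rejected. Isotropic Gaussian noise is
then added per atom. Default pose (HL −60°, HC1 70°, HC2 120°, LC1 120°,
LC2 80°, dc 16 Å) sits in the physiological range of packing geometries;
the twist families used throughout testing differ by 15° in HC2 with a 2°
within-family SD and n = 20 per cohort, the scale of the class difference
the measures are designed to resolve. Toy pMHC complexes place a 9-mer
peptide along +x over a two-layer pseudo-residue slab and lower the
receptor, its 104–104 vector set at the requested docking angle in the
groove plane, until the minimum receptor–environment separation equals the
requested groove gap (fixed-point iteration, 1e-8 Å tolerance). All
randomness flows from one explicit seed recorded in the ground truth.

What passing on this testbed shows: the geometric machinery is exact and
self-consistent, the statistics detect the designed effects at realistic
effect sizes, and every I/O path round-trips. What it does not show:
behaviour under real crystallographic pathologies (missing loops,
alternate conformers beyond occupancy selection, domain plasticity),
chemically realistic side-chain packing, or sequence realism — scaffold
sequences are a fixed labelled pattern, so sequence analyses are validated
on constructed profiles, not evolution.

## Statistics

Cohort comparisons use the two-sided two-sample Kolmogorov–Smirnov test per
measure (scipy; exact small-sample branch where applicable) and a two-sided
Mann-Whitney U on per-decoy total clash counts; both are cross-checked in
the test suite against exhaustive enumeration on tiny samples. No
multiple-testing correction is applied across the six measures; the
per-measure p-values are reported as-is and noted as uncorrected.

## Problem sizes

The test suite and acceptance script run at deliberately modest sizes —
25-pose round-trip grids, 20-structure cohorts, 4-point twist grids,
100-trial counting-oracle randomisations — chosen because the verified
properties (exactness, monotonicity, separation at 7.5 within-family SDs)
are insensitive to scale beyond these sizes.

## Known limitations

- Absolute measure values depend on the frame system in use; export the
  frame system (coresets are recorded on results) alongside any published
  numbers.
- Clash counts on Cα/Cβ-only models use the 3 Å Cβ rule and are not
  comparable to all-atom counts.
- The accession-backed docking-angle check requires the user to supply the
  crystal structure and IMGT sidecar (see `tests/test_acceptance.py`);
  structures and renumbering services are not bundled.
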