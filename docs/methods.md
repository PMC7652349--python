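# Methods

This note documents the models, rules and numerical choices behind
helixforge: a desk-scale pipeline for comparative modeling of G-protein
coupled receptors (GPCRs) from templates of low (<40%) sequence identity.
It covers the blended sequence/structure alignment, template selection,
partial threading, the Monte Carlo hybridization stage and its composite
score, the evaluation conventions, and the synthetic-family generator that
makes every stage testable without external structure downloads.

## The modeling problem

GPCRs share a seven-transmembrane-helix (7TM) fold whose structure is far
better conserved than its sequence: typical pairwise identity within the
family is near 30%, below the range where automated sequence alignment
reliably supports homology modeling. The pipeline therefore encodes the
field's structural knowledge directly:

1. **Template alignment** blends sequence and structure. Transmembrane
   helices are aligned outward from the most conserved residue of each
   helix — the Ballesteros–Weinstein (BW) x.50 anchor — using superposed
   coordinates to decide where insertions and deletions fall along the
   helical axis. Loops are aligned by spatial proximity and Cα→Cβ vector
   agreement, which survives sequence divergence. Residues no criterion
   can place are parked adjacent to defined secondary structure so that
   downstream fragment insertion bridges ordered and disordered regions
   cleanly.
2. **Template selection** ranks candidates by masked pairwise identity
   (TM bundle plus loops, long termini excluded), removes templates at or
   above 40% identity (the low-identity regime is the one under study),
   and models from the top five by default.
3. **Partial threading** copies template backbone onto the target through
   the alignment; columns gapped in the template stay unmodeled.
4. **Hybridization** completes and refines the model by Metropolis Monte
   Carlo recombination of segments from all threads plus 3/9-residue
   fragment insertions, under a lightweight composite score.
5. **Evaluation** reports per-region Cα RMSD (TM bundle, ECL2, full
   model) and benchmark statistics (fold change, template-count and
   identity-bin experiments).

## Alignment rules and their parameters

| parameter | default | meaning |
|---|---|---|
| `d_max` | 2.0 Å | Cα deviation from the column consensus that triggers indel handling during outward helix extension. A one-residue register slip displaces a Cα by ≈3.8 Å, coordinate noise by ≲1 Å, so 2.0 Å separates the two. |
| `d_loop` | 3.0 Å | maximum Cα–Cα distance for two loop residues to share a column. |
| `theta_max` | 60° | maximum angle between Cα→Cβ unit vectors for loop residues to share a column. |
| `termini_pad` | 10 | terminal residues adjacent to TM1/TM7 kept in the identity mask; anything further out counts as "long termini". |

Helix extension is greedy and consensus-based: at each step outward from
the anchor column, the per-row candidate Cα is compared with the
coordinate-wise median of all candidates. A deviating row receives a gap
(deletion) unless its *next* residue already matches the current
consensus, in which case the deviating residue becomes a row-exclusive
bulge column (insertion). This resolves single-residue indels exactly and
degrades gracefully (offset pairing) when no consensus exists.

Loop alignment is a medoid-star alignment refined in three passes. The
reference row is the loop most structurally compatible with all others
(a loop in an atypical conformation would poison everyone's register);
each remaining row is aligned to it by dynamic programming in which only
compatible pairs (distance + vector criteria) may match, with a
distance-weighted bonus so register ties resolve toward the geometrically
closer pairing and a large bonus that force-pins disulfide cysteines.
A consensus rescue pass then joins residues the star alignment left out
into columns whose member-median Cα is within `d_loop` (this is more
robust than the worst-pair criterion when a residue sits near the
tolerance boundary). Finally, residues still unplaced are clustered
greedily among themselves — order-preserving, mutual-compatibility
columns — so that correspondences absent from the reference row can
still form.

Precedence when rules conflict is: disulfide pinning > helical
secondary-structure elements > the vector criterion. Extended (strand-
like) runs are *not* force-protected: smooth loop geometry classifies as
extended under a Cα-trace classifier, and the vector criterion already
arbitrates register there, so breaking up such runs costs accuracy for no
benefit. Helical elements in loops are kept contiguous (an element split
across columns would leave an unbuildable fragment junction).

Aligning a structure-less target into the finished template MSA uses, in
order: exact family propagation (a region whose sequence matches a
template's region copies that template's placement — this also propagates
family-specific gaps); x.50 anchoring of each helix, with motif fallback
(DRY for TM3, CWxP for TM6, NPxxY for TM7) choosing the occurrence
nearest the expected mid-helix position, ties toward the N-terminus;
xWxxG anchoring of ECL1; ICL3 split at its midpoint with the halves
adjoined to TM5/TM6; ECL2 split at the conserved cysteine (pinned to the
TM3-disulfide column), each sub-loop halved toward its nearest fixed
feature; ECL3 cysteines pinned to disulfide columns when both sides have
them; every remaining loop half-split against its flanking helices. Odd
splits give the extra residue to the N-terminal half. Termini pack
against TM1/TM7.

Percent identity uses mutually non-gap masked columns as the denominator
(the common pairwise-identity convention); the alternative (all masked
columns) is available via `AlignConfig.identity_denominator`. Identity
binning truncates to integer percent before range testing, so 24.9%
falls in the 20–24 bin.

## The hybridization score

The composite score is this package's own lightweight objective — an
explicit stand-in for a molecular mechanics energy, not an approximation
of any particular force field. Its terms (Cα/Cβ level):

| term | definition | default weight |
|---|---|---|
| clash | Σ over nonadjacent Cα pairs of max(0, 4.0 − d)² | 1 |
| chainbreak | Σ (d(Cαᵢ, Cαᵢ₊₁) − 3.8)² | 10 |
| ss_agreement | fraction of residues whose Cα-trace geometry class (virtual-dihedral classifier) disagrees with the predicted secondary structure | 5 |
| disulfide | Σ over restraints of max(0, d(Cβ,Cβ) − 5.0)² | 10 |
| rg | max(0, Rg − Rg_ref)², Rg_ref = mean template Rg + 2 Å | 0.1 |
| template_consensus | mean Cα deviation from the per-residue median of the superposed threads | 50 |

The consensus weight deserves explanation because it is far from 1.
clash/chainbreak/disulfide/rg are *sums* over the chain (extensive),
while ss_agreement and template_consensus are per-residue *averages*
(intensive). With a weight of order 1 the consensus term cannot resist
the cumulative gain of polishing hundreds of virtual bonds, and the
search slowly random-walks away from the templates while idealizing
local geometry — on fixtures this degraded TM accuracy from ~0.4 Å to
~2.7 Å. A weight of ~0.25× a typical receptor length (≈200 residues)
makes a 1 Å mean drift cost as much as the strain it could relieve, which
restores template tracking without freezing the search. All weights are
configurable (`ScoreWeights`).

Monte Carlo details: the highest-identity thread seeds the state;
unmodeled runs are first completed by linear Cα interpolation (termini
extrapolate along the last chain step) with a locally rebuilt
pseudo-backbone. Moves are chosen 50/50 between template-segment swaps
(contiguous region of 5–30 residues copied from another thread after
local superposition on up to 3 flanking residues per side, which keeps
the global receptor frame) and fragment insertions (a 3- or 9-mer from
the library, superposed on the window's two end residues' N/Cα/C atoms).
Fragments are harvested from template windows whose observed
secondary-structure classes agree with the prediction in at least two
thirds of positions; ideal-geometry helix/strand/coil fragments guarantee
coverage everywhere. Temperature cools geometrically from 2.0 to 0.25
over 5000 steps per model (100 models per run by default); model *i*
runs an independent trajectory seeded `seed + i`, and the best state
encountered in each trajectory is returned. Everything is exactly
reproducible for a fixed seed.

A segment swap can only repair a mis-modeled region it can span: the
swap is anchored on the current state's flanks, so a defect longer than
`swap_max` minus the flanks must be crossed in several moves, each paying
a chainbreak barrier. This is a known limitation of flank-anchored
recombination and the reason the default `swap_max` (30) comfortably
exceeds the length of typical loop/helix defects at this scale.

## Evaluation conventions

RMSD is Cα-only (models are backbone-level) after least-squares (Kabsch,
SVD-based, proper rotation enforced) superposition. By default each
region is superposed on itself before measuring ("region" convention,
the strictest self-contained choice); `fit="global"` superposes once on
the mutual TM atoms and measures every region in that frame. Both are
provided because published per-region numbers are frequently ambiguous
about this; neither is labeled canonical. Residues unresolved in either
structure are excluded pairwise rather than imputed.

Fold change is mean(method RMSD)/mean(reference RMSD) per target, with
the benchmark summary being the mean of per-target ratios; the reference
method's own fold change is exactly 1.0 by construction.

## The synthetic-family generator

The generator is the pipeline's benchmark stand-in: idealized 7TM
receptors with *known* ground truth for alignments and coordinates.

An ideal bundle places seven ideal α-helices (1.5 Å rise, 100°/residue
twist) with axes on an 11 Å circle, alternating up/down so TM1 runs
extracellular→intracellular. Loops are smooth circular arcs sampled at
exact 3.8 Å chord spacing; ECL2 is routed past the extracellular end of
TM3 so the planted conserved TM3–ECL2 disulfide is geometrically
satisfied (Cβ–Cβ < 5 Å). The sequence is random (uniform over 20 amino
acids) but carries the class-A motifs (DRY, CWxP, NPxxY, xWxxG) at their
anchors; spurious loop cysteines are removed so the cysteine-anchored
loop rules are unambiguous. A short position-based relaxation pushes
nonadjacent Cα pairs to ≥4.2 Å (real Cα traces do not clash) while
pinning helices and the disulfide cysteines. Backbone N/C/O/Cβ atoms are
pseudo-atoms derived from the Cα trace — adequate for Cα-level modeling
and vector diagnostics, not an all-atom reconstruction.

Families evolve from the ancestor by:

* **point mutations** at a configurable per-residue rate, uniform over
  the 19 alternatives; anchors, disulfide cysteines and the planted
  motifs are protected (that is what "conserved" means in this family).
  `mutation_rate_for_identity` inverts the two-descendant identity
  expectation (1−m)² + m²/19 so tests can target an identity band.
* **single-residue loop indels** (per-loop probability `indel_rate`):
  an insertion bulges 2.8 Å perpendicular to the chain between its
  neighbours; a deletion re-lays only a ±2-residue window as a fresh arc
  between fixed flanks. Both perturb the structure locally, as real
  indels do — re-laying a whole loop would make the descent-based ground
  truth structurally meaningless. Helices admit bulge insertions only
  (`tm_indels=True`); a helix deletion would demand a register shift
  along the axis, not a local repair.
* **chain-correlated coordinate noise**: a Gaussian random field
  smoothed along the sequence (kernel SD 2 residues), rescaled to the
  requested per-residue RMS, then virtual bonds re-projected to 3.8 Å.
  White noise would strain every virtual bond — something no real
  structural ensemble does — and would hand the hybridization stage a
  spurious smoothing gradient.

Every edit is logged; the ground-truth alignment, per-residue descent
maps and actual displacements are exact. `structure_conserved_columns`
labels a truth column conserved only when every resident residue kept
both its position (≤ `d_loop`/2 = 1.5 Å) and its Cα→Cβ orientation
(≤ `theta_max`/2 = 30°) relative to the ancestor: residues flanking an
insertion bulge barely move but reorient ~90° and are genuinely no
longer structurally conserved — a displacement-only definition would
mislabel them. Alignment-recovery claims are made against this set; the
remaining (non-conserved) columns are cases where structure genuinely
contradicts descent and no structural aligner should be expected to
recover them.

Two special fixtures exercise specific claims. `make_region_specialists`
builds five templates that are each *inaccurate* in one distinct
22-residue window (rigid 2.5 Å displacement, edge-tapered so the chain
stays connected): every region is correct in four of five templates, so
the thread consensus is accurate everywhere and recombination can beat
every individual thread. The window is deliberately spannable by one
segment swap (see the limitation above). `make_binned_family` builds
template sets at ~35/27/22/17% identity to the target with coordinate
noise rising from 0.6 to 2.5 Å RMS — emulating the empirical fact that
lower-identity homologs are structurally farther from the target — to
probe how model accuracy degrades with template identity.

What passing these tests does and does not show: the fixtures have
idealized geometry, smooth loops, uniform sequence statistics and
noise-model variation, so green tests demonstrate the *machinery* —
alignment recovery under indels and divergence, threading fidelity,
reproducible stochastic search, the multi-template benefit, monotone
identity/accuracy degradation — not crystallographic accuracy on real
receptors, which additionally requires real template geometry and a
full-atom energy function.

## Problem sizes

Default study conditions: receptors of ~206 residues (7×22 TM, loops
5/6/5/13/9/6, 4-residue termini); 10-member families at ~30% identity
with per-loop indel probability 0.3 and 0.3 Å RMS noise for alignment
recovery; 20 models × 3000–5000 MC steps for modeling runs; 6–8 models
per condition in the template-count and identity-bin experiments. These
sizes make a full pipeline run take seconds to a few minutes on one CPU
while keeping every statistic well away from small-sample artifacts.

## Known limitations

* Backbone atoms beyond Cα are pseudo-atoms; no side chains, no
  all-atom refinement, no membrane-potential term (span files are
  emitted for downstream tools but do not enter the score by default).
* The composite score is a stand-in: it selects segments that fit
  locally and globally but has no claim to physical energies.
* Flank-anchored swaps cannot cross defects much longer than `swap_max`
  in one move (see above).
* The structure-guided helix aligner assumes template TM coordinates are
  broadly correct; templates with multi-Å helix displacements can
  trigger spurious indel handling (visible in the lowest identity bin of
  the bin experiment, where it adds to the degradation trend).
* Ground-truth recovery is only claimed for structure-conserved columns;
  columns where geometry contradicts descent are excluded by definition.
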