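# Methods

This note documents the models, parameter choices and numerical decisions
behind `spermepi`, and what the synthetic-data generator does and does not
emulate.

## Coordinate model and I/O

All coordinates are 0-based, half-open (BED convention); any 1-based
dialect must be converted at the parser boundary. Peaks are consumed from
BED3/BED6/narrowPeak text (narrowPeak column 7, `signalValue`, becomes the
peak's mean density; the BED5 score column is ignored because it is not a
density). Coverage tracks are bedGraph step functions; bases not covered by
any segment read as 0, so interval averaging follows the `mean0`
convention: `mean = Σ(value × overlap bp) / width`. The developmental axis
is a single canonical table (Undiff, A1, B, pL, L, Z, mP, D, RS2, RS4, RS8,
LS, Sperm); every module refers to it rather than re-declaring order, and a
`StageSeries` is any ordered subset of it.

Spike-in normalization uses the minimum-count reference: with aligned
spike-in read counts `c_i`, sample *i*'s track is scaled by
`min_j(c_j) / c_i`, so the smallest sample is unchanged and all others are
scaled down. Any fixed reference count can be supplied instead; changing
the reference rescales all samples jointly and cannot change any ratio.

## Broad domains

Peaks whose gap (next.start − prev.end for half-open intervals; touching
peaks have gap 0) is at most `max_gap = 500` bp are consolidated by
transitive closure per chromosome. The 500-bp bound is inclusive. Merged
domains with width strictly greater than `broad_min = 5000` bp are broad;
the rest are regular. A domain is promoter-proximal when it overlaps any
TSS ± 2 kb window by at least 1 bp (the window is symmetric, hence
strand-independent); overlap rather than center-containment is the weakest
faithful reading of "positioned within 2 kb of the TSS" and is the
default. The sharp/control split ranks regular domains by mean density over
the domain ("peak height"), takes the top *n* = 500 (ties broken by
coordinate, so the split is deterministic), and draws an equally sized
control uniformly without replacement from the remainder under a caller
seed.

## Super domains (ROSE-style)

Peaks within `stitch = 12,500` bp are stitched with the same merge
machinery. Each stitched region's total signal is its mean density times
its width. Signals are sorted ascending, both the rank axis and the signal
axis are rescaled to [0, 1], and the cutoff is the signal at the point
where a line of slope 1 is tangent to the scaled curve from below —
computed exactly as the argmin of (scaled signal − scaled rank), which for
the convex curves that arise in practice coincides with the tangent point.
Regions strictly above the cutoff are super. A completely flat curve has no
strict exceedance, hence zero supers; the super set is invariant under
multiplying all signals by a positive constant. TSS exclusion is off by
default.

## NOMe-seq engine

Cytosine contexts are fixed by the sequence: WCG = (A|T)CG reads out
endogenous CpG methylation, GCH = GC(A|C|T) reads out GpC-methyltransferase
accessibility, and GCG/CCG are excluded from both because the two signals
are confounded there. Minus-strand contexts are read 5'→3' on the minus
strand; positions at sequence edges are unclassifiable. Sites are kept
per-strand (no symmetric collapsing) since GCH is inherently
strand-specific.

A site's level is `meth / (meth + unmeth)` and is defined only at depth ≥
`min_depth = 3`. (The source convention is stated both as "3× coverage" and
as "depth greater than three"; ≥ 3 is the default and the parameter is
exposed.) Region means are unweighted means over contained site levels and
require ≥ 3 sites. The genome background pools counts over all
depth-qualified GCH sites; candidate windows are not excluded from the
background because they are a vanishing fraction of the genome.

### NDR calling

Windows of 100 bp every 20 bp, anchored at coordinate 0 of each chromosome
(deterministic phase), are candidates when their pooled GCH rate exceeds
the background rate and the Pearson χ² test (1 df, no continuity
correction) on the 2×2 table [window meth/unmeth vs background
meth/unmeth] gives p ≤ 10⁻¹⁰. The test is two-sided; one-sidedness is
enforced as the rate-direction gate rather than by halving p. Degenerate
tables (a zero margin) return p = 1.

Overlapping or book-ended candidate windows merge into regions; counts are
re-pooled over the region's sites and the test recomputed at region level.
Because a run of significant windows overhangs the truly accessible run by
up to one window length per side, region boundaries are then refined in two
steps:

1. **Likelihood trimming.** Trim depths (a, b) — up to 32 sites per side —
   are chosen to maximize a two-component binomial profile likelihood in
   which trimmed terminal sites follow the background rate and the retained
   core follows its own maximum-likelihood rate. Ties favor least trimming,
   so a region whose terminal sites all support the enrichment is left
   untrimmed at the merged-window span.
2. **Midpoint clamping.** The true edge lies somewhere between the
   outermost retained site and the nearest flanking site, so each boundary
   is clamped to the midpoint of that gap, never extending beyond the
   merged window span.

The refined region is an NDR iff p ≤ 10⁻¹⁰ **and** it has strictly more
than 5 GCH sites **and** is strictly wider than 140 bp **and** its rate
exceeds the background. At the generator's default conditions the
refinement raises the mean planted-vs-called Jaccard from ≈ 0.79 (raw
window union) to ≈ 0.91 without affecting detection or specificity.

NDRs overlapping any TSS ± 1.5 kb window are proximal, otherwise distal.
(The source text mentions the TES once in this definition but defines the
window around the TSS; the TSS reading is used.) Cross-sample merging
unions NDRs within a 10-bp gap and is idempotent and order-invariant.

### Matrices and profiles

The 1-kb bin matrix holds per-bin mean levels per sample; a bin is dropped
unless it has ≥ 3 qualified sites in *every* sample. Gene-body metagene
profiles use 10 fixed 500-bp bins upstream, 100 fractional gene-body bins,
and 10 fixed 500-bp bins downstream, mirrored for minus-strand genes so bin
1 is always 5'; per gene and bin the value is the mean site level (≥ 3
sites), and the profile is the nan-mean across genes. TSS accessibility
profiles pool individual GCH site levels into 200 × 20-bp bins across TSS ±
2 kb windows (strand-flipped) and subtract the sample's genome-wide mean
GCH site level (the "basic line"). Hypomethylated domains have mean WCG
level strictly below 0.3; domains with < 3 WCG sites are indeterminate and
reported separately rather than counted as either class.

## Bivalency

A bivalent domain is an H3K4me3 peak with ≥ 1 bp overlap with any H3K27me3
peak (H3K27me3 peaks are typically broader, so the span kept is the
H3K4me3 peak's). A gene's promoter state at a stage is: bivalent if its
TSS ± 2 kb window overlaps a bivalent domain; else K4_only / K27_only /
none by which peak sets hit the window. A promoter hit by a K4 and a K27
peak that do not overlap *each other* is deliberately **not** promoted to
bivalent — peak–peak overlap is constitutive of bivalency — and is
reported K4_only with a `both_marks_nonoverlapping` flag. Trajectories are
tracked over the universe of genes bivalent in at least one analyzed
stage; the state matrix must be complete over that universe, and every
stage-pair transition table's total equals the universe size by
construction.

## Chromatin-state dynamics

Segmentations (BED4 with `E<k>` or bare-integer labels, 15 states by
default) must be sorted and non-overlapping per chromosome; gaps are
allowed and excluded from every denominator. The per-state variable-base
fraction between stages is **directional** (t → t+1): bases labeled *s* at
the earlier stage whose later label differs, divided by bases labeled *s*
at the earlier stage, both restricted to bases assigned in both stages. A
symmetric union denominator is available as an option. The per-state
numerators sum exactly to the total changed bases. State scores are
`score(k) = n_states + 1 − k` (state 1, active promoter, scores highest);
5-kb bins take the assigned-length-weighted mean score, and bins lacking
assignment in any stage are dropped. Sex-chromosome exclusion and
DSB-hotspot/PAR masking are supported via a chromosome whitelist
(`Segmentation.restrict`) and an exclusion BED (`Segmentation.exclude`);
no hotspot catalogue is bundled.

## Expression timing

FPKM < 0.5 (strict) is repressed. DE classes use the inclusive bounds
log₂FC ≥ 0.5 (up) or ≤ −0.5 (down) with adjusted p ≤ 0.05; DE tables are
inputs, never fitted here. Peak timing takes the argmax stage over RS2,
RS4, RS8, LS (ties resolve to the earliest stage); early = {RS2, RS4},
late = {RS8, LS}; all-zero genes are unclassified. The knockout
timing-shift summary counts early genes down at early stages, early genes
up at late stages, late genes down at late stages, and late genes up at
early stages; a gene counts once per category if it qualifies at any stage
of the category's set. The stage-specificity filter (max-stage FPKM ≥ 1.0
and ≥ 2.0 × the median of the other stages) is this package's explicit
stand-in for a criterion whose exact form is not published; both thresholds
are parameters. Distal domains are assigned to the gene whose TSS is
nearest to the domain center (floor midpoint) within 100 kb, ties to the
lexicographically smaller gene id. Enhancers are distal H3K27ac peaks (no
TSS ± 2 kb overlap), classed Broad_SEplus / Broad_SEminus / typical by ≥ 1
bp overlap with broad H3K4me3 domains and super-enhancers; eRNA
comparisons use two-sided rank-sum tests with classes of < 2 members
skipped.

## Synthetic data: what it emulates, and what it does not

The generator plants every structure the pipeline is designed to detect,
at what we take to be realistic desk-scale conditions, and records exact
ground truth:

- **Peak landscape** (demo: two 2-Mb chromosomes, 40 broad domains of
  5.1–20 kb and 400 regular peaks of 0.5–2 kb, entities separated by
  > 500 bp so planted structure is unambiguous). Broad domains appear only
  in configured stages (demo: mP, RS4) and are emitted as 1–3 sub-peaks
  with internal gaps ≤ 500 bp so the merge path is genuinely exercised.
  Half the broads carry a TSS at their center; filler genes live in a
  reserved peak-free tail of each chromosome so planted location classes
  are exact.
- **NOMe counts**: random sequence at GC 0.42 (mouse-like), so GCH sites
  emerge from composition at ~15-bp spacing and window-phase edge cases
  occur naturally; per site, depth ~ Poisson(10) and methylated count ~
  Binomial(depth, p) with p = 0.6 inside planted 300-bp NDRs and 0.1
  elsewhere (WCG sites at 0.75). Read-level bisulfite conversion is not
  simulated: every in-scope operation consumes counts, not reads.
- **Segmentations**: 200-bp bins; stage 1 from a mildly skewed state
  frequency vector; each later stage relabels a bin with its state's change
  rate (defaults 0.5–3% across the 15 states, overall ≈ 2% changed bases
  per stage step), new state uniform over the rest. The truth records the
  realized changed bases per state, so conservation can be asserted
  exactly.
- **Expression**: each gene peaks at one spermatid stage (peak FPKM 20,
  off-peak 2, multiplicative lognormal noise σ = 0.1); the knockout
  multiplies peak-stage FPKM by 0.5 and off-peak FPKM by 2.0 for an
  affected half of the genes. DE tables carry the planted noiseless fold
  changes with small adjusted p for effects crossing the thresholds and
  uniform p elsewhere — DE fitting is out of scope, so p-values are
  planted, not estimated.

What passing tests on these data do **not** show: robustness to
alignment/mapping artifacts, copy-number or composition biases, replicate
variability, fragment-level ChIP signal shape, or peak-caller behavior —
peaks, segmentations and DE tables are consumed as inputs here, exactly as
the surrounding pipeline produces them with external tools.

## Numerical choices and degenerate inputs

- χ² p-values come from the χ²(1) survival function on the Pearson
  statistic computed in closed form; tests verify agreement with an
  independent `erfc` formulation to 1e-10 relative.
- All tie-breaks are deterministic and documented (coordinate order for
  sharp peaks, earliest stage for timing, lexicographic gene id for
  assignment ties); reruns are byte-identical.
- Empty inputs raise (`merge` of nothing is allowed; a cutoff over < 2
  stitched regions, a background with zero depth, and an all-dropped bin
  matrix are errors); undefined quantities (region mean with < 3 sites,
  persistence from an empty state, a state with zero denominator) are
  reported as missing, never silently 0.
- Problem sizes were chosen so the full test suite runs in about a minute
  and the acceptance script in well under one: the largest simulation is a
  10-Mb genome for NDR recovery; all other stages run at the 2 × 2 Mb demo
  scale.

## Known limitations

- The variable-bases denominator and the stage-specificity filter encode
  choices the source text leaves open; both are parameters, and the
  defaults are recorded here rather than claimed as published values.
- `bigWig` binary I/O is out of scope; tracks are bedGraph text.
- The PCA/ordination decomposition itself is delegated to standard
  numerics downstream; this package only builds the matrices.
- NDR boundary localization is limited by local GCH site density: a
  planted region whose edge falls in a site desert is truncated at the
  evidence boundary.
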