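# Methods

## The measurement

A panel of inbred lines with recorded divergence history is a set of
parallel mutation-accumulation experiments. For each repeat class k and
line m the pipeline computes

    u_{k,m}        = (c_{k,m} − Â_{k,m}) / G_m          copies/generation
    normalized     = u_{k,m} / Â_{k,m}                   copies/generation/copy
    absolute       = |u_{k,m}|

where c is the line's observed genome-wide copy number (per 1× coverage),
Â the reconstructed copy number at the line's parent node, and G the
terminal branch length in generations. Because Â is reconstructed from the
same panel, net change underestimates the underlying mutational flux
(back-and-forth changes cancel); the rates are lower bounds by design.

## Repeat counting (`satrate.counter`)

Reads are scanned, without any genome alignment, for maximal tandem
stretches of every primitive unit of 1–20 bp. The detection contract:

- a stretch must span ≥ 50 bases of the read (`min_span`);
- interior copies may carry one substitution each, but only for units of
  3 bp and longer — for a 2-bp unit a "one-substitution copy" admits half
  of all dinucleotides and systematically absorbs sequence that is
  periodic at other unit lengths, and for 1-bp units the tolerance is
  vacuous;
- a single base may be inserted between two complete copies, or deleted
  from a copy (deletions again only for units ≥ 3 bp);
- the first and last complete copies of a stretch must match the unit
  exactly, and partial end copies extend the span only by exact prefix
  match. A terminal copy carrying a substitution is indistinguishable from
  flanking sequence; trimming to exact anchors keeps 49-bp stretches below
  the span threshold instead of letting random flanks push them over;
- at most 4 consecutive inexact copies are allowed between exact anchors.
  Trimming would discard a longer inexact tail anyway; the bound stops
  runaway walks through sequence that is periodic at a neighbouring unit
  length (e.g. period-5 arrays read as 6-mers with one deletion per copy);
- `N` never matches and is never absorbed as an insertion;
- per read, one best unit is counted: maximal total covered bases, ties
  broken by longer unit, then lexicographically smallest canonical form.
  Copies are floor(span / unit length), summed over the best unit's
  non-overlapping stretches.

Units are keyed by their canonical form: primitive period first, then the
lexicographically smallest string among all rotations of the unit and of
its reverse complement. Arrays with high internal divergence (> 1
substitution per copy) are under-counted; this is an accepted bias of
read-level detection.

The scanner is validated against an exhaustive-alignment oracle
(`scripts/oracles.py`) that applies the same contract at every offset and
unit length with no pruning; on planted arrays with ≤ 1% error the
reported unit must match exactly and copies within ±1.

## GC normalization (`satrate.gcnorm`)

Sequencing depth depends on fragment GC. Depth profiles are consumed as
per-chromosome tables of (GC bin, depth sum, site count) and pooled
depth-weighted (never mean-of-means). Default bin width 0.05: fine enough
to separate repeat classes (unit GC values are multiples of 1/|unit|),
coarse enough that every bin is well populated at genome scale. A unit's
raw count is divided by its bin's mean depth; a bin with no sites is
explicitly undefined and falls back to the genome-wide mean depth with a
logged warning, preserving the per-1× scale without inventing local bias.
Copy numbers are displayed rounded to integers; full precision is kept in
all arithmetic. A `normalized` flag prevents double correction.

## Phylogeny and rates (`satrate.phylogeny`)

Trees come either as newick with branch lengths already in generations or
as pedigree records (child, parent, split age in years). Ages convert at
4.33 generations/year — a husbandry constant; since all lineages share
it, relative comparisons are unaffected by its error — and round half-up
to whole generations. The deep split between the two strain families is
set from a config constant (default 850 generations of separation, split
equally between the two root branches) because year-based dating
underestimates it; that basal branch only sharpens ancestral states and
is never a rate denominator G.

Ancestral states under Brownian motion are the minimizers of
Σ_branches (Δstate)²/length with tips fixed — the maximum-likelihood
states — obtained by solving the weighted-Laplacian linear system over
internal nodes (exact, no iteration; agrees with a brute-force numeric
minimizer to < 1e−6 relative on random trees). States are not clamped at
zero; normalized rates are reported NA when the reconstructed ancestor is
below 1 copy. Reconstruction uses the full tree including the focal tip,
matching standard comparative practice; this shrinks |tip − ancestor| and
is another reason the rates are conservative. It also means a strongly
biased line bleeds a little signal into its relatives' ancestors — the
sign-test calibration is therefore measured on bias-free panels.

Per line, gains and losses across repeats (zeros excluded) are tested
against 50:50 with the exact two-sided binomial sign test; per unit,
normalized rates are summarized across lines and ranked by mean absolute
rate.

## Phylogenetic signal (`satrate.signal`)

Blomberg's K compares the tip variance about the phylogenetic mean with
the variance after whitening by the BM covariance of the tree, scaled by
its BM expectation; K ≈ 1 under BM, lower for tree-independent values.
Significance comes from shuffling tip labels (default 1000 permutations,
p = (1 + #{K_perm ≥ K_obs})/(n_perm + 1), seeded and reproducible).

The randomized-ancestor scan replaces each tip's ancestor with the
reconstructed state of a random internal node (excluding the true parent
by default, to maximize contrast) and averages the signed normalized rate
across tips and replicates. Units without phylogenetic structure give
similar, small statistics; clade-partitioned units (hundreds of copies in
one clade, near zero in the other) produce extreme values because tips
are normalized against other-clade ancestors. A unit is flagged as an
outlier when |statistic − median| exceeds the two-sided normal quantile
for a 1% nominal false-positive rate in robust MAD units. A
median/MAD rule was chosen over a pooled-percentile cutoff because the
statistic's across-unit distribution is contaminated by the very signal
units the scan must find; the robust centre ignores them.

## Satellite depth (`satrate.satellite`)

Complex satellites (e.g. 234-bp major, 120-bp minor, HOR-organized Ymin)
are quantified from per-position mapped depth over a multicopy consensus
construct (default 3 tandem copies, so junction-spanning reads map):

    copies = mean per-position depth × construct units / genome mean depth
           = total mapped bases / (unit length × genome mean depth)

The first and last construct units are excluded from the average
(boundary undercoverage), configurable. HOR satellites use the HOR length
as the unit, monomeric satellites the monomer — same estimator. A 31-mer
exclusivity check between two consensus sequences guards against
cross-mapping. Read mapping itself is delegated to standard aligners;
depth arrives as a TSV.

## Synthetic data (`satrate.simulate`)

The generator emulates the study design, not mouse biology:

- fixture tree: 14 tips in two clades of 7, terminal branches 64–294
  generations, 850 generations of separation at the basal split;
- copy-number evolution: per-generation Gaussian steps, variance
  σ²·copies (`variance_mode="copy"`), accumulated in 8 sub-steps per
  branch and reflected at zero. Copy-scaled variance mirrors the
  empirical tendency of change rates to grow with abundance, and makes
  the process multiplicatively skewed: losses outnumber gains even
  without drift. `variance_mode="constant"` (variance frozen at σ²·root
  copies) gives symmetric steps and is the fair-coin null used for
  sign-test calibration;
- hypermutators: designated tips get a signed drift (copies/generation/
  copy) on their terminal branch. Detection-power checks use a drift
  equal to 3 standard deviations of the branch's diffusion,
  b = 3σ√(copies/G)/copies;
- reads: 150 bp from a background genome (iid bases at GC 0.41) with one
  planted tandem array per unit, sampled uniformly with per-GC-bin
  acceptance multipliers and per-base substitution error; matching GC
  depth profiles are emitted so normalization is exactly consistent with
  the sampler. A deterministic tiled mode (`tile_stride`) emits
  evenly-spaced reads with systematic (noise-free) GC thinning, for
  recovery checks that should not carry sampling noise;
- satellite depth: Poisson per position with mean copies × genome depth ×
  unit/construct length, or exact means in noise-free mode.

What the generator does not emulate: real repeat sequence context,
paired-end structure, PCR duplicates, mappability, indel sequencing
errors, array interruptions and structure. Passing the recovery tests
shows the estimators are correct under the stated model, not that the
biases of real libraries are absent.

## Problem sizes and numerics

The test suite and the acceptance harness run on deliberately small
instances chosen to keep results stable: 100 random 6–14-tip trees for
oracle equivalence; 200 replicates × 50 units for rate-ranking recovery
(constant ancestral copies of 1000, σ log-spaced over 1.5 decades, so the
ranking reflects σ rather than abundance); 100 panels of 63 units for
power/calibration; 1000 planted reads for scanner-oracle agreement; 200
simulations for K calibration (99 permutations each); pipeline
determinism on a 4-unit, 2× coverage configuration. All randomness flows
from explicit seeds; identical seeds give byte-identical outputs
end-to-end (TSV floats serialized at 10 significant digits).

Known limitations: rates are net-change lower bounds; no mutation-process
model is fitted (copy-number dynamics over hundreds of generations are
not identifiable from endpoint data at this panel size); the counter
under-captures diverged arrays and reports one unit per read; exact
equivalence with other repeat-counting tools is not claimed —
the detection contract above is the specification.
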