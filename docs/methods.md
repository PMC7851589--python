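# Methods

## The problem

Bacterial chromosomes replicate bidirectionally from a single origin
(*oriC*; *repC*-family origins on large secondary replicons), so the two
replication forks define two replichores and a position's natural coordinate
is its distance from the origin along its own replichore. Many molecular
trends — gene expression, essentiality, substitution rate — have been
reported to vary along this coordinate. Testing whether *substitutions*
follow such a gradient is confounded by genome rearrangement: a locus
observed near the terminus today may have spent most of its history near the
origin. `oriscan` addresses this by reconstructing, at every internal node
of a phylogeny, both the ancestral nucleotide of each aligned column and the
ancestral genomic position of the block containing it, and by mapping each
inferred substitution to the origin-relative coordinate of the genome in
which it occurred.

## Coordinate transform

For a circular replicon with origin *o* and terminus *t* (1-based), a
position *p* on the arc from *o* to *t* in increasing coordinates (the right
replichore) gets distance `(p − o) mod L`; any other position gets
`(o − p) mod L` on the left replichore. The origin maps to distance 0 and
the terminus is reachable from both sides, with the two distances summing to
*L*. On linear replicons (e.g. *Streptomyces*-like chromosomes) replication
terminates at the chromosome ends; positions carry a signed coordinate
`p − o` (negative left of the origin) and regressions use its magnitude.
When no terminus annotation is available the antipodal midpoint
`((o − 1 + ⌊L/2⌋) mod L) + 1` is used, which is what "midpoint" accomplishes
for a replicon without a mapped *dif* site: equal replichore lengths.
Each position is assigned to the replichore that contains it, even when the
two arcs are unequal.

## Alignment hygiene

Inputs are locally colinear blocks (LCBs) from a rearrangement-aware
whole-genome aligner, in Mauve-dialect XMFA or per-block FASTA. Filters, in
order: (1) keep only blocks present in every analyzed taxon; (2) remove
columns whose gap fraction exceeds a threshold (default 0.2) — a simple,
documented stand-in for heuristic alignment trimmers, exposed as a config
knob; (3) keep only columns where every taxon is protein-coding with the
identical codon position (1/2/3, computed on the coding strand from the
annotations); (4) split each gene at gapped/ambiguous columns into segments
and discard segments under 100 ungapped bp (long enough to compare
reliably, short enough to keep most of the data); (5) for the selection
stage, trim segments to start on codon position 1 and end on position 3.
A gene crossing a block boundary is processed per block as separate
"genes". Reverse-strand genes are handed downstream reverse-complemented to
coding orientation, with position maps kept in forward genomic coordinates.

## Ancestral reconstruction

**Nucleotides.** Marginal maximum likelihood under HKY85 with empirical base
frequencies (one pseudocount per base) and a transition/transversion ratio
κ fitted by bounded 1-D likelihood maximization — by default pooled across
segments, since all segments share the tree and fitting κ per short segment
is noisy. Felsenstein's pruning algorithm computes per-column partial
likelihoods with per-column scaling; a preorder pass yields per-node
marginal posteriors; the max-posterior base is the reconstructed state, with
exact ties broken by the fixed order A<C<G<T and flagged. Columns missing a
base in any leaf are treated as missing data and excluded. No among-site
rate heterogeneity is modelled (rates enter the *analysis* only through the
spatial regression, and the reconstruction regime here is low-divergence).

**Positions.** Each block's per-taxon (start, strand) label is one
categorical character. Sankoff parsimony with unit change cost finds the
minimum-change assignments over observed labels; among minimum-change
assignments the one maximizing a likelihood with per-branch stay probability
`exp(−ρt)` and change probability `(1 − exp(−ρt))/(K−1)` is chosen, with ρ
fitted as parsimony changes per unit tree length (it matters only at ties
and is reported). Positions are reconstructed per block, not per column:
blocks move as units, and per-column reconstruction would be redundant and
could fragment within-block consistency. Per-column ancestral positions
then come from the position map of the leaf that donated the winning label.

**Events.** A substitution event is a (branch, column) where the
max-posterior parent and child states differ; multiple hits at one column on
different branches are all counted. Each event records both the parent
node's genomic position (the ancestral position, used for spatial mapping by
default) and the child's (available via config for sensitivity analysis);
the worked three-taxon example records both without prescribing which enters
the regression, and the parent is the coherent choice for "where the
substitution happened".

## Spatial statistics

The site table has one row per analyzed coding site: ancestral position
(the first event's parent position, or the root node's reconstruction for
substitution-free sites), transformed distance, event count, and the binary
indicator "≥1 substitution". The logistic regression
`logit P(indicator) = β0 + β1·d` is fitted by IRLS (convergence
|Δlog-likelihood| < 1e−8, ≤100 iterations; the design is standardized
internally because genome-scale distances make β1 ~1e−7); Wald standard
errors and p-values are reported, and separation yields a flagged result
rather than an exception. The per-site indicator is the default response
(the data are binary even though multiple hits are counted); per-(site,
branch) rows are a config alternative.

Window summaries divide substitutions by coding sites per distance window
(default 10 kb, both replichores pooled; per-replichore and signed-distance
tables are emitted for linear replicons). Outliers are Tukey fences
(beyond Q1 − 1.5·IQR or Q3 + 1.5·IQR, quartiles by linear interpolation) on
window densities; the literal reading "outside the interquartile range"
would discard half the data and contradicts the retained spread in plotted
densities, but is available behind a switch. Sites inside outlier windows
are excluded from the logistic fit; for selection, outliers are instead
flagged on per-segment ω (below). Windowed OLS of substitution totals on
window midpoints runs at 10/25/50/100/200/400 kb. The origin-shift
permutation refits the logistic model with the origin slid ±100 kb in 10-kb
steps (21 fits; a midpoint-rule terminus moves with the origin). The taxon
jackknife reruns block selection → reconstruction → regression with each
leaf pruned (branch lengths merged through the removed node), flagging
removals of root-adjacent leaves, the classic cause of sign flips.

## Selection

Per-segment dN and dS use Nei–Gojobori (1986) counting: synonymous site
fractions per codon position, differences apportioned over stop-free
shortest mutation paths, Jukes–Cantor correction `−(3/4)·ln(1 − 4p/3)`,
pairwise over all unordered taxon pairs with saturated pairs (p ≥ 3/4)
excluded. Counting is appropriate here because in the low-divergence regime
the method targets, per-site synonymous and nonsynonymous counts are small
and model choice has little leverage; the method name is stamped in every
output row. ω = dN/dS is undefined (not infinite) when dS = 0; such
segments are excluded from the length-weighted genome ω average but keep
their dN and dS in the rate averages. ω outliers (Tukey fences on defined ω
only) drag their dN and dS out of all downstream summaries. Genome
averages weight by segment length in bp; selection-vs-distance OLS uses the
transformed distance of each segment's midpoint in the reference taxon
(first taxon in the config), plus windowed-average variants at the same six
widths.

## The simulator

The generator emulates exactly the structure the analysis assumes, with
truth logs so every stage has a parameter-recovery test. Defaults (the
study conditions): 5 taxa on a clock-like random coalescent-shape tree of
root-to-tip height 0.02 expected substitutions/site; a 500-kb circular
replicon, origin at 1, antipodal terminus; ~85% coding in non-overlapping
genes of mean 900 bp built from sense codons on both strands; substitution
kernel with transition bias κ = 3; per-site rate `μ·exp(g·d)` with g = 0
unless a gradient is requested, evaluated in the *current* genome's
coordinates (a rearranged block acquires the rate of its new neighborhood —
precisely the coupling the method is designed to detect); purifying
selection as rejection of nonsynonymous proposals with probability 0.8;
rearrangement counts per branch Poisson-distributed with mean proportional
to branch length (0.5 per average-length branch, so rearrangements
accumulate over time like substitutions do, consistent with the
reconstruction's tie-break model), spans of 5–30 kb translocated to a
uniform locus and inverted with probability 0.3.

Rearrangement breakpoints induce the emitted block decomposition (blocks
are present in all taxa by construction; gene gain/loss and indels are not
simulated — the gap-handling filters are exercised with hand-built
fixtures). The truth ledger records every accepted substitution (branch,
root-site identity, position in the parent and child genomes, from/to base,
syn/nonsyn) and every rearrangement in application order;
``replay_truth`` reapplies the ledger to the root genome and must reproduce
every leaf byte-exactly. What passing recovery tests do *not* show: realism
of indel processes, horizontal transfer, alignment error, or rate
heterogeneity beyond the radial gradient — the simulator validates the
inference machinery, not the biology of any particular genus.

## Problem sizes and determinism

The recovery suites run the full pipeline on 500-kb, 5-taxon data sets
(≈60k true substitutions each) across 20 seeds per regime — large enough
that a rate doubling across a replichore is decisively detectable while a
null gradient stays null, and comfortably desk-scale (a few seconds per
seed). All randomness flows from a single integer seed through
`numpy.random.default_rng`; the analysis itself is deterministic, and
rerunning a report on identical inputs is byte-identical.

## Known limitations

* Position reconstruction chooses among *observed* leaf labels; a true
  ancestral position carried by no extant leaf is unrecoverable by design.
* Distant rearrangements shift the absolute coordinates of untouched
  blocks (excision/insertion offsets), so exact position recovery is
  evaluated on rearrangement-free branches; recovered positions elsewhere
  are accurate up to such offsets.
* The logistic model treats sites as independent; no spatial
  autocorrelation or mixed-effects structure is modelled.
* NG86 counting saturates near p = 3/4 and is not a substitute for ML dS
  at high divergence.
* Non-stationary base composition along the replicon (GC skew) is neither
  simulated nor modelled.
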