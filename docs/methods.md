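# Methods

This package implements a single-locus species-delimitation comparison:
given an aligned DNA-barcode matrix for a local assemblage, it delimits
specimens into molecular operational taxonomic units (MOTUs) with six
approaches and scores each MOTU partition against a reference
morphospecies partition.  This note documents the models, the
parameters that matter, the numerical choices, and what the simulator
does and does not emulate.

## Distance models

Pairwise distances use pairwise deletion: a site enters a pair's
comparison only when both residues are unambiguous bases (A/C/G/T).
Gaps, `N` and IUPAC ambiguity codes count as missing, never as partial
matches — the simplest defensible convention when chromatogram
disagreements are recorded as ambiguities.  Supported models, with `p`
the mismatch proportion and `P`, `Q` the transition/transversion
proportions over compared sites:

* `p` — raw proportion;
* `jc69` — d = −(3/4)·ln(1 − 4p/3);
* `k80` (the barcoder's "K2P") — d = −(1/2)·ln((1 − 2P − Q)·√(1 − 2Q)).

A pair is *saturated* when a logarithm argument is non-positive
(p ≥ 0.75 under JC69).  The default policy is a per-pair error, because
empirical barcode distances sit far below saturation and a saturated
pair indicates corrupted input; `saturation="cap"` substitutes a large
constant for exploratory work.  Summaries pool within-species pairs
(species with ≥ 2 specimens) and between-species pairs; the two
threshold counts use strict inequalities (species whose *maximum*
infraspecific distance exceeds t; species pairs whose *minimum*
interspecific distance falls below t — species pairs, not specimen
pairs, which the output documents).  The histogram uses fixed 0.01-wide
bins from zero; medians of even pools average the central order
statistics.

## Threshold clustering

Single linkage at an inclusive boundary: specimens i, j link whenever
d(i,j) ≤ t and MOTUs are the connected components, the semantics of the
classic `tclust` approach.  Default t = 0.03 on K2P distances, the
conventional 3% barcode gap.  Group labels are the lexicographically
smallest member id, so output is independent of input order.

## ABGD (barcode-gap discovery)

For each of 50 priors P log-spaced on [0.001, 0.1] (the web-server
defaults, with JC69 distances and relative gap width X = 1):

1. rank all pairwise distances;
2. scan gaps between consecutive ranked distances whose upper edge
   exceeds P, in rank order, and declare the first gap *significant*
   whose width exceeds X times the local average gap width (trailing
   window of up to 10 candidate gaps; the first candidate is compared
   against the mean of the remaining candidates) — scanning in rank
   order makes the lowest-distance gap win ties;
3. cluster by single linkage below the gap;
4. recurse inside every group (groups of < 3 specimens cannot show a
   gap and stop the recursion) until nothing splits.

The "best" partition is the one whose group count persists over the
longest consecutive run of priors, ties toward the smaller prior; the
chosen prior range is recorded in provenance.  The selection
deliberately omits closeness to the reference species count as a
criterion — that would be circular for de novo use — but the per-prior
scan is returned so a user can override manually.

## TCS statistical parsimony

Specimens are collapsed into haplotypes (comparing only mutually
unambiguous sites), haplotypes link when their nucleotide difference is
within the connection limit, and MOTUs are the connected components.
Full network topology (inferred intermediate haplotypes, loops) is not
reconstructed; component membership is all delimitation consumes.

The connection limit is the largest step count j whose probability of
parsimony is ≥ 0.95.  That probability is evaluated from a
truncated-Poisson argument under a Jukes–Cantor site model: with the
per-site substitution expectation μ obtained by inverting the observed
mismatch proportion j/m, the probability that an observed difference
reflects exactly one substitution is μe^(−μ) / ((3/4)(1 − e^(−4μ/3))),
and P_j is that ratio to the j-th power (joint over the observed
differences).  For the 658-bp barcode this gives a 95% limit of 9 steps
(~1.4% divergence), in the range barcoding practice reports for
COI-scale loci.  Different published implementations make slightly
different approximations here; the limit is frozen as a regression
value and delimitation behaviour, not the exact limit, is the tested
contract.

## PTP-family tree delimitation

A delimitation of a rooted tree with branch lengths in
substitutions/site picks a set of "species root" nodes forming an
antichain covering all tips.  Edges above the species roots form the
*speciation* class; edges inside them the *within-species* class.
Branch lengths in each class are exponential; with each rate at its
closed-form maximum n/ΣL, a class with n edges of total length S
contributes n·ln(n/S) − n to the profile log-likelihood (empty classes
contribute zero).

* **PTP** pools all within-species edges under one coalescent rate.
  The likelihood then depends on a delimitation only through (n, S) of
  the speciation class and is convex in S for fixed n, so the optimum
  over achievable S values lies at an achievable extreme; a
  knapsack-style DP over the tree tracks the exact min/max achievable S
  for every n with witness delimitations.  This search is therefore
  exact at every tree size, and is verified against brute-force
  enumeration on small trees.
* **bPTP-style support** comes from a Metropolis–Hastings walk over
  delimitations: uniform prior, proposals move one
  speciation/coalescent transition point one edge up or down, and the
  chain is driven by the profile likelihood.  Defaults are 100,000
  generations, thinning 100, burn-in 0.1, seed 123.  The support of a
  group in the ML delimitation is the fraction of post-burn-in thinned
  samples containing exactly that group.  A single seeded stream makes
  runs bit-reproducible.
* **mPTP** gives each species its own coalescent rate.  The
  within-species term is additive over species, so each node carries a
  Pareto frontier over (speciation length, within-species score) per
  speciation-edge count; the frontier DP is exact but worst-case
  exponential, so above 48 tips frontiers are thinned to a
  deterministic 24-point beam (endpoints always kept).  Exactness below
  that size is what the enumeration oracle tests.  Two further choices
  follow the behaviour of the reference multi-rate implementation:
  likelihood ties resolve toward fewer species, and a minimum
  informative branch length (`minbr`) excludes branches the locus
  cannot resolve from the likelihood.  The pipeline's default is
  1/alignment-length (one expected substitution on the locus); without
  it the per-species profile likelihood chases degenerate tiny-rate
  species inside tight coalescent clades and oversplits badly.

Zero-length branches (identical haplotypes) are floored at 1e-8
substitutions/site before likelihood computation.  Singleton species
contribute only their stem edge, which belongs to the speciation class.
Note that the exact multi-rate optimum is *not* guaranteed to coincide
with the generating species partition even under cleanly separated
simulation regimes: on the packaged easy-regime fixture its optimum
lumps the closest sister pair by a small margin (~0.08 log units), a
property of the model rather than of the search.

Trees come from the user (any rooted Newick with branch lengths; an
unrooted tree is accepted and midpoint rooted) or from the internal
neighbor-joining fallback, which warns that it is not a substitute for
a model-based ML tree.  Midpoint rooting places the root halfway along
the longest tip-to-tip path, breaking ties toward the lexicographically
smallest tip-name pair; all pairwise tip path lengths are preserved to
1e-9.  Monophyly classification calls a species monophyletic when the
MRCA of its tips subtends no other species' tips; singletons are
classed separately and species with specimens missing from the tree are
"untested".

## Partition agreement

N_match counts groups with identical specimen sets in both partitions;
the match ratio is 2·N_match/(N_MOTU + N_morph).  Ratios are computed
in full precision and rounded half-up to two decimals only in reports.
Per-species classes: *match* (specimen set equals one MOTU), *split*
(spans ≥ 2 MOTUs, each wholly inside the species), *lumped* (one MOTU
that also contains other species), *mixed* (any non-nesting overlap,
as non-monophyletic species produce).

## The assemblage simulator

The generator emulates a densely sampled single-locality assemblage:
56 species, 14 singletons, non-singleton sample sizes on 2–8 (mean
≈ 4.2, ≈ 190 specimens), a 658-bp locus under K80 with κ = 2.  It is
calibrated rather than free-running, so the knobs mean what they say:

* **Species tree** — a forward pure-birth (Yule) realization, rescaled
  so the mean tip-pair path equals 2 × `interspecific_depth` exactly
  (default 0.085, putting mean interspecific K2P near 0.17).  Species
  stems are floored at 0.25 × `interspecific_depth` and internal
  branches shrunk to restore the mean: distinct species never collide
  by accident, so identifiability is broken only by the explicit deep
  -split and haplotype-sharing knobs.
* **Within species** — a Kingman coalescent rescaled so the basal
  within-species divergence (tip-to-tip through the species ancestor)
  equals `intraspecific_depth` exactly (default 0.015; infraspecific
  means land near 0.015).  Species pendants are shaved by the
  genealogy height, so specimen-level divergences stay on the
  species-tree calibration.
* **Deep coalescence** — a configurable fraction of multi-specimen
  species (default 0.21, i.e. 12 of 56) carries a basal two-deme split
  with tip-to-tip divergence uniform on [0.04, 0.07]: past the 3%
  barcode gap by construction, topping out at the ~7% maxima seen in
  real assemblages.
* **Haplotype sharing** — with probability `sharing_prob` per
  multi-specimen species, one specimen is re-grafted as a zero-length
  sister of a specimen of the nearest other species.  This produces
  shared haplotypes and non-monophyly (introgression-like) with one
  parameter; truth labels keep the recipient species.

Two named regimes fix the study conditions for method evaluation: the
*easy* regime (no deep splits, no sharing, depths 0.005/0.15) separates
all species cleanly, and the *deep* regime raises the deep fraction to
0.5.  Simulation-based tests all use seed 42.

What the simulator does *not* emulate: rate variation among sites or
lineages (real data fit GTR+I+G-class models), explicit multispecies
-coalescent depth in ancestors (gene divergence equals species
divergence at the calibration points), selection, alignment error, or
missing data/ambiguity codes.  Passing tests therefore demonstrate
method correctness and the deep-coalescence failure mode, not
performance under every real-data pathology.

## Problem sizes and determinism

Default analyses run the full ~190-specimen assemblage end to end
(distances, all six methods, scoring) in well under a minute per
regime; the test suite uses the same scale plus small crafted trees
for the enumeration oracles (≤ 8 tips, where exhaustive search is the
reference).  Every stochastic component (simulator, MCMC) takes an
explicit integer seed and a single numpy generator stream; identical
(config, seed) reproduces outputs byte for byte.

## Known limitations

* The TCS probability-of-parsimony evaluation is a first-principles
  reconstruction; published implementations differ by a step or two in
  the connection limit at a given length.
* The mPTP beam above 48 tips is deterministic but not certified
  optimal; in practice it matches or exceeds the truth-partition
  likelihood on all packaged fixtures.
* ABGD's gap-significance rule has no single canonical published form;
  the trailing-window rule here is documented above and tested for the
  behaviours that matter (clean two-cluster splits, monotone group
  counts in the prior, recursion refining the initial partition).
* BIN-style service-side partitions are consumed as external files and
  scored; the underlying clustering algorithm is not reimplemented.
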