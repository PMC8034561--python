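# Methods

This note documents the statistical model, the algorithmic choices and the
simulation design behind `netsegmine`, including the places where the
design was genuinely open and what the test suite does and does not show.

## Data model

The input is a binary genotype matrix `D ∈ {0,1}^{n×d}` (samples ×
variants, dominant coding: carrier of at least one alternate allele → 1),
a binary phenotype `y`, an optional categorical covariate vector
`c ∈ {1..K}` (absent → one class, the stratified test degenerates to the
plain 1-df test), gene intervals (1-based, fully inclusive; GFF3 `gene`
features or a 4-column TSV) and an undirected gene–gene network. A
variant maps to a gene iff it lies within `window_bp` of the gene
interval on the same chromosome, on both sides regardless of strand; a
variant may map to several genes, and genes without variants are flagged
unrepresentable and their edges skipped. `window_bp` defaults to 0
(intragenic variants only) and is a required choice for real data — 50 kb
flanks are a common alternative for sparse marker panels.

## Patterns and encodings

A gene segment `(s, l)` is a run of `l` consecutive mapped variants
starting at the gene's `s`-th variant. Its heterogeneity encoding is the
columnwise OR; two segments from network-adjacent genes combine by a
second OR into the interaction encoding `w`. OR-encodings are monotone:
extending a segment can only turn 0s into 1s, so per-class supports
`x_k` never decrease along the sub-pattern → super-pattern order. This
single fact underlies both the closed enumeration and the pruning rule.

Closed enumeration skips a segment whose encoding equals that of an
immediate length-`(l−1)` sub-segment; under OR, equality with an
immediate sub-segment is necessary and sufficient for equality with any
deeper one, so only the two immediate sub-segments are compared.
Closedness is applied per segment, not to the combined interaction
encoding: two distinct segment pairs with identical `w` are both tested.
Interactions are enumerated in ascending total length `l1+l2` (ties by
`(s1,l1,s2,l2)`), which is a topological order of containment: every
super-interaction appears after all of its sub-interactions, so a
prunability verdict removes its whole subtree before any member is
materialised. (A nested per-gene loop, the more obvious order, violates
this guarantee across different start positions.)

## Test statistic

Association is measured with the Cochran–Mantel–Haenszel 1-df statistic
across the `K` per-class 2×2 tables, without continuity correction and
with the standard `n_k − 1` variance convention. Degenerate strata
(pattern or phenotype constant within the class, or `n_k = 1`) contribute
zero to numerator and denominator; an entirely degenerate table yields
p = 1, so such patterns can never be significant. In a single stratum the
statistic equals Pearson's chi-squared scaled by `(n−1)/n` — exact
equality with the classical test is not expected. The continuity-corrected
variant is deliberately not offered: the corner-minimisation argument
below relies on the uncorrected quadratic form. The 1-df upper tail is
computed as `erfc(√(t/2))`, identical to the chi-squared survival
function to ~1e−15 and much cheaper in the per-pattern hot loop.

## Minimum attainable p-value and prunability

For fixed margins the table collection has one degree of freedom, the
total `Σ_k a_k`; the statistic is a quadratic in that total, so its
maximum over all feasible cell counts is attained with every `a_k`
jointly at its upper or jointly at its lower bound. `min_pvalue`
evaluates exactly these two corners; the test suite proves equality with
exhaustive minimisation for all margin configurations with `K ≤ 2` and
class sizes up to 15.

A pattern is *prunable* at threshold δ iff every reachable margin vector
`x'` (`x_k ≤ x'_k ≤ n_k`, the consequence of OR-monotone supports) has
minimum p-value above δ. The statistic is a ratio of sums and is not
coordinatewise monotone, so no exact per-class envelope exists; the
implementation first evaluates cheap witnesses (the per-class optima
`n1_k` and `n_k − n1_k` clipped into the box, plus the box corners — a
witness at or below δ disproves prunability immediately and resolves
almost every call), and otherwise enumerates the reachable box exactly,
in chunks, with early exit. Correctness is defined by the quantified
condition and checked against brute-force box enumeration.

## FWER control

**Testability procedure.** The threshold `δ̂` starts at 1 and is lowered
along a strictly decreasing candidate grid (geometric, ratio 0.5, down to
1e−30 by default; for `K = 1` an exact grid of achievable minimum
p-values is available) whenever the running bound `δ̂·|T| ≥ α`, evicting
patterns whose minimum p-value now exceeds `δ̂`. Because `δ̂` never
increases, evicted patterns can never return, which is what makes the
control valid, and prunable subtrees stay prunable.

A coarse grid can overshoot: the first grid value satisfying the bound
may lie below the best admissible threshold, silently discarding patterns
that even a Bonferroni correction would have kept. The engine therefore
retains a one-grid-step cushion of near-testable patterns during mining
and, once all edges are processed, refines the threshold to the largest
*observed* minimum p-value `d ≤ δ̂_prev` with `d·|{p_min ≤ d}| < α` —
equivalent to having lowered along the finest possible grid. The Tarone
bound is unchanged (`d·|T(d)| < α`, and the final test level is
`δ* = α/|T|` as before), the result no longer depends on grid
granularity, and `δ* ≥ α/m` holds for any total hypothesis count `m`, so
the reported set always contains the Bonferroni-significant set. Pruning
and the cushion gate both use `δ̂_prev`, one grid step above `δ̂`, so the
refinement never resurrects a pruned pattern.

The phenotype is used only after mining finishes: the surviving testable
patterns are tested against `y` at `δ* = α/|T|` and reported sorted by
p-value with a fixed lexicographic tie-break, making runs bit-for-bit
reproducible and, in testability mode, invariant to the order in which
edges are processed (the final threshold is a function of the multiset of
minimum p-values).

**Westfall–Young light.** The permutation route draws `n_p` permuted
phenotypes up front (default 1000; a warning is emitted when
`α·n_p < 10`) and maintains the per-permutation smallest p-value across
all processed patterns; the empirical FWER at δ is the fraction of
permutations whose minimum is ≤ δ, and the final threshold is the lower
α-quantile of those minima (largest observed value whose empirical FWER
stays ≤ α; ties handled by explicit search, 0 if none qualifies).
Untestable patterns are skipped entirely — their minimum p-values exceed
the current threshold and are invariant under margin-preserving
permutations — and the suite verifies that the permutation minima are
bit-identical with pruning on and off. The printed form of the
threshold-lowering loop in the source algorithm lowers δ̂ when the
estimate is *already* compliant; the implementation follows the
accompanying prose ("lower while the estimate exceeds α"), the only
reading under which δ̂ moves toward compliance. The default permutation
scheme permutes `y` within covariate classes, which preserves every
`n1_k` and hence the exact permutation-invariance of minimum p-values
that the skipping argument requires; a global scheme is available for
sensitivity analysis but forfeits that exactness. One master seed drives
all permutations; the elementwise-min merge is associative and
commutative, so permutations and patterns may be processed in any order.

## Simulation design

`SimulationDesign` reconstructs the package's evaluation conditions. The
published values are the network size (75 genes, 100 edges) and the
association-strength semantics `p_s ∈ [0.5, 1]`; the remaining defaults
are this package's declared choices: 200 samples, 5 variants per gene,
background carrier frequency 0.2 (i.i.d. Bernoulli — dominant-coded
variants at minor-allele frequencies around 10% yield carrier rates of
this order), 2 balanced covariate classes assigned independently of
genotype and phenotype, and planted segment lengths (2, 2). One edge is
chosen at random, one segment per endpoint gene, and the phenotype is
drawn as `P(y=1|w=1) = p_s`, `P(y=1|w=0) = 1 − p_s`: symmetric flips
give an exact null at `p_s = 0.5` and a deterministic link at 1.
Genes are disjoint intervals on one chromosome (10 kb spacing, variants
100 bp apart), so window-0 mapping reproduces the generating structure
exactly. An optional first-order Markov mode (`markov_rho`) introduces
within-gene genotype correlation for robustness experiments.

In power experiments a replicate counts as a detection when a reported
interaction names the planted gene pair and both reported position ranges
intersect the planted segments; any other report is a false positive, and
on null data every report is. Per-replicate seeds derive deterministically
from a master seed.

What the generator does *not* emulate: linkage disequilibrium beyond the
optional Markov mode, minor-allele-frequency spectra, population
structure correlated with genotype (covariates are independent by
construction), missing genotypes, and gene-length variation. Passing
tests therefore demonstrate calibration and power under idealised
exchangeable conditions, not robustness to confounded real cohorts —
on real data the covariate vector must carry the structure correction.

## Problem sizes used in the checks

The suite's null-calibration experiment uses 200 replicates of a compact
design (100 samples, 20 genes × 5 variants, 30 edges, 2 classes) chosen
so the full 6750-hypothesis search runs in well under a second per
replicate; the same design with 200 samples drives the power checks
(50 replicates at `p_s = 1.0`, a 6-point `p_s` grid at 16 replicates).
Monte-Carlo slack of two standard errors is applied to both the FWER
bound and the power-monotonicity check. Oracle-equivalence checks run
exhaustively (all margins with `K ≤ 2`, `n_k ≤ 15`; 100 random genes for
closed enumeration; 50 random instances for pruning soundness; 10 for the
single-variant-pair equivalence).

## Known limitations

* Binary phenotypes and binary dominant-coded genotypes only; no
  genotype-likelihood handling, imputation or kinship estimation.
* The covariate vector is consumed as given; deriving it (e.g. clustering
  kinship eigenvectors) is out of scope.
* Only pairwise gene interactions along edges are mined, not larger
  modules; segments never span two genes and contain no gaps.
* Edges are processed sequentially; parallel edge processing would
  require a state-merge step that preserves final-state equivalence and
  is not provided. Permutation p-values for one pattern are computed
  vectorised instead.
* FDR control is not offered — the procedure is specifically built around
  familywise error.
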