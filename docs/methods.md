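# Methods

## Decisiveness

An internal edge `e` of a binary unrooted tree induces a four-way partition
of the tips: the two subtrees attached at one endpoint (A1, A2) and the two
at the other (B1, B2). A locus with taxon set Y can possibly inform `e` iff Y
intersects all four blocks; a locus meeting this condition is *decisive* for
the edge. Branchwise counts simply tally the decisive loci per internal edge
of the observed tree. Rooted inputs are handled on the unrooted view: the two
edges adjacent to a bifurcating root encode the same bipartition and are
counted once. All per-branch outputs are keyed by a canonical bipartition
string (sorted labels of the smaller side joined by `|`, lexicographic
tie-break at even splits), so independent runs are diffable.

Partial decisiveness *d* is the fraction of (tree, internal edge) pairs over
**all** binary unrooted labeled trees on the taxon set for which at least one
locus is decisive. "All possible trees" is read combinatorially, so the tree
distribution is uniform over labeled topologies, realized through the
insertion bijection: taxon k+1 attaches to one of the 2k−3 edges chosen
uniformly. Exhaustive enumeration is limited to 9 taxa (135,135 trees, under
a minute in pure Python with bitmask block tests); beyond that the Monte
Carlo estimator samples `n_trees` topologies, scores the per-tree fraction of
decisive edges, and reports the mean with SE = sd/√n_trees. Per-tree
fractions (not pooled edges) are the sampling unit, which makes the SE an
honest replicate-level error. An edge counts as distinguishable when ≥1 locus
is decisive (single-locus sufficiency); the groupwise variants of
decisiveness are out of scope. For nested coverages under the same seed the
estimate is monotone, since the sampled tree sequence depends only on the
seed and the taxon count.

## Quartet jackknife

Terminal branches carry no meaningful support and are skipped. For an
internal branch, each replicate draws one tip uniformly and independently
from each of the four blocks. Any topology for such a quartet either contains
the focal bipartition (t1t2|t3t4) or one of the two conflicting resolutions,
so the inferred quartet topology scores the branch without reference to the
rest of the tree. Note the quartet's internal path is exactly the focal edge:
the two tips drawn from A1 and A2 meet at one endpoint, the two from B1 and
B2 at the other. Support for short edges is therefore limited by the edge
itself, not softened by neighboring branches.

Columns where fewer than 2 of the 4 tips have data are dropped
(a character is "data" unless it is `-`, `?`, `N` or an unrecognized symbol;
partial ambiguity codes count as data). If fewer than `min_sites` (default 1)
retained columns have data for ≥3 tips, the replicate is *uninformative*: it
still records a uniformly random topology — mirroring what a tree search
forced to emit a resolved quartet does on contentless input — and is flagged;
an option retries fresh draws up to k times first, and ICA can be recomputed
excluding uninformative replicates.

The ML engine evaluates the three topologies by the pruning algorithm over
site patterns (identical columns share one evaluation). Branch lengths (four
pendants + internal) are optimized by cyclic per-branch bounded optimization
on [1e-8, 10] substitutions/site, at least two full cycles, stopping when a
cycle improves lnL by less than 1e-6. Two exact JC69-specific reductions keep
this fast without changing results: (i) JC69 is invariant under base
relabeling, so pure ACGT/missing columns are collapsed onto their
permutation-orbit representative before evaluation; (ii) with e = exp(−4t/3)
the per-site likelihood is linear in e for any single branch, making each
coordinate step a strictly concave 1-D problem solved by safeguarded Newton.
Both were verified against the direct pruning values and a brute-force
16-internal-state summation (tests keep those oracles). GTR (fixed,
user-supplied exchangeabilities and frequencies, eigendecomposition of the
symmetrized rate matrix) uses literal bounded Brent per branch. JC69 is the
default: for four taxa the topology decision, not model richness, is the
mechanism under study, and it admits an exactly testable engine.

Exact lnL ties (within 1e-9, as in the all-constant-columns case, where the
three likelihoods are structurally identical) are broken uniformly at random
and flagged. Per-branch RNG streams are derived as
SHA-256(seed ‖ bipartition-key) mod 2³¹, so tallies are invariant to
traversal order and to the `workers` setting; replicate-level RNG consumption
is independent of the memo cache (ML results are cached per sorted tip set;
random draws happen outside the cached computation), so caching cannot
change results. Quartets are drawn with replacement across the default 500
replicates per branch.

## ICA

With counts (c₀, c₁, c₂) over the three mutually exclusive resolutions and
pᵢ = cᵢ/n, the magnitude is M = 1 + Σ_{pᵢ>0} pᵢ log₃ pᵢ — one minus the
normalized Shannon entropy. The base is fixed at 3 because a quartet has
exactly three resolutions; zero-frequency categories contribute 0 (the
p log p limit). The sign is positive only when c₀ strictly exceeds both
alternatives; a tie with the best alternative is conservative (negative) and
flagged `tied`. Endpoints: (n,0,0) → 1, (0,n,0) → −1, (n/3,n/3,n/3) → 0.
With only two categories occupied at equal frequency the fixed base gives
M = 1 − log₃2 ≈ 0.369 rather than 0; the zero point is exactly the
all-three-equal case. Uninformative replicates are included in the
denominator by default, with an exclusion flag.

The support-vs-depth analysis is OLS of ICA on the branch's decisive-locus
count, over all branches and over a count window (exclusive bounds, default
5 < count < 25), reporting slope, intercept, r, r², the two-sided p for
slope ≠ 0, and per-count means/SDs. A constant response returns slope 0 and
r = 0 rather than the 0/0 ambiguity. The species-accumulation extrapolation
is `ceil((goal − current)/rate)` years from a base year (default 2012);
ceiling, because a partially completed year does not reach the goal.

## Monophyly and annotation

A family's monophyly is evaluated on the rooted input tree, as a working
taxonomy would be read: the family's tips present in the tree must equal the
leaf set of some node. Families with no tips in the tree are excluded from
the denominator; single-tip families cannot be rejected. A `rooted=False`
mode tests bipartition membership instead (clade status under some rooting),
which is invariant to root placement. Exemplars per (genus, locus) are the
longest records, ties broken by earliest deposition year then species name
(deterministic; any rule would do). Oldest-exemplar ages assign each tip the
minimum year over its exemplar records and each edge the minimum over its
descendant tips; the value is therefore non-increasing toward the root.
FigTree-ready NEXUS output maps branch values linearly onto a matplotlib
palette, with a default gray for unvalued branches.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not any particular dataset:

- **Trees**: Yule (rate 1, waiting times Exp(k·λ), final Exp(n·λ) stretch;
  expected total length (n−1)/λ) or coalescent; branch lengths optionally
  rescaled to a target root-to-tip depth in substitutions/site.
- **Sequences**: site-independent JC69 down the tree with per-locus rate
  multipliers (slow coding loci vs fast spacers); verified against the
  closed-form expected pairwise difference (3/4)(1 − e^(−4t/3)).
- **Missingness** is locus-major with clade bias — the two features of
  repository-derived matrices that make quartet overlap hard: per-locus keep
  probabilities from a two-component mixture (few high-q "workhorse" loci, a
  sparse tail) and, per locus, a random subset of mid-sized clades with keep
  probability multiplied by e^(−λ). When a target missingness is set, the
  probability matrix is rescaled to match it in expectation and cells are
  then drawn per locus by weighted sampling without replacement (Gumbel
  top-k) at the expected count, pinning realized character-wise missingness
  to the target up to per-locus rounding (≲0.1 pp at the default scale) for
  any seed. Cell-independent Bernoulli thinning would leave ~0.3 pp of seed
  noise and, more importantly, no taxon clustering.
- **Taxonomy**: families are disjoint clades obtained by repeatedly splitting
  the largest block; each perturbed family absorbs one whole child-subtree of
  an unperturbed donor clade's root. The donor remainder is its other child
  (still a clade) while the receiver provably is not one, so exactly the
  requested number of families is non-monophyletic — a ground truth the
  monophyly test must match family-for-family.
- **Records**: 1–3 species-level records per present cell; deposition years
  drawn as base + span·u^(1+3f) with f the locus's normalized sampling
  fraction, so well-sampled loci skew earlier (they accumulated first).

Presets: `tiny` (16 tips, 4×300 bp, no missingness), `default` (200 tips,
5 workhorse + 15 tail loci, clade bias λ=1, 96% target missingness),
`sparse96` (as default with a 35-locus tail), `structure32` (32 tips,
10×500 bp, no missingness). Tree depth is 1.0 for the sparse presets —
saturation of fast loci on deep branches is part of the regime being
emulated — and 0.25 for the clean recovery bundles: a quartet's per-site
signal scales as t_focal·e^(−(16/3)·depth), so depth ≈ 3/16 maximizes power,
and 0.25 keeps mean pairwise distances near 0.4 substitutions/site
(moderate divergence). Problem sizes (500 replicates/branch, 500 Monte-Carlo
trees, 200-tip default bundles) keep a full pipeline run under a minute on
one core while leaving replicate-count noise on ICA near ±0.04.

## What passing tests do and do not show

The generator omits alignment error, chimeric or misidentified sequences,
model misspecification (real data are not JC69), rate heterogeneity across
sites, and non-random taxon sampling by collectors. Recovery results on the
clean bundles are therefore upper bounds on what the pipeline would deliver
on real supermatrices; the sparse presets exercise the bookkeeping and the
decisiveness machinery under realistic coverage, not realistic substitution
processes. Quartet support on branches shorter than ~10⁻³ substitutions/site
is statistically unresolvable at desk-scale alignment lengths regardless of
implementation.

## Degenerate inputs and numerical choices

Ragged alignments, overlapping partitions, duplicate labels and tip-set
mismatches fail fast with the offending names. Taxa with no data at any
locus are retained but reported. Quartets with all-missing rows are handled
by the uninformative rule. d on fewer than 4 taxa is an error; enumeration
beyond 9 taxa points to the estimator. Branch-length bounds [1e-8, 10]
substitutions/site; lnL convergence 1e-6; tie tolerance 1e-9; newick output
uses shortest round-trip float formatting and orders children by smallest
descendant label, making tree files canonical.
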