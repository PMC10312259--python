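# Methods

## Probabilistic model

Each group (or condition) is modelled as a graph-generating process: an
l × l random adjacency matrix of possibly dependent Bernoulli link
indicators on the node set {0, …, l−1}.  The diagonal is part of the grid —
self-loops are legal link positions — so a directed static process has l²
candidate positions and 2^(l²) − 1 nonempty candidate subgraphs.  A process
is fully characterized by its subgraph occurrence probabilities
π(G) = P(all links of G present), where occurrence means containment: the
generated graph may have additional links.  Link labels (integer time lags)
are part of link identity; a dataset must be either entirely lagged or
entirely unlagged, because mixing the two would make identity ambiguous.

For two independent groups, the observed occurrence counts f₁(G), f₂(G) are
independent binomials; conditioning on f(G) = f₁ + f₂ makes the group-1
count hypergeometric under H₀: π₁(G) = π₂(G) (Fisher's exact test).  For
within-subject data the two conditions of a subject may be dependent; the
subjects' condition pairs are i.i.d., and conditioning on the discordant
count d(G) makes the A-only count Binomial(d, ½) under marginal homogeneity
(McNemar's exact test).  Two-sided p-values are twice the smaller tail.
The doubling can exceed 1, so values are capped at 1; the cap never changes
a rejection at any α ≤ 0.5.  Rejection is inclusive (p ≤ threshold).

Tail sums use exact integer arithmetic (`math.comb` numerators, one float
division), so p-values are exact to double precision and bit-reproducible.
The test suite cross-checks them against scipy's hypergeometric and
binomial distributions for every margin with n ≤ 30 at 10⁻¹².

## Testability and the correction factors

Both tests are discrete: given the conditioning margin there is a minimum
achievable two-sided p-value p\*.  For Fisher it is attained at a maximally
uneven feasible allocation (the implementation evaluates the two extreme
f₁ values; the suite verifies this against a full scan), and it is 1 at
f = 0 and f = n.  For McNemar it is min(1, 2·(½)^d).

* **Bonferroni** divides α by the number of conceivable subgraphs:
  2^(l²) − 1 (directed static), 2^(l(l+1)/2) − 1 (undirected).  For lagged
  data the conceivable-pattern space has no finite closed form, so the
  factor falls back to 2^|observed universe| − 1 with a logged warning.
  Correction factors like 2^100 − 1 are kept as exact integers; corrected
  thresholds that underflow to zero simply mean nothing is rejectable.
* **Tarone** uses K(α) = min{k ≥ 1 : m(k) ≤ k}, with m(k) the number of
  supported subgraphs whose p\* reaches α/k; p\* depends on G only through
  f(G) (resp. d(G)), so m(k) is computed from the multiset of margin
  statistics.
* **Hommel refinement (opt-in).**  The union bound behind Tarone's factor,
  FWER ≤ m(t)·t for rejection threshold t, does not require t = α/k with
  integer k.  The `hommel` method takes the best threshold
  t\* = max{t ≤ α : m(t)·t ≤ α}, searched over the achievable minimum
  p-values, the implied levels α/m(t), and α/K(α) (which guarantees it is
  never below plain Tarone's threshold).  Default remains plain Tarone.
* **Westfall-Young** estimates the α-quantile δ of the permutation
  distribution of the minimum p-value under the complete null: uniform
  group-label reshuffles preserving group sizes (between), or independent
  fair coin flips of each subject's condition pair (within), identity
  permutation always included and counted.  Per-permutation minima are
  taken over the candidate set T(1) = {supported G : p\*(G) ≤ α}.  This is
  exact rather than an approximation: T(1) membership depends only on
  margins that the permutation scheme preserves, and any subgraph outside
  T(1) has p > α ≥ δ in every permutation.

**Quantile convention.**  δ is the ⌊α·n_perm⌋-th smallest permutation
minimum; if ties would push the fraction of minima ≤ δ above α, δ steps
down to the next smaller distinct value (or to a degenerate 0 when
⌊α·n_perm⌋ = 0, as with n_perm = 1).  This guarantees the estimated
P(min-p ≤ δ) ≤ α.  Rejection is p ≤ δ; per-record adjusted p-values are
the fraction of permutation minima at or below the observed p.  The
adjusted p-value of an extreme observation can be as small as 1/n_perm and
may lie below the raw p — that is inherent to the permutation definition.

## Mining engine

Occurrence of an edge set is itemset containment, so candidates are
generated by depth-first search over the deterministically ordered universe
of *observed* edges (sorted by source, target, lag), each node extending
only with later-ordered edges.  Subgraphs containing an unobserved edge
have f = 0 and p\* = 1 and can never be testable, so restricting to the
observed universe is lossless.  Graphs are bitmasks over the samples;
support counting is AND + popcount.

Total support is anti-monotone, so a branch is pruned when its support
drops below σ(t) = min{f : p\*(f) ≤ t} for the operative threshold t (for
the within design the pruning bound is the minimum discordant count, valid
because d ≤ f).  Only the low-support side prunes: p\* is U-shaped in f, and
high-f untestables are enumerated but not counted testable.  The K(α)
search interleaves enumeration with the factor search: k starts at 1 and is
incremented whenever the running testable count exceeds k, tightening σ as
it goes; subgraphs skipped by a tightened bound are untestable at every
remaining level, so the final (K, m(K)) agree with explicit evaluation of
m(k) for k = 1…K (verified against an exhaustive oracle in the tests).
Significant sets are sorted by p-value with ties broken by the edge-universe
order, making results bit-reproducible.

`max_links` restricts mining to subgraphs of at most that many links, which
shrinks the search space and the correction factor; validity is unaffected,
but the restriction must be chosen before looking at the data.

## Synthetic data

The Erdős-Rényi generator samples every grid position independently with a
common density p, giving π(G) = p^|E(G)| — a closed form the tests check
against empirical frequencies.  Self-loops are included by default to match
the l² grid; a switch drops them.  The generator realizes the complete null
(equal densities) for FWER studies and the complete alternative
(p₂ = p₁ + e) for power studies.  Defaults mirror the validation study
conditions: α = 0.05, densities 0.1–0.3, effects 0.1–0.3, group sizes
20–40, 1,000 replicates, 10,000 permutations; every knob is overridable,
and the acceptance script uses group sizes {20, 40}, l ∈ {2, 4, 6} (WY:
{2, 4}), 500–1,000 replicates and 2,000 permutations — problem sizes chosen
to keep a full run in the minutes range on one CPU while leaving the
per-setting binomial standard errors small against the quantities compared.

The within-design null generator draws condition A as ER(p) and lets
condition B copy each A link with probability ρ, resampling it otherwise:
marginals are equal by construction (a valid complete null for any ρ) while
pairs are dependent for ρ > 0.  This generator is this package's own
construction for exercising the within-subject machinery.

What the simulators do *not* emulate: dependent links within a graph
(empirical networks show strong link co-occurrence, which raises testable
counts far above the independent-links prediction), inhomogeneous per-link
densities, and lag structure.  Passing FWER/power tests on ER data
therefore validate error control and relative power of the corrections,
not absolute power on real networks.  For the latter, the resampling tools
(`independent_links` per-edge empirical frequencies, `joint` bootstrap of
whole graphs) and `detection_by_effect` (detection frequency stratified by
empirical effect size |π̂₁ − π̂₂| and by min(π̂₁, π̂₂), in bins of 0.05)
operate on observed datasets.  Reported standard errors are binomial for
FWER, SEs of the mean for power counts, and naive across-subgraph SEs in
the detection tables — detection events of overlapping subgraphs are
correlated, and no covariance correction is attempted.

## Numerical and design choices

* Seeds: every sampler takes an integer seed (or numpy Generator);
  experiment harnesses derive per-replicate seeds from a `SeedSequence`, so
  runs are reproducible and replicates independent.
* Degenerate inputs: empty subgraphs are accepted by `occurs` and
  `count_support` (support n₁, n₂) but excluded from mining — their null is
  trivially true and p ≡ 1.  Datasets with no observed edges mine to an
  empty result.  α must lie in (0, 1) for mining; α = 0 in the permutation
  engine yields no candidates and no rejections.
* Undirected graphs store edges with source ≤ target; all downstream
  machinery is unchanged.
* The Fisher minimum-p is evaluated at the two extreme feasible
  allocations in O(1); the exhaustive-scan equality is a test invariant,
  not a runtime cost.
* `complement_dataset` flips every link position (unlagged data only) so
  that very dense networks can be mined through their sparse negatives.

## Known limitations

* Strong FWER control holds for Bonferroni and Tarone; the Westfall-Young
  procedure is guaranteed only under the complete null unless subset
  pivotality holds, which has not been established for subgraph mining.
  Weak control licenses the claim "the processes differ somewhere", not the
  localization of specific subgraphs.
* The permutation engine is the direct per-permutation evaluation over the
  testable candidate set; it is comfortably fast for the network sizes
  studied here (dozens of links, thousands of permutations) but does not
  implement across-permutation speedups for much larger problems.
* Enumeration cost grows with graph density and with link co-occurrence;
  `max_links` (or complementation) is the remedy for dense data.
* Exact integer tail sums are computed per distinct margin and cached; for
  sample sizes in the many hundreds a log-space implementation would be
  preferable.
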