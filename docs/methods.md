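# Methods

## Model

An uncertain graph 𝒢 = (V, E, P) assigns every edge of a simple
undirected backbone an independent existence probability P(e) ∈ (0, 1].
Under possible-world semantics 𝒢 is a distribution over the 2^|E| edge
subsets; a world G_i has probability
Π_{e∈E_i} P(e) · Π_{e∉E_i} (1 − P(e)). Per-node degree moments are exact
sums of Bernoulli moments over incident edges. Full distributional
properties (the degree histogram, graphlet counts) are estimated by
Monte-Carlo: S worlds are sampled, the largest connected component of each
is kept (ties broken toward the smallest node label, so extraction is
deterministic; this re-introduces variability in the order n that the
fixed node set would otherwise suppress), and means **E** and population
standard deviations **s** of order, size, degree histogram and the
count vector of all graphlets of order ≤ n_g are recorded. The target
envelope for generated graphs is the closed band **E** ± 2**s** — roughly
the central 95% of sampled worlds under a normal approximation.

A graphlet is a connected induced subgraph; orders 3–5 give 2 + 6 + 21 =
29 isomorphism classes, labeled M1–M29 by sorting (order, edge count,
descending degree sequence). This fixes M1 = open triplet, M2 = triangle,
M3 = 4-star, M8 = 4-clique, M29 = 5-clique; intermediate labels follow the
same deterministic rule and are documented by the catalog itself
(`graip.catalog.graphlet_types`). Any external per-type comparison should
match types structurally rather than by label, since no published
numbering of the non-anchored types is assumed.

## Counting

Labeled subgraphs on an ordered node tuple are encoded as bit-strings:
pair (v_i, v_j), i < j, maps to bit (j−1)(j−2)/2 + (i−1). All 2³ + 2⁶ +
2¹⁰ strings are classified once per process by brute-force minimization
over node permutations (≈ 0.1 s, cached in memory), after which
classification is a table lookup. The full counter enumerates every
connected node set of size 3..n_g exactly once (ESU-style exclusive-
neighborhood extension rooted at each node's minimum-index member).

Incremental updates use the same enumeration anchored at the
modification: an edge edit can only change instances whose node set
contains both endpoints, so those sets are enumerated (on the graph with
the edge present — a set may be connected only through it) and each is
classified twice, with the edge bit set and cleared; the difference is the
delta. A node edit only creates or destroys instances containing the
node. Exactness of these deltas against full recounts over randomized
edit sequences is the package's central correctness property and is
tested for all three maximum orders.

## Degree binning

A high-degree backbone node spreads its degree over many values across
worlds, so each per-degree mean falls below one node while any generated
graph must place an integer count there; unbinned bounds would then be
unsatisfiable. Degrees are therefore binned sweeping from the highest
observed degree downwards, closing a bin when its accumulated weight
reaches one (accumulation is done in raw-count scale, where the
threshold "total ≥ S" is exact, rather than in mean scale where float
rounding can leave an isolated peak a hair under weight one and collapse
the whole histogram into a single bin), when a run of unobserved degrees
ends, or at degree one. Degree 0 never occurs in the largest component
and is excluded. Runs of unobserved degrees become dedicated zero-weight
bins; afterwards boundary degrees occurring in fewer than 1% of samples
(mean occurrence < 0.01) are moved — weight included — into adjacent zero
bins, so bin widths stay stable as S grows. Width-one bins keep their
sampled stdev; wider bins get the minimal s for which weight ± 2s covers
⌊weight⌋ and ⌈weight⌉, i.e. s = max(weight − ⌊weight⌋, ⌈weight⌉ −
weight)/2, because the number of generated nodes in the bin is an
integer while the weight usually is not. The binned distribution envelope
is **E**_p = weights / E_n with s_p scaled the same way. When a generated
graph has degrees outside the binned range they are accumulated into the
nearest boundary bin, which registers as out-of-bounds rather than
crashing.

## Generator

Parameters (defaults): S = 10 000 samples (well past convergence for the
networks of interest); n_g = 5 (3 or 4 cut cost sharply on dense
targets); node_step = 5 (a node move changes several edges at once, so it
is proposed less often); w = 2/3 (balances the two cost terms in
practice); max_rej = round(0.02 E_m), floored at 1 (forces an acceptance
after that many consecutive rejections so the search cannot stall at the
band edge); seed graph = preferential-attachment graph with 20% of the
expected nodes and edges (small enough that its topology washes out;
scale-free like the biological targets). With max_s unset the loop runs
until the envelope is met; the bounds check runs at the top of every
iteration, including the first.

Node moves are gated by the logistic function 1/(1 + exp(−(n − E_n)/s_n))
(add when the uniform draw exceeds the gate), edge moves by the same gate
on (m·E_n/n − E_m)/s_m; the E_n/n rescaling prevents an off-target order
from dragging the density the wrong way. Zero stdevs (certain targets)
are floored at 1e−6, degenerating the gates into step functions. New
nodes anchor on an existing node drawn proportionally to degree; if the
anchor lies in a clique of order ≥ 4 the new node joins the largest
clique containing it (found exactly within the anchor's closed
neighborhood, truncated to the 12 highest-degree members on large
neighborhoods — the rule targets small dense groups); otherwise each
anchor neighbor is wired independently with the probability that makes
the anchor's expected local clustering equal the target's average global
clustering (clamped to [0, 1]). Targets with E_n < 5 are rejected as
degenerate: the 20% seed would be empty.

The cost is w·cost_p + (1−w)·cost_c. cost_p is the mean relative
deviation of the *reversed cumulative* binned degree distributions
(cumulating from the high-degree side tolerates an excess of low-degree
nodes matched by a missing high-degree tail, which is how high-degree
nodes form here); cumulative bins with zero target mass are skipped.
cost_c adds, for each graphlet type outside its band, log of C/E in base
1 ± f with f = 2s/E — the factor that maps E to the band edge — so a
count a whole band-width out costs one unit regardless of the type's
combinatorial volatility. Guards keep the term finite and monotone at the
edges of its domain: C = 0 below the band substitutes C = 0.5; a lower
base below 0.01 (f ≥ 1) is clamped; types with E = 0 contribute nothing
at C = 0 and use E floored at 0.5 otherwise; f is floored at 1e−6.
Candidate costs are computed from the incrementally updated count vector
and a degree-adjusted histogram; the modified graph is materialized only
on acceptance (rejected moves leave it untouched, forced acceptances
reset the rejection streak). Node and edge choices use O(1) swap-pop
registries so per-iteration work stays local to the modification instead
of growing with a per-step rebuild of node/edge lists.

RNG: one seedable stream drives everything; per step the gate draw comes
first, then proposal draws, and world sampling consumes edge draws in
canonical sorted-edge order — a seeded run is reproducible regardless of
storage order.

## SwapCon baseline

Step 1 draws round(E_n) degrees from the binned expected distribution
(bin midpoints, total degree forced even); step 2 builds a
configuration-model graph and projects it simple (self-loops/multi-edges
discarded, so realized degrees can only fall short); step 3 applies
degree-preserving double-edge swaps under simulated annealing with
initial temperature 0.01, cooling factor 0.99 per proposal, stopping at
5% energy, after round(E_m) consecutive non-accepted proposals, or at a
wall-clock cap. The energy is the mean relative deviation of graphlet
counts from their expected values, |C_i − E_i|/max(E_i, 1) averaged over
types — an interpretation chosen so the 5% threshold reads as 5% average
relative error; the counts are recomputed with the full counter per
proposal, which for swaps (two removals plus two additions) is typically
no slower than four anchored updates.

## Evaluation

Quality: unbiased squared MMD (Gaussian kernel) between per-graph
statistic vectors of the generated and sampled ensembles — normalized
degree histograms padded to the common maximum degree, or graphlet count
vectors (raw by default; no normalization convention is imposed, a
`normalize` option divides by the total). The bandwidth defaults to the
median pairwise distance of the pooled vectors, so absolute MMD values
depend on that choice and only orderings between generators are
comparable across studies. Batched scoring (10 × 100 by default) averages
the estimator over batches. Randomness: the ratio of 5th–95th percentile
spreads (linear-interpolation percentiles) of the diameter (largest
component) and the mean local clustering coefficient; a zero sampled
spread makes the ratio undefined and is reported as such rather than as a
number.

## Synthetic fixtures

The generators emulate the controlled-size experimental setup: ER and BA
backbones with the edge count pinned exactly to round(n·mean_degree/2)
(G(n,m) for ER; a BA draw adjusted by uniform edge insertions/removals),
edge probabilities uniform on (0, 1], and the n-node star with uniform
probability p whose hub (expected degree (n−1)p, variance (n−1)p(1−p))
is the canonical isolated-degree-peak case for the binning rules. They
reproduce sparsity, heavy tails (BA) and uniform uncertainty, but not the
structured confidence scores, correlated errors, cliques/complexes or
degree–confidence correlations of real interaction data — tests passing
on them validate the machinery, not biological fidelity of any
particular null model.

## Problem sizes used in the tests

The suite samples envelopes at S between 150 and 10 000 depending on what
the test measures (binning worked examples use the star at S = 3 000–
10 000; generator runs use an uncertain ER target n = 50, mean degree 4 at
S = 500 and BA targets n = 100–400 at S = 100–200). Incremental-counting
exactness is checked over ~200 randomized edits on ER graphs up to n = 60
across all three maximum orders. These sizes were chosen to keep the
whole suite in the one-minute range on a laptop-class core while leaving
every assertion at its stated strength.

## Known limitations

- Only simple undirected graphs; no directed or labeled graphlets.
- The envelope constrains binned degree fractions and graphlet counts,
  not the order/size directly; for weakly constrained (very uncertain)
  targets, graphs substantially smaller than E_n can satisfy it — the
  logistic gates bias toward E_n but the stopping rule does not require
  reaching it.
- Anchored enumeration is effective on sparse graphs; on dense graphs the
  neighborhood of an edit approaches the whole graph and a combinatorial
  counter would be preferable.
- Exact clique search in the node-insertion rule is truncated on
  neighborhoods above 12 nodes.
- The annealing energy of SwapCon is an interpretation (see above); other
  choices would change its convergence behavior.
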