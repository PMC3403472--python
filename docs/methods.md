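# Methods

## The inference problem

A physical protein–protein interaction is typically mediated by a contact
between one domain of each partner. Given an observed PPI network
*I = (P, E)* and per-protein domain compositions, the candidate set

D = {(Dᵢ, Dⱼ) : Dᵢ ∈ Pₘ, Dⱼ ∈ Pₙ, (Pₘ, Pₙ) ∈ E}

contains every domain pair that could explain at least one edge
(homodomain pairs included). Parsimony inference selects the cheapest
subset of D such that (almost) every edge contains a selected pair — a
weighted set cover. The package builds three variants of one linear
program over variables *d_ij ∈ [0, 1]* (one per candidate pair) and
*e_mn ∈ [0, 1]* (one slack per edge):

* **PE** (pure explanation): minimize Σ d_ij subject to
  Σ_{(i,j)∈(Pm,Pn)} d_ij ≥ 1 per edge. Every edge must be explained.
* **ILP**: the same cover constraints gain slacks,
  Σ d_ij + e_mn ≥ 1, with a budget Σ e_mn ≤ (1 − sd)·|E|. The parameter
  *sd* ∈ (0, 1] is the fraction of edges that must be explained; lowering
  it lets the model discard the least compressible (often least reliable)
  interactions.
* **WILP**: ILP with objective Σ w_ij d_ij, weights below.

All programs are solved as LP relaxations with the HiGHS solver
(scipy.optimize.linprog); variable and constraint order is sorted and
deterministic. Optima are integral in practice on PPI-like inputs; the
count of fractional variables (tolerance 1e-6) is always reported, and
predictions are thresholded at *d_ij ≥ 0.5*.

### Exactness of the relaxation

At sd = 1 (pure cover) the relaxation almost always attains the integer
optimum on sparse, mostly-single-domain instances; the test suite checks
this against an exhaustive subset-enumeration oracle on 200+ small random
instances. At sd < 1 the relaxation is a *lower bound* on the integer
optimum rather than an equal value: the real-valued slack budget
(1 − sd)·|E| can be spent fractionally across edges, and at the budget
boundary the optimal basis is generically fractional. The suite therefore
asserts exact equality in the pure-cover regime and the valid-bound
property at sd < 1. This distinction matters only for the objective value
at fractional budget boundaries; thresholded predictions remain
well-defined, and the fractional-variable count makes any non-integrality
visible.

## Triangle-derived weights

PPI networks have a clustering coefficient far above both an Erdős–Rényi
G(n, m) ensemble with matched size and a degree-preserving rewiring
ensemble. In the Watts–Strogatz definition used here (local value =
triangles/triples at a vertex, degree < 2 contributing 0; global value =
plain average over all vertices), low-degree vertices carry the largest
local contributions, so triangles through low-degree ("poor") proteins
are the structural signature of genuine complexes. Combined with the
disassortative mixing of PPI networks (hubs attach to poor nodes), edges
that close a triangle through a poor node — particularly edges joining a
poor protein to a hub — are the interactions most likely to be real.

Concretely: the degree range [d_min, d_max] is split into K equal-width
subintervals; a node of degree d falls in bin
min(K, ⌊(d − d_min)/width⌋ + 1), and when all degrees are equal every
node is assigned bin 1 (the weights then degenerate to 1 and WILP
coincides with ILP). For every poor protein P (bin 1) and every observed
edge (Pₘ, Pₙ) between two of P's neighbors, each candidate pair of that
edge receives weight 1/(1 + |s − t|), s and t the endpoint bins; a pair
spanning several such edges keeps the smallest weight, and the priority
set S is every pair that received one. With s = t the weight is 1 —
indistinguishable in the objective from a non-priority pair, but still a
member of S; this follows the set definition literally and is flagged
here because it is consequential at small scale, where degree ranges are
narrow. K defaults to 50 at interactome scale; at desk scale (hundreds
of proteins, degree range ≈ 1–20) K of about 5 keeps bin 1 wide enough
to contain wedge centers, and the sd/K sweep utilities expose both knobs.

## Randomization tests

**Parsimony essential.** T₀ is the PE optimum on the observed data; T is
the same quantity after destroying the PPI–composition co-organization
while conserving marginals, either by (a) permuting the global multiset
of domain tokens across protein slots of conserved sizes (a repair pass
swaps colliding tokens so no protein receives a duplicate domain — plain
permutation under set semantics would silently shrink compositions) or
(b) rewiring edges by attempted double-edge swaps (attempts =
10 × |E|; swaps creating self-loops or duplicate edges rejected; graphs
with no valid swap, e.g. triangles and stars, pass through unchanged).
P-values are Gaussian: fit mean and sd (n − 1 denominator) to the null
samples, report the lower tail Φ((T₀ − mean)/sd). Defaults: 200 shuffles.
A zero-variance null is reported as undefined rather than 0 or 1.

**Weight significance.** The observed statistic is TP — the number of
gold pairs among thresholded WILP predictions with the triangle weights.
The null redraws weights as i.i.d. Uniform(0, 0.5) on a uniformly chosen
candidate subset of size |S| and re-solves; the upper Gaussian tail of
the true TP against 500 such runs (default) measures whether the
*placement* of the discounts carries information beyond their count and
magnitude.

**PE scores.** LP-score: each cover constraint is kept independently with
probability r (edge reliability) and the pure-cover LP re-solved; a
pair's score is its mean LP value over 1000 runs (default). Empirical
p-values compare the observed LP-score per pair against the same score on
1000 degree-preserving rewirings of the network (compositions fixed;
pairs absent from a rewired candidate set score 0), counting the fraction
of rewirings with an equal or larger score. The pw-score combines this
with witness evidence — witnesses are interacting single-domain protein
pairs, which pin their edge's explanation to a single candidate pair —
as min(p-value, (1 − r)^w).

## Evaluation

Because structurally confirmed DDIs are scarce, only gold pairs that are
actually candidates count as recoverable:

sensitivity = TP / |gold ∩ D|,
fold change = (TP / Total) ÷ (|gold ∩ D| / |D|).

Fold change is precision relative to the gold density of the candidate
set; predicting all of D gives exactly 1, and the identity
fold_change · Total · |gold ∩ D| = TP · |D| holds exactly. At the scale
of the yeast DIP/Pfam data these denominators are 756 and 30394; the
suite verifies that every published (Total, TP) row reproduces its
printed sensitivity and fold change to two decimals under this reading —
the only reading of the fold-change formula consistent with all rows.

## Synthetic data generator

The generator draws data from the mechanism the inference assumes, so
recovery is well-defined:

* Each of n_proteins proteins receives ≥ 1 domains; counts are shifted
  geometric with mean `domains_per_protein` (default 1.5), and domains
  are drawn with a mild Zipf-like popularity (rank^−0.5), giving a
  promiscuous-domain tail and hence degree heterogeneity — hubs and poor
  nodes — without explicit preferential attachment and without letting a
  few domain pairs dominate candidate support.
* A fraction `planted_ddi_density` (default 0.02) of all domain pairs is
  planted as truly interacting, uniformly at random.
* Protein pairs sharing a planted pair become potential edges, subsampled
  to a `mean_degree` of 5 (≈ 500 edges at the default 200 proteins — LP
  solves take well under a second).
* Noise: `fn_rate` of true edges removed; `fp_rate` × (true edges)
  spurious edges added between proteins sharing no planted pair (when
  there are no true edges the budget falls back to the nominal edge
  count, so a pure-noise network is expressible).
* `triangle_boost` closes that fraction of wedges centered on low-degree
  nodes (bottom third of positive degrees) with explainable edges; when
  the endpoints share no planted pair, one is planted, keeping the "every
  non-spurious edge is explainable" invariant while enriching triangles
  through poor nodes the way complexes do.

Defaults are desk-scale study conditions. Two derived configurations are
used by the test suite:

* the default spec for the parsimony shuffle tests (a planted repertoire
  of ~40 DDIs explaining ~500 edges is dramatically more parsimonious
  than any shuffle);
* a *near-private cover* configuration for the weight-significance and
  WILP-vs-ILP comparisons: single-domain proteins, a domain universe
  larger than the proteome (n_domains = 220, density 0.012), fp_rate 0.4,
  triangle_boost 0.6. This reproduces the structural regime of real
  interactome data in which the weight test is informative: roughly one
  candidate pair per edge (so total predictions are nearly independent of
  the weights, and TP differences reflect *which* edges the budget keeps),
  low gold density among candidates, and a large false-positive fraction
  for the weights to discriminate against. In the opposite regime — a few
  promiscuous pairs covering hundreds of edges, gold density near one —
  the Uniform(0, 0.5) null mechanically predicts more pairs and the TP
  comparison is uninformative about the weights.

What the generator does **not** emulate: the exact degree distribution or
domain-frequency spectrum of any real interactome, protein abundance or
experimental ascertainment biases, and correlated (non-independent) noise.
Passing tests therefore demonstrate correctness of the machinery and the
direction of the published effects under the generative assumption, not
effect sizes on real data; interactome-scale absolute numbers (e.g. a
cover of 12663 pairs for the yeast network) require the original database
snapshots.

## Numerical choices and degenerate inputs

* LP: HiGHS via scipy, bounds [0, 1], deterministic ordering; budget RHS
  kept real-valued (LP semantics, not floored).
* Rounding threshold 0.5 inclusive; fractional count always reported.
* Self-interactions are dropped at load (the cover constraints index
  pairs of distinct proteins and the clustering statistics assume a
  simple graph); the load report counts them.
* Compositions are sets: domain copy number cannot change which pairs
  exist.
* Gaussian p-values use the sample sd (n − 1); sd = 0 ⇒ undefined flag.
* Degenerate binning (all degrees equal) ⇒ all nodes bin 1, S empty at
  K = 1 semantics, WILP ≡ ILP.
* The weight test refuses to run when S is empty (no triangle through a
  poor node touches any candidate), with a message pointing at K.
* Empty harmonized networks are legal (warning); empty candidate sets
  solve trivially to objective 0.

## Known limitations

* The sd < 1 relaxation bound discussed above.
* Weights are recomputed from the *observed* (noisy) degree sequence;
  heavy false-positive rates distort binning itself, an effect the paper
  regime shares but the generator can exaggerate at small n.
* The empirical p-value machinery re-solves ~n_networks × n_runs LPs and
  is the only piece that is expensive at interactome scale; run counts
  are configurable downward.
* Homodomain pairs are legal candidates throughout, but wedge closure in
  the generator never specifically favors them.
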