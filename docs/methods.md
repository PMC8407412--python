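# Methods

## The transition model

A community profile is a relative-abundance vector over a shared feature
space (OTUs or any opaque feature ids). Two communities are held to be one
"direct transition" apart when their similarity is *significantly high*
relative to the collection-wide background: among N evaluated pairwise
similarities, the threshold T_dt is the smallest value in the top
⌈αN⌉ (default α = 0.01, no interpolation — the rank-of-top-α reading).
Calibration requires N ≥ ⌈1/α⌉ so the requested resolution exists. For
large collections the full n(n−1)/2 enumeration is quadratic; a seeded
uniform subsample of pairs estimates the same quantile and the calibration
record flags `sampled=true`. Where a significance level for T_dt against
the between-habitat similarity distribution is wanted, the upper-tail
permutation p-value uses the add-one convention, p = (#{s ≥ T_dt}+1)/(N+1);
ties and the empty-exceedance case are therefore never zero.

The network connects each sample to its exhaustive top-k matches
(k = 100 default) whose similarity is ≥ T_dt. An edge exists when *either*
endpoint lists the other (union rule): the construction iterates a search
per query and links the query to its matches, so an asymmetric hit still
produces the edge; a mutual-top-k rule would drop such edges. All rankings
break score ties by ascending sample id, which makes the edge set invariant
under re-ordering of the input table.

## Similarity measures

The framework is measure-agnostic: any symmetric function of two
normalized profiles with values in [0, 1] and score 1 on identity plugs
in. Two measures ship:

- `braycurtis` (default): Σ_i min(a_i, b_i), the complement of Bray-Curtis
  dissimilarity for relative abundances. The matrix route computes it as
  1 − L1/2 via `scipy.spatial.distance.pdist`.
- `weighted_unifrac`: 1 − normalized weighted UniFrac (scikit-bio), for
  phylogeny-aware comparisons when a rooted feature tree is available.
  The backend requires integer counts, so fractions are projected onto a
  10^9 integer grid; the metric depends only on per-sample proportions, so
  the projection error is ~1e−9.

Because the measure is pluggable, published numeric thresholds do not
transfer between measures or datasets; T_dt is always recalibrated.

## Closures and bridging

A closure is a maximal set of samples mutually reachable by direct or
indirect transitions — a connected component, not a clique ("fully
connected" in the reachability sense). The largest component is the main
closure (ties broken by smallest lexicographic member), and its fraction of
all nodes is the headline connectivity statistic.

Bridging asks whether an external reference collection can reconnect two
separated closures. Every member of each closure is searched against the
reference (same k and T_dt as network construction); above-threshold hits
accumulate per side, and any reference sample reached by both sides
completes the bridge. When no overlap exists, each side absorbs its own
hits and searches again — critically, a side's search pool excludes only
the hits *it* has already absorbed, so two-hop chains (r1 near side A, r2
near side B, r1–r2 above threshold) are found in the second round. Rounds
are bounded (default 5) because the underlying procedure iterates until a
transfer sample appears or no side can grow; an empty result means the
reference holds no transfer node for that pair. On success the returned
set includes all absorbed reference samples, a superset of the minimal
chain that is guaranteed to merge the closures on rebuild.

## Network statistics

Shortest transition steps are unweighted edge counts (a direct transition
counts as 1); breadth-first search from each closure member covers all
pairs, and a seeded uniform pair sample bounds the cost on large closures
(sampled runs flag the diameter as a lower bound, since the true maximum
needs all pairs). The degree distribution includes isolated nodes in the
histogram but excludes k = 0 from the scale-free fit (log undefined); the
fit is least squares of log10 P(k) on log10 k over degrees with nonzero
count, requiring ≥ 3 distinct degrees, and reports Pearson r and the slope
−γ. Log base is irrelevant to r and to the slope. A perfectly flat
distribution has zero variance in log P(k); r is reported as 0 rather than
NaN. Robustness experiments retain a seeded uniform node subset per
(fraction, replicate) cell, take the induced subgraph, and recompute
main-closure fraction plus step statistics of the residual main closure.

Habitat transition frequencies count, per habitat h, within-habitat edges
toward both endpoints (within(h) = 2·E_hh/n_h) and cross-habitat edges
toward the h endpoint (between(h) = E_h·/n_h): an edge is a transition
available to each of its samples, which is one defensible reading of
"average direct transitions per sample". Mock-labeled control samples are
excluded throughout. The within-vs-between contrast across habitats is a
two-sided paired t-test.

## Habitat prediction

For sample a with network neighbors ranked by edge similarity (descending,
id-ascending on ties) and truncated to n = 10, habitat h_k receives weight
Σ_{j∈h_k} (n−j+1)·s_j normalized by Σ_i (n−i+1)·s_i. When fewer than 10
neighbors exist, n is the actual neighbor count, keeping all weights
positive. Mock neighbors are dropped before ranking. Isolated samples
abstain; leave-one-out evaluation counts abstentions as incorrect and also
reports them separately, and the mismatch matrix carries an `unassigned`
column so each row sums to its habitat's sample count. Self-labels never
leak into the evaluation because self-edges do not exist.

The habitat-connectivity recursion extends a measured within-habitat
assignment rate p to the probability that m habitats all join one network:
p(2) = 1 − p and p(m) = p(m−1)·(1 − p^(m−1)), the added habitat failing to
join only if all m−1 potential cross-habitat links fail. It is strictly
decreasing in m; at p = 0.8928 it falls below 1.5e−05 by m = 19.

## Roadmap

Sample-level distances are dist = 1 − sim. The first-level MST of the main
closure uses Kruskal with deterministic tie-breaking by (distance,
lexicographic id pair); Kruskal is implemented in-package with union-find
because the tie order is part of the contract (library MST routines do not
specify it), and it is verified against exhaustive spanning-tree
enumeration on ≤ 7-node fixtures. The habitat graph G′ has an edge
(h_i, h_j) iff the first-level MST contains at least one inter-habitat edge
between them, weighted by the arithmetic mean of those MST edges only (not
all network edges between the habitats); the roadmap is the MST of G′,
falling back to a minimum spanning forest with a warning when G′ is
disconnected.

Significance: each permutation replaces every roadmap edge's distance with
that of a uniformly drawn network edge connecting the same two habitats —
the pool is all direct-transition edges between the pair in the full
network, the most inclusive reading — and p = (#{perm_total ≤
roadmap_total}+1)/(n_perm+1) over 10,000 permutations by default. Ties
count against significance, so a habitat pair crossed by a single
above-threshold link contributes a degenerate null and drives p toward 1;
the test discriminates only when habitats are joined by many alternative
links. An edge with an empty candidate pool is an error naming the pair.

## Synthetic data generator

The generator emulates the one statistical feature the framework needs:
within-habitat similarity stochastically exceeding between-habitat
similarity, with controllable separation. The feature space is split into
a shared block (fraction `base_overlap`, default 0.3 of 100 features) plus
equal private blocks per habitat; each habitat draws a base composition
Dirichlet(1) over its block and samples follow
Dirichlet(concentration × base) on the same support. Defaults — 3 habitats
× 20 samples, concentration 300 — give mean within-habitat Bray-Curtis
similarity ≈ 0.8 against between ≈ 0.3, a separation in the range typical
of habitat-level 16S surveys; `base_overlap = 0` gives disjoint supports
and exactly zero between-habitat similarity, and concentration → ∞
collapses each habitat to identical replicates. Sequencing depth and
mapping rate are drawn uniformly from (5,000–50,000) and (0.85–0.99) so
generated samples pass the default quality filter (minimum 500 mapped
sequences, minimum 0.80 mapping rate, both inclusive).

Planted transitions: for each configured habitat adjacency, a chain of
convex-combination profiles runs from the first sample of one habitat to
the first of the other. For the default measure the consecutive similarity
of an m-step linear chain is exactly 1 − |p−q|_1/(2m), so the step count
starts at the closed-form bound ⌈|p−q|_1 / 2(1−T)⌉ and doubles until every
link verifies post hoc (which also serves any other measure). Chain
interiors are labeled with the nearer habitat. The generator does **not**
emulate ecological assembly dynamics, sparsity patterns, compositional
zero-inflation, or sequencing noise; passing tests show the graph-side
machinery behaves correctly under controlled separation, not that any
particular real survey is scale-free or monophyletic.

## Problem sizes and numerical choices

Test fixtures use 20–70 samples with full pairwise enumeration, all-pairs
BFS, and 10,000-draw permutations; these sizes make every oracle
(reachability by boolean matrix powers, Floyd–Warshall, full-sort top-k,
exhaustive spanning trees) exact and fast. Profile normalization is
validated to 1e−9 at construction and 1e−6 at similarity time; probability
vectors in prediction normalize to 1 within 1e−12. The quality-control
thresholds are inclusive lower bounds ("minimum" read as ≥). Zero
total-count samples are rejected at read time because relative abundance is
undefined. The table writer emits 12 significant digits, which round-trips
double-precision abundances to 1e−12.

## Known limitations

- Exhaustive O(n²) search; no approximate index. Desk-scale collections
  only — hundreds to low thousands of samples.
- The scale-free diagnostic is the log-log Pearson fit, not a rigorous
  power-law likelihood test; dense clustered fixtures can yield positive
  slopes, which the fit reports honestly.
- BIOM support covers the 1.0 JSON dialect only.
- Transition networks are undirected and time-free; no directionality or
  longitudinal modeling.
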