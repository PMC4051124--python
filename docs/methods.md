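# Methods

## Biological distance and the gene network

The network is an undirected weighted graph whose nodes are gene symbols
and whose edges are direct protein-protein interactions. Input confidence
scores are normalized into (0, 1] by dividing by a configurable scale
(default 1000, matching the STRING convention of integer scores in
1..1000). Duplicate unordered pairs collapse to the maximum score — the
conservative choice toward connectivity, and deterministic — and self-loops
are dropped with a logged count.

Scores are inverted into direct distances. The default inversion is the
reciprocal, d = 1/s: it penalizes weak interactions super-linearly and
leaves distances unbounded, which matches the long-tailed distance
distributions seen in practice; a gene connected only through low-confidence
edges ends up genuinely far from everything. The complement inversion
d = 1 − s + ε (ε = 1e−6, keeping perfect-confidence edges strictly
positive) is provided for sensitivity analysis; both are strictly
decreasing in the score, so rankings by a single direct edge agree between
the modes. The choice between the two is genuinely open — published
descriptions of score "inversion" do not pin down the functional form — and
the reciprocal is the default here.

The graph is undirected: physical binding is symmetric, and the reciprocal
p-value construction below presumes symmetric distances. Genes known to the
study but absent from the interaction table can be injected as isolated
nodes (`include_nodes`); they are reachable from nothing and rank last.

## Connectomes

Shortest distances and one minimizing route per target are computed with
Dijkstra's algorithm (networkx) from the core gene; edge weights are
strictly positive so the algorithm is exact. The connectome orders targets
by (distance, symbol) — the alphabetical tie-break makes output
bit-reproducible — with all unreachable targets after all reachable ones.
Per record:

- **rank**: ordinal 1..N over the N non-core genes.
- **p-value**: rank / N; unreachable targets get 1 regardless of rank. The
  rank-percentile definition is the minimal one that makes the null
  (targets drawn uniformly from the connectome) exactly uniform on
  {1/N, …, 1}; it is a relative, not inferential, quantity and is meant
  for ordering candidates, not for significance claims.
- **BRP**: min of the two directed p-values of the pair. A hub core ranks
  half the genome closely, inflating everything's p; the reciprocal
  direction restores contrast for peripheral targets. Symmetric by
  construction and never larger than either directed p-value.
- **ratios**: distance divided by the median and the mean of the *finite*
  distances of the connectome. Infinite distances are excluded — a single
  disconnected gene would otherwise destroy both statistics — and
  unreachable targets report NA ratios.
- **sphere**: ceil(10·rank/N), i.e. the rank decile (1–10). Deciles are the
  simplest percentile coarsening; nothing finer is warranted by the data.
- **degrees of separation**: the edge count of the reported
  minimal-*distance* route, not an independently minimized hop count. The
  route shown and the degrees reported therefore always describe the same
  path.
- The core gene queried against its own connectome is special-cased:
  distance 0, rank 0, route [core], degrees 0, p-value at the 1/N floor.

Computing BRP for a whole connectome costs one Dijkstra run per reachable
target (O(N) single-source runs); `build_connectome(..., with_brp=False)`
skips it, and `prioritize` computes BRP only for candidate rows — one
reverse run per candidate covers every core gene at once.

## Prioritization

Candidates resolve to network nodes by exact match first, then through the
alias table (symbols are upper-cased at read time, so case differences
never matter). Unresolvable candidates are reported in an `unresolved`
list, never silently dropped and never an error: real WES gene lists
routinely contain symbols absent from interaction databases, and the tool
should maximize discovery rather than stop. An alias mapping to two
different canonical symbols, by contrast, is a hard error — guessing would
silently corrupt a ranking.

Global mode reports each candidate once with the core gene minimizing the
chosen metric ("closest to any core"); per-core mode keeps every
(candidate, core) pair grouped by core. For a single core, ranking by
p-value and by distance give identical orders (p is monotone in rank, rank
in distance); BRP can reorder, by design.

Per-patient p-values are combined either as a plain product — appropriate
when each patient contributes an independent rank-percentile probability —
or by Fisher's method (upper tail of −2Σln p under χ² with 2k d.o.f.).
Both are monotone in Σln p and so rank gene sets identically; the product
is the default because it is the quantity with the direct "joint
probability of ranks this extreme" reading.

## Variant filter

Three rules, in order: (i) drop synonymous variants; (ii) keep variants
with frequency strictly below 1% in *both* population databases (the two
databases are named conjunctively in the filtering protocol, so both must
pass — equivalent to cutting the maximum); (iii) drop variants carried by
more than 0.6% of other-disease cohort patients, a guard against sequencing
batch effects and hypermutable genes. Boundary semantics: the population
cut is exclusive (`< 0.01`), the cohort cut inclusive (`≤ 0.006`, the rule
reads "more than"). A missing frequency parses as 0 and is kept: absence of
a database record must not discard a rare variant. The kept set is
independent of rule order and monotone in every threshold; only the
per-rule drop attribution (first failing rule) depends on the order.

## Synthetic benchmark

The generator emulates the premise that phenotype genes cluster: an
Erdős–Rényi background (default 500 genes, edge probability 0.02, scores
uniform in [0.15, 0.40)) carries a planted, fully connected module (10
genes, scores uniform in [0.70, 0.95)) containing both the core gene and
the causal candidate. Erdős–Rényi was chosen over a scale-free background
because its edge count is analytically checkable (binomial mean/variance);
an optional hub mode wires one node to 30% of the genome with high scores
to emulate the loss of contrast seen with highly central core genes. The
variant table has an exact composition — 25% synonymous, 25% common (both
population frequencies in [0.02, 0.20)), 10% cohort-frequent, the rest rare
nonsynonymous in distinct background genes plus one guaranteed-surviving
causal variant — so the filter's kept count is a known constant, and the
filtered gene list has exactly the configured candidate count (default
200). All randomness flows through seeded numpy generators; identical
configs give identical outputs, and fixtures are regenerated at test time
rather than stored.

The chance-level control ("degraded module") plants *nothing*: the network
is pure background and the causal gene is an exchangeable random node. This
is deliberate — if the module kept its clique structure but only background
scores, the causal gene would still hold a guaranteed direct edge to the
core (against a background edge probability of 0.02) and would rank far
above chance; only the fully unplanted network makes "mean rank ≈ half the
candidate count" the correct null prediction.

What the benchmark does *not* emulate: the real interaction network's
degree distribution and score calibration, alias noise, linkage between
variants, or per-patient variance in list size. Passing it shows the
pipeline recovers a planted proximity signal and is correctly calibrated
at chance when none exists — not that any particular real disease gene
will rank first.

## Numerical and degenerate-input choices

Distances are exact IEEE doubles; no rounding happens before output
(tables print 10 significant digits). Unreachable = infinite distance,
empty route, NA degrees/ratios, p = BRP = 1. Empty interaction lists,
empty candidate lists, no resolvable core, scores outside (0, scale], and
unknown effect classes are hard errors naming the offending value and,
for file input, the line number. Problem sizes in the test suite and the
acceptance script (100 oracle graphs up to 30 nodes, 300-node calibration
networks, 100 benchmark replicates of 500 genes) were chosen so the whole
verification runs in well under a minute on a single core while keeping
binomial/KS noise far from the decision thresholds.

## Known limitations

- The rank-percentile p-value ignores network topology beyond rank; a
  degree-preserving rewiring null would be stronger but is a different
  (and far costlier) statistic.
- BRP for large connectomes is O(N) shortest-path runs; precomputation or
  caching would be needed for genome-scale all-pairs use.
- Alias resolution is file-based and exact; no fuzzy matching of
  misspelled symbols.
- One minimizing route is reported even when several are tied; the
  alphabetical tie-break picks a deterministic but arbitrary one.
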