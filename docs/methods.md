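# Methods

`netsig` implements a network-topology approach to biomarker discovery for
case/control transcriptomics: score every gene in an interaction network
with twelve topological metrics, evaluate each metric's top genes as a
diagnostic panel, and select biomarkers with a composite index that fuses a
local community metric with a global connector metric.

## Node-scoring metrics

All metrics operate on an undirected simple graph of gene symbols.
Disconnected graphs are allowed everywhere; path-based sums run over
reachable nodes only.

**Local metrics** (a node's immediate neighbourhood):

- *Degree* — number of incident edges.
- *Clustering Coefficient* — `2e / (k(k-1))` for a node with `k`
  neighbours and `e` edges among them; `k < 2` scores 0.  High values flag
  members of densely connected communities (candidate functional modules).
- *MNC* — node count of the largest connected component of the subgraph
  induced by the node's neighbours.
- *DMNC* — `E / N^epsilon` over that same component (`epsilon = 1.7` by
  default), a density-corrected variant; components with `N <= 1` score 0.
  When components tie on node count, the one with more edges (then the
  lexicographically smallest node set) is used, so scores are
  deterministic.
- *MCC* — sum over all maximal cliques containing the node of
  `(|C| - 1)!`; if the node's neighbourhood contains no edges the score
  falls back to the degree (applied per node).

**Global metrics** (the whole network):

- *Betweenness* — `sum sigma_st(v) / sigma_st` over unordered pairs with
  endpoints excluded.  The doubling convention (ordered pairs) would scale
  every score by 2 without changing any ranking; unordered is pinned so
  tests can assert exact values.
- *Stress* — the count (not fraction) of shortest paths through the node,
  same pair convention.
- *Closeness* — reciprocal-distance (harmonic) form `sum_w 1/d(v, w)`;
  unreachable pairs contribute 0, which makes the definition uniform on
  disconnected graphs.
- *Eccentricity* — maximum distance to a reachable node, per component;
  singletons score 0.  Raw eccentricity is largest for peripheral nodes;
  `top_k(..., ascending=True)` is available when a centre-first ranking is
  wanted.  The descending convention is the default.
- *Radiality* — per component, `sum_w (diam + 1 - d(v, w)) / (n_c - 1)`
  with `diam` the component diameter and `n_c` its size.
- *Bottleneck* — for every source `s`, grow a BFS shortest-path tree and
  give `v` one point if more than `bottleneck_fraction` (default 1/4) of
  the tree's nodes reach `s` through `v` (the subtree of `v`, itself
  included; the source never scores in its own tree).  The BFS parent is
  the lowest-sorting neighbour among those one step closer to the source,
  so trees — and therefore scores — are reproducible.  Where several
  equally short trees exist, the score genuinely depends on this choice.
- *EPC* — edge-percolated component: each realization keeps every edge
  independently with probability `epc_retention` (default 0.5) and the
  node scores the number of *other* nodes still reachable; the score is
  the mean over `epc_realizations` (default 1000) seeded realizations.

Tie-aware selection: `top_k` returns every gene tied with the k-th score
(so nominal top-10 lists may be longer), with a secondary alphabetical
sort making order deterministic; equal scores share a rank.

## Panel evaluation

Per-gene diagnostic value is the oriented Mann-Whitney AUC,
`P(case > control) + 0.5 P(tie)`, reported as `max(a, 1 - a)` because
informative genes may be down-regulated.  The chosen orientation is
recorded; validation data should be scored under the training
orientation rather than re-auto-oriented, which would bias validation
upward (auto-orientation on null data already yields AUC ~0.53 at
n = 40+40).

A panel's *integrated AUC* z-scores each member gene across samples,
averages the z-scores per sample, and takes the AUC of that aggregate.
The aggregator is a plain mean; the panel-score function is the single
place to change if a weighted variant is wanted.  For m independent genes
with a common shift `delta` against unit noise the aggregate is normal
with shift `delta` and variance `1/m`-scaled, giving the closed form
`AUC = Phi(delta / sqrt(2/m))` used by the simulation tests.  Correlated
panels (shared latent factor) gain less from averaging — the synthetic
generator's `factor_loading` exists precisely to exercise this.

`greedy_signature` grows a panel along a ranked gene list and reports the
integrated AUC of every prefix plus the smallest prefix achieving the
peak.  `precision(selected, reference, k)` is the fraction of a selected
top-k that appears in the first k entries of a reference ranking.

## Composite selection and the C-Index

A composite fuses the tie-aware top-k sets of two or more metrics
(default component k = 10), ranks the union by individual oriented AUC
(unscored members last, alphabetical; AUC ties alphabetical), truncates
to the selection size, and evaluates integrated AUC plus precision at
selection sizes 10 and 20.  Ranking the union by per-gene AUC is the
reading of "top genes of the superset" that reproduces the published
70% worked example from the published tables alone, so it is pinned.

The *C-Index* is this procedure with Clustering Coefficient and
Bottleneck as components: one local metric that finds dense communities,
one global metric that finds the cut points connecting them.  The
enumeration helper imposes no redundancy exclusions (e.g. it will happily
evaluate Betweenness together with Bottleneck even though they capture
similar structure).

## Packaged reference tables

The package ships the printed per-metric top-gene lists, the overall
AUC-ranked gene table (19 rows), and the per-metric panel-AUC summary as
TSV data, stored exactly as printed.  Four symbols are typos in the
source tables (`CNNB1`, `NUSAP`, `PTRB`, `Il6`); the corrections ship as
a separate data file applied at load time, so analyses can run with or
without normalization.  `KIAA0101` is kept as printed (a dated but valid
alias).  The worked example — 70% precision for the Clustering
Coefficient + Bottleneck composite, 11% panel-AUC improvement of
Clustering Coefficient over Degree — is recomputed from these tables by
`scripts/acceptance.py` and by the acceptance tests.

## Differential-expression screen

The screen keeps genes with two-sided `p < 0.01` and `|logFC| > 1.2`
(strict inequalities, matching the printed thresholds), where logFC is
the case-minus-control difference of log2 group means.  P-values come
from a per-gene Welch t-test; a moderated backend can be substituted by
passing any per-gene (p, logFC) table to `screen_table` — the package's
contribution is downstream of the screen, so the plain test suffices and
keeps the screen dependency-free.  BH FDR is computed over all tested
genes.  The gene-set direction z-score is
`(N_up - N_down) / sqrt(N_up + N_down)` over a set's differential genes;
"count" is read as `N_up + N_down` (set members that are not
differential do not enter).

## Synthetic benchmark

`SyntheticConfig` defaults define the benchmark used throughout the
tests: 2 modules of 15 genes (intra-module edge probability 0.6) joined
by 1 cut-vertex bridge, 10 hub decoys of degree 14 attached to pairwise
non-adjacent background genes, 20 background genes wired among
themselves at probability 0.01, a 40 vs 40 cohort, a 1.0 log2-unit
down-shift in cases for module members and bridges, within-module factor
loading 0.5, and unit Gaussian noise.  Down-shift is the default effect
direction because the motivating disease signatures are down-regulated;
`effect_direction="up"` flips it.

Sizing rationale (chosen once, as the benchmark's design):

- decoys out-degree every module gene, so a Degree ranking is dominated
  by uninformative decoys;
- decoys attach only to background genes: wired into modules they would
  become genuine global connectors (and could merge components), which
  would defeat their purpose as *decoys* and break the bridge
  cut-vertex guarantee;
- the background + decoy component (30 nodes) is strictly smaller than
  the bridged two-module component (31 nodes), and every non-bridge node
  of that component routes a whole module through the bridge, so the
  bridge's bottleneck score (30) exceeds anything attainable in the
  background blob (at most 29) — bridge recovery is structural, not
  statistical;
- the 1.0 log2-unit shift keeps panel AUCs away from 1.0 at n = 40+40,
  so composite comparisons measure selection quality rather than
  saturating.

Decoy targets are found with a low-degree-first greedy independent-set
search (optimal on the forest-like sparse background); genuinely
infeasible configurations raise an error.

Expression follows `x_gs = mu_g + loading * F_{m(g),s} + eps` with
`mu_g ~ N(8, 1)` (log2-intensity scale), one latent factor per module,
and `eps ~ N(0, noise_sd)`.  What the generator does *not* emulate:
heavy-tailed or count-based expression, batch effects, scale-free degree
structure, or overlap between modules — passing tests show the selection
machinery recovers the planted structure it assumes, not that it is
robust to everything real cohorts do.  All randomness flows from one
seed through two spawned child streams (graph, expression), so the graph
is unchanged when only the cohort size changes.

## Cascading stage classifier

The cascade classifies case vs. control, then true cases into early
(stages I-II) vs. late (III-IV) — the early/late boundary is not
standardized upstream; I-II/III-IV is the conventional split and is
pinned here — then the stage within each branch.  Levels 2 and 3 train
on *true* subsets (not on upstream predictions), which keeps every level
independently testable; routing at prediction time guarantees a
control-called sample gets no stage and a predicted stage matches its
branch.  A level that sees a single class degrades to a constant
predictor with a warning.  The learner is injected through the
scikit-learn `fit`/`predict_proba` protocol; the default is an
L2-regularized logistic scorer, and the tests also exercise a
depth-limited decision tree.  Level metrics are computed on the samples
that truly belong to each level; end-to-end stage accuracy is bounded by
level-1 accuracy (a mis-routed sample cannot receive its true stage).

## Pipeline and reproducibility

`run_pipeline` chains screen, scoring, per-metric top sets, composite
evaluation, C-Index selection, greedy signature and cascade report into
one output directory with a manifest of SHA-256 artifact hashes.  Every
tabular output carries a header with the package version, seed and a
hash of the configuration (output directory excluded, since it does not
affect the analysis).  Reruns with the same configuration reproduce all
artifacts byte-for-byte; the only stochastic metric (EPC) is seeded from
the run seed.

## Numerical and testing choices

- Z-scores use the sample standard deviation (ddof = 1); constant genes
  cannot be z-scored and are dropped with a warning.
- The stratified split takes `ceil(fraction * n)` per group, clamped to
  `n - 1` so validation keeps at least one sample per group.
- Metric correctness is established against brute-force oracles
  (explicit path enumeration, pivot-free clique enumeration, explicit
  tree-descendant walks) on random graphs up to n = 25, exactly for
  integer-valued metrics and to 1e-9 otherwise.  The EPC cross-check
  runs both implementations on identical percolation samples (common
  random numbers), making the component-count comparison exact;
  independent-stream behaviour is verified against closed forms
  (retention 0 and 1, and the single-edge expectation p).
- Bottleneck and EPC are excluded from the node-relabeling equivariance
  test: their deterministic tie-breaking/sampling is label-dependent by
  construction.

## Known limitations

- The Welch screen is not a moderated test; at very small n it is
  conservative relative to empirical-Bayes alternatives (the interface
  accepts external tables for that reason).
- Bottleneck scores depend on the deterministic BFS tree in graphs with
  equal-length alternative paths; rankings are stable but not unique
  mathematically.
- MCC enumerates maximal cliques and is exponential in the worst case;
  it is intended for DEG-scale networks (hundreds of nodes), not
  proteome-scale graphs.
- The composite-evaluation reference ranking and the union ranking are
  computed on the same cohort; on small cohorts this couples their
  noise.  Held-out evaluation via `split_train_validation` with locked
  AUC orientations is the supported remedy.
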