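# netsig

Topological scoring of gene-interaction networks and composite biomarker
panel selection for case/control transcriptomics.

Hub genes found by Degree — the most common choice in network biomarker
studies — are often not the genes that best separate cases from controls:
a node can have many neighbours without sitting in a functional community
or on a critical signalling route.  `netsig` implements twelve node
scoring metrics (local: Degree, MCC, DMNC, MNC, Clustering Coefficient;
global: Betweenness, Bottleneck, Eccentricity, Closeness, Radiality,
Stress, EPC), evaluates each metric's top genes as a diagnostic *panel*,
and selects biomarkers with the **C-Index**, a composite of the top local
and top global metric:

```
C-Index = N_top( S_clustering_coeff  ∪  S_bottleneck )
```

where `S_m` is the tie-aware top-k gene set of metric `m` and `N_top`
takes the top genes of the union after re-ranking by individual AUC.
Panels are scored with the **Integrated AUC** — the AUC of the mean
per-gene z-score — and with **Precision** = `N_correct / N_total` against
a reference list of top disease-correlated genes.  A planted-structure
synthetic benchmark (dense modules, cut-vertex bridges, non-clustered hub
decoys), a Welch/BH differential-expression screen, a greedy
signature-size search, and a three-level cascading stage classifier
(cancer/control → early/late → stage I-IV) round out the toolkit.

## Worked example

The package ships the reference tables of the motivating study as data:
the per-metric top-gene lists, the overall AUC-ranked gene table, and the
per-metric panel AUCs.  Reproducing the published composite worked
example takes a few lines:

```python
import netsig as ns

fx = ns.load_fixtures()
union = ns.build_superset({m: fx.table1a[m]
                           for m in ("clustering_coefficient", "bottleneck")})
top10 = ns.rank_union(union, fx.auc_by_gene).genes[:10]
hit = ns.precision(top10, fx.top_auc_genes(10), 10)
print("union size:", len(union))
print("top-10 of union:", ", ".join(top10))
print(f"precision vs overall top-10: {hit.n_correct}/{hit.n_total} = {hit.precision:.0%}")
cc, deg = fx.table2["clustering_coefficient"][0], fx.table2["degree"][0]
print(f"clustering-coefficient panel AUC {cc} vs degree {deg}: +{100*(cc-deg)/deg:.0f}%")
```

which prints:

```
union size: 32
top-10 of union: AGER, CA4, RASIP1, CAV1, FAM107A, CDH5, SPP1, PTPRB, SOX7, SDPR
precision vs overall top-10: 7/10 = 70%
clustering-coefficient panel AUC 0.877 vs degree 0.7875: +11%
```

The 21-gene Clustering-Coefficient list and the 11-gene Bottleneck list
are disjoint (union 32); ranked by their published AUCs, seven of the top
ten union members (AGER, CA4, RASIP1, CAV1, FAM107A, CDH5, SPP1) are
among the overall top-10 disease-correlated genes — 70% precision — and
the Clustering-Coefficient panel's integrated AUC beats the Degree
panel's by 11%.

On the synthetic benchmark the same machinery recovers the planted
structure — the composite's top-10 are module members and the bridge,
while a Degree ranking is captured by the planted hub decoys:

```
C-Index top-10 on planted benchmark: BRIDGE_1, MOD2_15, MOD1_03, MOD2_10, ...
greedy signature: best prefix 6, integrated AUC 0.9731
```

## Command line

```bash
netsig simulate --seed 7 --out-prefix bench/          # planted benchmark
netsig score --graph bench/edges.tsv --metrics all --out scores.tsv
netsig top --graph bench/edges.tsv --metric clustering_coefficient -k 10
netsig degs --expr bench/expr.tsv --ann bench/ann.tsv --out degs.tsv
netsig cindex --graph bench/edges.tsv --expr bench/expr.tsv \
              --ann bench/ann.tsv -k 10 --out panel.txt
netsig run --expr bench/expr.tsv --ann bench/ann.tsv \
           --graph bench/edges.tsv --out run1   # full pipeline + manifest
```

Expression input is a genes × samples TSV plus a sample-annotation TSV
(`group` ∈ {control, case}, optional `stage` and clinical covariates);
networks are 2-3 column edge lists (SIF-compatible, optional confidence);
gene sets are GMT.  See `docs/methods.md` for the operator definitions,
benchmark design and numerical conventions.

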