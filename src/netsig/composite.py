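"""Composite metric selection: supersets, AUC-ranked unions, and the
C-Index (Clustering Coefficient union Bottleneck).

A composite takes the tie-aware top-k gene sets of two or more metrics,
forms their union (the "superset"), ranks the union members by their
individual oriented AUC, and truncates to the selection size.  The
composite evaluation protocol scores each selection by its Integrated
AUC and by its precision against a reference list of top
disease-correlated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .evaluate import individual_aucs, integrated_auc, precision
from .metrics import (
    METRIC_NAMES,
    MetricParams,
    RankedGeneSet,
    compute_metric,
    top_k,
)
from .types import ExpressionMatrix, GeneGraph

logger = logging.getLogger(__name__)

__all__ = [
    "CompositeSpec",
    "CompositeEvaluation",
    "build_superset",
    "rank_union",
    "c_index_select",
    "evaluate_composition",
    "enumerate_compositions",
]


@dataclass(frozen=True)
class CompositeSpec:
    """A metric composition: which component metrics, the per-component
    top-k, and the selection sizes to evaluate."""

    metrics: tuple[str, ...]
    k_component: int = 10
    selection_k: tuple[int, ...] = (10, 20)

    def __post_init__(self) -> None:
        if len(self.metrics) < 2:
            raise ValueError("a composite needs >= 2 component metrics")
        unknown = set(self.metrics) - set(METRIC_NAMES)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")

    @property
    def name(self) -> str:
        return "+".join(sorted(set(self.metrics)))


@dataclass
class CompositeEvaluation:
    name: str
    superset_size: int
    integrated_auc: dict[int, float]  # selection_k -> AUC
    precision: dict[int, float]  # selection_k -> precision
    warnings: list[str] = field(default_factory=list)


def build_superset(
    sets: Mapping[str, RankedGeneSet] | Mapping[str, Sequence[str]],
) -> dict[str, list[str]]:
    """Union of per-metric gene sets; returns gene -> contributing metrics."""
    if not sets:
        raise ValueError("no component sets")
    provenance: dict[str, list[str]] = {}
    for metric, ranked in sets.items():
        genes = ranked.genes if isinstance(ranked, RankedGeneSet) else list(ranked)
        for g in genes:
            provenance.setdefault(g, []).append(metric)
    return provenance


def rank_union(
    superset: Iterable[str],
    auc_source: ExpressionMatrix | Mapping[str, float],
) -> RankedGeneSet:
    """Rank union members by individual oriented AUC, descending.

    ``auc_source`` is either an expression matrix (AUCs computed here) or
    a precomputed gene -> AUC mapping (e.g. a published table).  Members
    with no available AUC rank below all scored members, alphabetically;
    AUC ties also break alphabetically.
    """
    members = sorted(set(superset))
    if not members:
        raise ValueError("empty superset")
    if isinstance(auc_source, ExpressionMatrix):
        present = [g for g in members if g in set(auc_source.genes)]
        aucs = (
            individual_aucs(auc_source, present)["auc"].to_dict() if present else {}
        )
    else:
        aucs = {g: float(auc_source[g]) for g in members if g in auc_source}
    if not aucs:
        raise ValueError("no superset member has an AUC")
    scored = sorted(aucs.items(), key=lambda kv: (-kv[1], kv[0]))
    unscored = sorted(set(members) - set(aucs))
    entries: list[tuple[str, float, int]] = []
    rank = 0
    prev: float | None = None
    for i, (gene, a) in enumerate(scored, 1):
        if prev is None or a != prev:
            rank = i
            prev = a
        entries.append((gene, a, rank))
    for i, gene in enumerate(unscored, len(scored) + 1):
        entries.append((gene, float("nan"), i))
    return RankedGeneSet(entries=entries, source="union", nominal_k=len(entries))


def _component_sets(
    spec: CompositeSpec,
    g: GeneGraph,
    params: MetricParams,
) -> dict[str, RankedGeneSet]:
    return {
        m: top_k(compute_metric(g, m, params), spec.k_component, source=m)
        for m in dict.fromkeys(spec.metrics)
    }


def c_index_select(
    g: GeneGraph,
    m: ExpressionMatrix,
    k_component: int = 10,
    k_select: int = 10,
    params: MetricParams = MetricParams(),
) -> RankedGeneSet:
    """The C-Index selector: tie-aware top-k by Clustering Coefficient and
    by Bottleneck, union, AUC-rank, truncate to ``k_select``.

    The two components capture complementary structure: dense local
    communities (clustering) and global cut points on shortest paths
    (bottlenecks).
    """
    spec = CompositeSpec(
        metrics=("clustering_coefficient", "bottleneck"), k_component=k_component
    )
    shared = set(g.nodes) & set(m.genes)
    if len(shared) < k_select:
        raise ValueError(
            f"graph and matrix share only {len(shared)} genes (< k_select={k_select})"
        )
    union = build_superset(_component_sets(spec, g, params))
    ranked = rank_union(union, m)
    return _truncate(ranked, k_select, source="c_index")


def _truncate(ranked: RankedGeneSet, k: int, source: str) -> RankedGeneSet:
    if k > len(ranked.entries):
        logger.warning(
            "%s: requested %d genes but the union only holds %d; returning all",
            source,
            k,
            len(ranked.entries),
        )
        k = len(ranked.entries)
    return RankedGeneSet(entries=ranked.entries[:k], source=source, nominal_k=k)


def evaluate_composition(
    spec: CompositeSpec,
    g: GeneGraph,
    m: ExpressionMatrix,
    reference: Sequence[str],
    params: MetricParams = MetricParams(),
) -> CompositeEvaluation:
    """Evaluate one composition: for each selection size, AUC-rank the
    superset, truncate, and compute Integrated AUC plus precision against
    the reference top list."""
    if len(reference) < max(spec.selection_k):
        raise ValueError("reference shorter than the largest selection_k")
    union = build_superset(_component_sets(spec, g, params))
    ranked = rank_union(union, m)
    warnings: list[str] = []
    if len(union) < max(spec.selection_k):
        warnings.append(
            f"superset of {len(union)} genes is smaller than selection_k="
            f"{max(spec.selection_k)}"
        )
    aucs: dict[int, float] = {}
    precs: dict[int, float] = {}
    matrix_genes = set(m.genes)
    for k in spec.selection_k:
        sel = _truncate(ranked, k, source=spec.name).genes
        panel = [g_ for g_ in sel if g_ in matrix_genes]
        aucs[k] = integrated_auc(m, panel).auc
        precs[k] = precision(sel, reference, k).precision
    return CompositeEvaluation(
        name=spec.name,
        superset_size=len(union),
        integrated_auc=aucs,
        precision=precs,
        warnings=warnings,
    )


def enumerate_compositions(
    metrics: Sequence[str],
    sizes: Iterable[int],
    g: GeneGraph,
    m: ExpressionMatrix,
    reference: Sequence[str],
    k_component: int = 10,
    selection_k: tuple[int, ...] = (10, 20),
    params: MetricParams = MetricParams(),
) -> pd.DataFrame:
    """Evaluate every metric combination of the given sizes; one row per
    composition, sorted by Integrated AUC at the smallest selection size."""
    rows = []
    first_k = selection_k[0]
    for size in sizes:
        for combo in combinations(metrics, size):
            spec = CompositeSpec(
                metrics=tuple(combo), k_component=k_component, selection_k=selection_k
            )
            ev = evaluate_composition(spec, g, m, reference, params=params)
            row: dict[str, object] = {
                "composition": ev.name,
                "size": size,
                "superset_size": ev.superset_size,
            }
            for k in selection_k:
                row[f"integrated_auc@{k}"] = ev.integrated_auc[k]
                row[f"precision@{k}"] = ev.precision[k]
            rows.append(row)
    table = pd.DataFrame(rows)
    return table.sort_values(
        f"integrated_auc@{first_k}", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
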