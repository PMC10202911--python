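"""Core in-memory containers: expression matrices and gene-interaction graphs.

An :class:`ExpressionMatrix` holds a genes x samples table of log2-scale
expression values together with per-sample annotations (case/control group,
optional tumour stage and clinical covariates).  A :class:`GeneGraph` is a
thin wrapper over an undirected simple :class:`networkx.Graph` whose nodes
are gene symbols and whose edges may carry an interaction-confidence score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

GROUP_CONTROL = "control"
GROUP_CASE = "case"
VALID_GROUPS = (GROUP_CONTROL, GROUP_CASE)
VALID_STAGES = ("I", "II", "III", "IV", "none")

__all__ = [
    "ExpressionMatrix",
    "GeneGraph",
    "GROUP_CONTROL",
    "GROUP_CASE",
    "VALID_GROUPS",
    "VALID_STAGES",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol, columns are sample ids.
    annotations
        DataFrame indexed by sample id.  Must contain a ``group`` column
        with values ``"control"``/``"case"``; may contain ``stage``
        (I/II/III/IV/none) and arbitrary clinical covariates (age, sex,
        smoking, ...).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        genes = self.values.index
        if genes.duplicated().any():
            dupes = sorted(set(genes[genes.duplicated()]))
            raise ValueError(f"duplicate gene symbols: {', '.join(dupes)}")
        samples = self.values.columns
        if samples.duplicated().any():
            dupes = sorted(set(samples[samples.duplicated()]))
            raise ValueError(f"duplicate sample ids: {', '.join(dupes)}")
        if "group" not in self.annotations.columns:
            raise ValueError("annotations must have a 'group' column")
        missing = [s for s in samples if s not in self.annotations.index]
        if missing:
            raise ValueError(
                "samples missing from annotations: " + ", ".join(map(str, missing))
            )
        extra = [s for s in self.annotations.index if s not in set(samples)]
        if extra:
            raise ValueError(
                "annotated samples missing from matrix: " + ", ".join(map(str, extra))
            )
        # align annotation order with the matrix columns
        self.annotations = self.annotations.loc[list(samples)]
        bad = set(self.annotations["group"]) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if "stage" in self.annotations.columns:
            stages = self.annotations["stage"].fillna("none")
            bad = set(stages) - set(VALID_STAGES)
            if bad:
                raise ValueError(f"unknown stage labels: {sorted(bad)}")
            self.annotations = self.annotations.assign(stage=stages)

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> pd.Series:
        """Per-sample group labels, in matrix column order."""
        return self.annotations["group"]

    @property
    def case_mask(self) -> np.ndarray:
        return (self.groups == GROUP_CASE).to_numpy()

    def group_samples(self, group: str) -> list[str]:
        if group not in VALID_GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return list(self.groups.index[self.groups == group])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in set(self.samples)]
        if missing:
            raise KeyError(f"unknown samples: {', '.join(missing)}")
        return ExpressionMatrix(
            self.values[samples].copy(), self.annotations.loc[samples].copy()
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in set(self.genes)]
        if missing:
            raise KeyError(f"unknown genes: {', '.join(missing)}")
        return ExpressionMatrix(self.values.loc[genes].copy(), self.annotations.copy())

    def require_both_groups(self) -> None:
        counts = self.groups.value_counts()
        for g in VALID_GROUPS:
            if counts.get(g, 0) == 0:
                raise ValueError(f"group {g!r} has no samples")


@dataclass
class GeneGraph:
    """Undirected simple graph of gene symbols with optional edge confidence."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        if isinstance(self.graph, (nx.DiGraph, nx.MultiGraph)):
            raise TypeError("GeneGraph requires an undirected simple graph")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops}")
        if self.graph.number_of_nodes() == 0:
            raise ValueError("graph has no nodes")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "GeneGraph":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for edge in edges:
            a, b = edge[0], edge[1]
            conf = float(edge[2]) if len(edge) > 2 else 1.0
            if a == b:
                continue
            if not g.has_edge(a, b):
                g.add_edge(a, b, confidence=conf)
        return cls(g)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b in self.graph.edges]

    def confidence(self, a: str, b: str) -> float:
        return float(self.graph.edges[a, b].get("confidence", 1.0))


def as_nx(g: "GeneGraph | nx.Graph") -> nx.Graph:
    """Coerce a GeneGraph or bare networkx graph to networkx.Graph."""
    return g.graph if isinstance(g, GeneGraph) else g
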