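"""Differential-expression screening and gene-set direction statistics.

The screen keeps genes with two-sided p < p_max AND |logFC| > logfc_min
(strict inequalities), where logFC is the case-minus-control difference of
group means on log2-scale expression.  P-values come from a per-gene Welch
t-test; Benjamini-Hochberg FDR is computed over all tested genes.  Any
external per-gene (p, logFC) table (e.g. from a moderated linear model)
can be screened through :func:`screen_table` instead.

The direction z-score of an annotated gene set is
``(N_up - N_down) / sqrt(N_up + N_down)``: negative values flag sets whose
differential genes are predominantly down-regulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, GROUP_CASE, GROUP_CONTROL

__all__ = [
    "DegRecord",
    "TermDirectionStats",
    "welch_test",
    "gene_stats",
    "screen_degs",
    "screen_table",
    "term_direction_stats",
    "go_zscore",
]


@dataclass(frozen=True)
class DegRecord:
    gene: str
    logfc: float
    p: float
    fdr: float
    direction: str  # "up" iff logfc > 0


@dataclass(frozen=True)
class TermDirectionStats:
    term: str
    n_up: int
    n_down: int

    @property
    def count(self) -> int:
        return self.n_up + self.n_down


def welch_test(m: ExpressionMatrix, gene: str) -> tuple[float, float]:
    """Two-sided Welch t-test for one gene, control vs. case.

    Returns ``(t, p)`` with t computed as control-minus-case (so a gene
    up-regulated in cases has negative t and positive logFC).
    """
    if gene not in set(m.genes):
        raise KeyError(f"gene {gene!r} not in matrix")
    row = m.values.loc[gene]
    control = row[m.groups == GROUP_CONTROL].to_numpy(dtype=float)
    case = row[m.groups == GROUP_CASE].to_numpy(dtype=float)
    if len(control) < 2 or len(case) < 2:
        raise ValueError(f"gene {gene!r}: need >=2 samples per group")
    if np.var(control, ddof=1) == 0 and np.var(case, ddof=1) == 0:
        if np.mean(control) == np.mean(case):
            return 0.0, 1.0
        raise ValueError(f"gene {gene!r}: zero variance in both groups")
    t, p = stats.ttest_ind(control, case, equal_var=False)
    return float(t), float(p)


def gene_stats(m: ExpressionMatrix) -> pd.DataFrame:
    """Welch test + logFC for every gene; vectorized across the matrix.

    Returns a DataFrame indexed by gene with columns t, p, logfc.
    Genes with zero variance in both groups get t=0, p=1 (if means equal).
    """
    m.require_both_groups()
    vals = m.values.to_numpy(dtype=float)
    case_mask = m.case_mask
    control = vals[:, ~case_mask]
    case = vals[:, case_mask]
    t, p = stats.ttest_ind(control, case, axis=1, equal_var=False)
    logfc = case.mean(axis=1) - control.mean(axis=1)
    # degenerate rows (zero variance in both groups): identical means -> null
    degenerate = np.isnan(t)
    t = np.where(degenerate & (logfc == 0), 0.0, t)
    p = np.where(degenerate & (logfc == 0), 1.0, p)
    return pd.DataFrame({"t": t, "p": p, "logfc": logfc}, index=m.values.index)


def screen_table(
    table: pd.DataFrame, p_max: float = 0.01, logfc_min: float = 1.2
) -> list[DegRecord]:
    """Screen a per-gene (p, logfc) table; BH-FDR over all tested genes."""
    finite = table.dropna(subset=["p", "logfc"])
    fdr = pd.Series(
        multipletests(finite["p"].to_numpy(), method="fdr_bh")[1], index=finite.index
    )
    kept = finite[(finite["p"] < p_max) & (finite["logfc"].abs() > logfc_min)]
    return [
        DegRecord(
            gene=str(g),
            logfc=float(row["logfc"]),
            p=float(row["p"]),
            fdr=float(fdr[g]),
            direction="up" if row["logfc"] > 0 else "down",
        )
        for g, row in kept.iterrows()
    ]


def screen_degs(
    m: ExpressionMatrix, p_max: float = 0.01, logfc_min: float = 1.2
) -> list[DegRecord]:
    """Welch-test every gene and keep p < p_max AND |logFC| > logfc_min."""
    return screen_table(gene_stats(m), p_max=p_max, logfc_min=logfc_min)


def degs_to_frame(degs: Sequence[DegRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.gene, d.logfc, d.p, d.fdr, d.direction) for d in degs],
        columns=["gene", "logfc", "p", "fdr", "direction"],
    )


def term_direction_stats(
    degs: Sequence[DegRecord], gene_sets: Mapping[str, Sequence[str]]
) -> list[TermDirectionStats]:
    """Count up/down differential genes within each annotated gene set."""
    direction = {d.gene: d.direction for d in degs}
    out = []
    for term, members in gene_sets.items():
        dirs = [direction[g] for g in members if g in direction]
        out.append(
            TermDirectionStats(
                term=term,
                n_up=sum(d == "up" for d in dirs),
                n_down=sum(d == "down" for d in dirs),
            )
        )
    return out


def go_zscore(stats_or_up: TermDirectionStats | int, n_down: int | None = None) -> float:
    """Direction z-score (N_up - N_down) / sqrt(N_up + N_down).

    Accepts either a :class:`TermDirectionStats` or the two counts.
    """
    if isinstance(stats_or_up, TermDirectionStats):
        n_up, n_down = stats_or_up.n_up, stats_or_up.n_down
    else:
        if n_down is None:
            raise TypeError("pass TermDirectionStats or both counts")
        n_up = stats_or_up
    count = n_up + n_down
    if count < 1:
        raise ValueError("z-score undefined for an empty term (count = 0)")
    return (n_up - n_down) / np.sqrt(count)
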