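"""ROC/AUC machinery for single genes and biomarker panels.

The panel statistic ("Integrated AUC") aggregates a panel by z-scoring
each member gene across samples, averaging the z-scores per sample, and
computing the AUC of that aggregate score for case vs. control.  The AUC
itself uses the Mann-Whitney form, P(case > control) + 0.5 P(tie), which
is identical to the trapezoidal area under the empirical ROC curve.

Orientation: many informative genes are down-regulated in cases, so the
raw AUC can fall below 0.5.  With ``direction="auto"`` the oriented AUC
max(a, 1 - a) is reported and the chosen orientation is recorded, so a
validation set can be evaluated under the training-set orientation
instead of re-auto-orienting (which would bias validation upward).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .types import ExpressionMatrix, GROUP_CASE

__all__ = [
    "AucResult",
    "PrecisionResult",
    "SignatureResult",
    "auc",
    "individual_aucs",
    "integrated_auc",
    "mean_individual_auc",
    "greedy_signature",
    "precision",
]

CASE_HIGH = "case_high"
CASE_LOW = "case_low"


@dataclass
class AucResult:
    """Oriented AUC with its ROC curve.

    ``auc`` is the reported (oriented) value; ``raw_auc`` is
    P(case > control) + 0.5 P(tie) on the unmodified scores; ``direction``
    records which orientation the reported value corresponds to.
    ``roc_points`` are (fpr, tpr) pairs for the oriented score.
    """

    auc: float
    raw_auc: float
    direction: str
    roc_points: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class PrecisionResult:
    """Top-k precision: fraction of a selected set found in the reference
    top-k list."""

    n_correct: int
    n_total: int

    @property
    def precision(self) -> float:
        return self.n_correct / self.n_total


@dataclass
class SignatureResult:
    """Greedy panel construction trace: integrated AUC per prefix size."""

    genes: list[str]
    integrated_auc: list[float]
    best_size: int
    best_auc: float


def _split_scores(score: np.ndarray, case_mask: np.ndarray):
    case = score[case_mask]
    control = score[~case_mask]
    if len(case) == 0 or len(control) == 0:
        raise ValueError("AUC needs both case and control samples")
    return case, control


def auc(
    score: Sequence[float] | np.ndarray,
    case_mask: Sequence[bool] | np.ndarray,
    direction: str = "auto",
) -> AucResult:
    """Mann-Whitney AUC of a per-sample score against case/control labels.

    direction
        ``"auto"`` reports max(a, 1-a); ``"case_high"``/``"case_low"``
        lock the orientation (used to carry a training orientation onto
        validation data).
    """
    score = np.asarray(score, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    case, control = _split_scores(score, case_mask)
    u = stats.mannwhitneyu(case, control, alternative="two-sided").statistic
    raw = float(u) / (len(case) * len(control))
    if direction == "auto":
        chosen = CASE_HIGH if raw >= 0.5 else CASE_LOW
    elif direction in (CASE_HIGH, CASE_LOW):
        chosen = direction
    else:
        raise ValueError(f"unknown direction {direction!r}")
    oriented = raw if chosen == CASE_HIGH else 1.0 - raw
    oriented_score = score if chosen == CASE_HIGH else -score
    fpr, tpr, _ = roc_curve(case_mask.astype(int), oriented_score)
    return AucResult(
        auc=oriented,
        raw_auc=raw,
        direction=chosen,
        roc_points=np.column_stack([fpr, tpr]),
    )


def individual_aucs(
    m: ExpressionMatrix, genes: Iterable[str], direction: str = "auto"
) -> pd.DataFrame:
    """Oriented per-gene AUC table (columns: auc, raw_auc, direction)."""
    genes = list(genes)
    missing = sorted(set(genes) - set(m.genes))
    if missing:
        raise KeyError(f"genes not in matrix: {', '.join(missing)}")
    m.require_both_groups()
    mask = m.case_mask
    rows = []
    for gene in genes:
        res = auc(m.values.loc[gene].to_numpy(), mask, direction=direction)
        rows.append((gene, res.auc, res.raw_auc, res.direction))
    return pd.DataFrame(rows, columns=["gene", "auc", "raw_auc", "direction"]).set_index(
        "gene"
    )


def panel_score(m: ExpressionMatrix, panel: Sequence[str]) -> np.ndarray:
    """Aggregated panel score per sample: mean across the panel of each
    gene's z-score (across samples)."""
    panel = list(panel)
    if not panel:
        raise ValueError("panel is empty")
    missing = sorted(set(panel) - set(m.genes))
    if missing:
        raise KeyError(f"genes not in matrix: {', '.join(missing)}")
    vals = m.values.loc[panel]
    sd = vals.std(axis=1, ddof=1).replace(0.0, np.nan)
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0).fillna(0.0)
    return z.mean(axis=0).to_numpy()


def integrated_auc(
    m: ExpressionMatrix, panel: Sequence[str], direction: str = "auto"
) -> AucResult:
    """AUC of the aggregated (mean of per-gene z-scores) panel score."""
    m.require_both_groups()
    return auc(panel_score(m, panel), m.case_mask, direction=direction)


def mean_individual_auc(m: ExpressionMatrix, panel: Sequence[str]) -> float:
    """Arithmetic mean of the oriented per-gene AUCs of a panel."""
    panel = list(panel)
    if not panel:
        raise ValueError("panel is empty")
    return float(individual_aucs(m, panel)["auc"].mean())


def greedy_signature(
    m: ExpressionMatrix, ranked_genes: Sequence[str], max_size: int | None = None
) -> SignatureResult:
    """Grow a panel along a ranked gene list, one gene at a time, and find
    the prefix size at which the integrated AUC peaks.

    Returns the full AUC trace; ``best_size`` is the smallest prefix
    achieving the maximum.
    """
    ranked_genes = list(ranked_genes)
    if not ranked_genes:
        raise ValueError("ranked_genes is empty")
    if max_size is None:
        max_size = len(ranked_genes)
    max_size = min(max_size, len(ranked_genes))
    trace = [
        integrated_auc(m, ranked_genes[:size]).auc for size in range(1, max_size + 1)
    ]
    best_idx = int(np.argmax(trace))  # argmax returns the first (smallest) peak
    return SignatureResult(
        genes=ranked_genes[:max_size],
        integrated_auc=trace,
        best_size=best_idx + 1,
        best_auc=trace[best_idx],
    )


def precision(
    selected: Iterable[str], reference: Sequence[str], k: int
) -> PrecisionResult:
    """Fraction of the selected genes found among the reference list's
    first k entries (the "top-k disease-correlated genes")."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(reference):
        raise ValueError(f"k={k} exceeds reference length {len(reference)}")
    top = set(reference[:k])
    n_correct = len(set(selected) & top)
    return PrecisionResult(n_correct=n_correct, n_total=k)
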