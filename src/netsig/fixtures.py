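"""Packaged reference tables: per-metric top-gene lists, the overall
AUC-ranked gene table, and per-metric panel AUC summaries.

These small tables are the published worked example the package is checked
against: the Clustering-Coefficient and Bottleneck top lists combined and
re-ranked by individual AUC recover 7 of the overall top-10 genes (70%
precision), and the Clustering-Coefficient panel AUC improves on Degree's
by 11%.

Symbols are stored exactly as printed in the source tables; a small,
explicitly shipped typo-normalization map (e.g. ``CNNB1 -> CCNB1``) is
applied on load unless ``normalize_typos=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["Fixtures", "load_fixtures", "METRIC_DISPLAY_NAMES"]

#: canonical metric id -> display name used in the fixture tables
METRIC_DISPLAY_NAMES: dict[str, str] = {
    "degree": "Degree",
    "mcc": "MCC",
    "dmnc": "DMNC",
    "mnc": "MNC",
    "clustering_coefficient": "Clustering coefficient",
    "betweenness": "Betweenness",
    "bottleneck": "Bottleneck",
    "eccentricity": "Eccentricity",
    "closeness": "Closeness",
    "radiality": "Radiality",
    "stress": "Stress",
    "epc": "EPC",
}

_DISPLAY_TO_ID = {v: k for k, v in METRIC_DISPLAY_NAMES.items()}


@dataclass(frozen=True)
class Fixtures:
    """The packaged printed tables.

    Attributes
    ----------
    table1a
        metric id -> ordered list of top genes for that metric.
    table1b
        DataFrame (gene, auc, logfc, fdr) ordered by AUC descending.
    table2
        metric id -> (integrated_auc, mean_individual_auc).
    typo_map
        printed symbol -> corrected symbol (applied iff requested).
    """

    table1a: dict[str, list[str]]
    table1b: pd.DataFrame
    table2: dict[str, tuple[float, float]]
    typo_map: dict[str, str]

    def top_auc_genes(self, k: int) -> list[str]:
        """The overall top-k disease-correlated genes by individual AUC."""
        return list(self.table1b["gene"].iloc[:k])

    @property
    def auc_by_gene(self) -> dict[str, float]:
        return dict(zip(self.table1b["gene"], self.table1b["auc"]))


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("netsig.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_fixtures(normalize_typos: bool = True) -> Fixtures:
    """Load the packaged tables, optionally applying the typo map."""
    typo = _read("typo_normalization.tsv")
    typo_map = dict(zip(typo["printed"], typo["corrected"]))

    def fix(symbol: str) -> str:
        return typo_map.get(symbol, symbol) if normalize_typos else symbol

    t1a = _read("table1a.tsv")
    table1a: dict[str, list[str]] = {}
    for display, sub in t1a.groupby("metric", sort=False):
        metric = _DISPLAY_TO_ID[display]
        table1a[metric] = [fix(g) for g in sub.sort_values("rank")["gene"]]

    t1b = _read("table1b.tsv")
    t1b = t1b.assign(gene=[fix(g) for g in t1b["gene"]])

    t2 = _read("table2.tsv")
    table2 = {
        _DISPLAY_TO_ID[row.metric]: (float(row.integrated_auc), float(row.mean_individual_auc))
        for row in t2.itertuples()
    }
    return Fixtures(table1a=table1a, table1b=t1b, table2=table2, typo_map=typo_map)
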