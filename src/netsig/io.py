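"""Readers/writers for the tabular formats, normalization and data splitting.

Formats handled here:

* expression: TSV, first column gene symbol, remaining columns samples,
  values on log2 scale; paired with a sample-annotation TSV (first column
  sample id, a ``group`` column, optional ``stage`` and covariates);
* network: 2-3 column whitespace/tab edge list (SIF-compatible), optional
  third column with interaction confidence in [0, 1];
* gene sets: GMT (name, description, member genes).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GeneGraph, VALID_GROUPS

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "read_graph",
    "write_graph",
    "read_gmt",
    "zscore_normalize",
    "split_train_validation",
]


def read_expression(path: str | Path, annotation_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus its sample-annotation TSV.

    Raises on duplicate gene symbols (naming them) and on any mismatch
    between the matrix's sample ids and the annotation's.
    """
    table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    table.index = table.index.astype(str)
    dupes = sorted(set(table.index[table.index.duplicated()]))
    if dupes:
        raise ValueError(f"duplicate gene symbols in {path}: {', '.join(dupes)}")
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0, comment="#")
    ann.index = ann.index.astype(str)
    missing = [s for s in table.columns if s not in ann.index]
    if missing:
        raise ValueError(
            f"annotation {annotation_path} is missing samples: {', '.join(missing)}"
        )
    return ExpressionMatrix(table.astype(float), ann)


def read_graph(path: str | Path, min_confidence: float = 0.0) -> GeneGraph:
    """Read an undirected edge list; drop edges below ``min_confidence``.

    Lines hold two or three whitespace-separated fields ``a b [confidence]``;
    a missing confidence counts as 1.0.  Duplicate/reversed edges collapse to
    one edge keeping the first confidence seen; self-loop rows are dropped
    with a warning.
    """
    edges: list[tuple[str, str, float]] = []
    nodes: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 1:
                nodes.append(fields[0])
                continue
            if len(fields) > 3:
                raise ValueError(f"{path}:{lineno}: expected 2-3 columns, got {len(fields)}")
            a, b = fields[0], fields[1]
            conf = float(fields[2]) if len(fields) == 3 else 1.0
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %s", path, lineno, a)
                continue
            nodes.extend((a, b))
            if conf >= min_confidence:
                edges.append((a, b, conf))
    # nodes that only appear on filtered edges stay as isolated nodes
    return GeneGraph.from_edges(edges, nodes=nodes)


def write_graph(g: GeneGraph, path: str | Path) -> None:
    """Write the edge list with confidences; isolated nodes as single fields."""
    with open(path, "w") as fh:
        for a, b in sorted(map(sorted, g.edges())):
            fh.write(f"{a}\t{b}\t{g.confidence(a, b):g}\n")
        connected = {n for e in g.edges() for n in e}
        for n in sorted(set(g.nodes) - connected):
            fh.write(f"{n}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT: name <tab> description <tab> gene..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def zscore_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene across samples (sample sd, ddof=1).

    Constant genes cannot be z-scored and are dropped with a warning.
    """
    vals = m.values
    sd = vals.std(axis=1, ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index
    if len(constant):
        logger.warning(
            "dropping %d constant gene(s): %s", len(constant), ", ".join(constant)
        )
        vals = vals.drop(index=constant)
        sd = sd.drop(index=constant)
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, m.annotations.copy())


def split_train_validation(
    m: ExpressionMatrix, fraction: float, seed: int
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Stratified-by-group random split into train/validation.

    Per stratum the training count is ``ceil(fraction * n)``, clamped to
    ``n - 1`` so the validation side stays non-empty whenever the stratum
    has at least two samples.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    m.require_both_groups()
    rng = np.random.default_rng(seed)
    train: list[str] = []
    valid: list[str] = []
    for group in VALID_GROUPS:
        members = m.group_samples(group)
        if len(members) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 samples")
        n_train = min(math.ceil(fraction * len(members)), len(members) - 1)
        order = rng.permutation(len(members))
        train.extend(members[i] for i in order[:n_train])
        valid.extend(members[i] for i in order[n_train:])
    # keep original column order within each side
    order_index = {s: i for i, s in enumerate(m.samples)}
    train.sort(key=order_index.__getitem__)
    valid.sort(key=order_index.__getitem__)
    return m.subset_samples(train), m.subset_samples(valid)
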