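"""End-to-end pipeline driver: DEG screen -> network scoring -> composite
evaluation -> C-Index panel -> greedy signature -> cascade report.

Every output file starts with a header comment recording the package
version, the seed and a hash of the configuration, so a run can be
matched to the exact settings that produced it.  Rerunning with the same
config reproduces all outputs (stochastic steps are seeded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .cascade import build_features, evaluate_cascade, fit_cascade, logistic_factory
from .composite import CompositeSpec, c_index_select, enumerate_compositions
from .dge import degs_to_frame, screen_degs
from .evaluate import greedy_signature, individual_aucs
from .io import read_expression, read_graph
from .metrics import METRIC_NAMES, MetricParams, score_all, top_k
from .types import ExpressionMatrix, GeneGraph

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    expression_path: str
    annotation_path: str
    graph_path: str
    out_dir: str
    p_max: float = 0.01
    logfc_min: float = 1.2
    min_confidence: float = 0.0
    k_component: int = 10
    k_select: int = 10
    composite_metrics: tuple[str, ...] = ("clustering_coefficient", "bottleneck")
    composite_sizes: tuple[int, ...] = (2,)
    max_signature_size: int = 10
    cascade_panel_size: int = 4
    use_clinical: bool = False
    seed: int = 0
    params: MetricParams = field(default_factory=MetricParams)

    def validate(self) -> None:
        unknown = set(self.composite_metrics) - set(METRIC_NAMES)
        if unknown:
            raise ValueError(f"unknown metric name(s): {sorted(unknown)}")
        for p in (self.expression_path, self.annotation_path, self.graph_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    def config_hash(self) -> str:
        # out_dir does not affect the analysis, so it stays out of the hash
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return f"# netsig {__version__} seed={cfg.seed} config={cfg.config_hash()}\n"


def _write_tsv(frame: pd.DataFrame, path: Path, cfg: RunConfig, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        frame.to_csv(fh, sep="\t", index=index)


def _write_json(obj, path: Path, cfg: RunConfig) -> None:
    wrapped = {
        "netsig_version": __version__,
        "seed": cfg.seed,
        "config": cfg.config_hash(),
        "result": obj,
    }
    path.write_text(json.dumps(wrapped, indent=2, default=str) + "\n")


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Writes degs.tsv, scores.tsv, ranked_sets.tsv, composites.tsv,
    cindex_panel.txt, signature.json, cascade_report.json and
    manifest.json.  Any stage failure raises with the stage name; files
    already written are left in place.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def stage(name: str):
        logger.info("pipeline stage: %s", name)
        return name

    current = stage("load inputs")
    try:
        matrix = read_expression(cfg.expression_path, cfg.annotation_path)
        graph = read_graph(cfg.graph_path, min_confidence=cfg.min_confidence)

        current = stage("differential expression screen")
        degs = screen_degs(matrix, p_max=cfg.p_max, logfc_min=cfg.logfc_min)
        _write_tsv(degs_to_frame(degs), out / "degs.tsv", cfg, index=False)
        artifacts.append("degs.tsv")

        current = stage("network scoring")
        params = MetricParams(
            dmnc_epsilon=cfg.params.dmnc_epsilon,
            bottleneck_fraction=cfg.params.bottleneck_fraction,
            epc_realizations=cfg.params.epc_realizations,
            epc_retention=cfg.params.epc_retention,
            seed=cfg.seed,
        )
        scores = score_all(graph, params)
        score_table = pd.DataFrame(scores.scores).rename_axis("gene").sort_index()
        _write_tsv(score_table, out / "scores.tsv", cfg, index=True)
        artifacts.append("scores.tsv")

        current = stage("per-metric top sets")
        rows = []
        for metric in METRIC_NAMES:
            ranked = top_k(scores[metric], cfg.k_component, source=metric)
            for gene, score, rank in ranked.entries:
                rows.append((metric, rank, gene, score))
        ranked_table = pd.DataFrame(rows, columns=["metric", "rank", "gene", "score"])
        _write_tsv(ranked_table, out / "ranked_sets.tsv", cfg, index=False)
        artifacts.append("ranked_sets.tsv")

        current = stage("composite evaluation")
        reference = (
            individual_aucs(matrix, sorted(set(matrix.genes)))
            .sort_values("auc", ascending=False)
            .index.tolist()
        )
        max_sel = max(cfg.k_select, 10)
        selection_k = tuple(k for k in (10, 20) if k <= len(reference)) or (len(reference),)
        composites = enumerate_compositions(
            list(cfg.composite_metrics),
            cfg.composite_sizes,
            graph,
            matrix,
            reference,
            k_component=cfg.k_component,
            selection_k=selection_k,
            params=params,
        )
        _write_tsv(composites, out / "composites.tsv", cfg, index=False)
        artifacts.append("composites.tsv")

        current = stage("C-Index selection")
        panel = c_index_select(
            graph, matrix, k_component=cfg.k_component, k_select=cfg.k_select,
            params=params,
        )
        with open(out / "cindex_panel.txt", "w") as fh:
            fh.write(_header(cfg))
            for gene in panel.genes:
                fh.write(gene + "\n")
        artifacts.append("cindex_panel.txt")

        current = stage("greedy signature")
        sig = greedy_signature(matrix, panel.genes, max_size=cfg.max_signature_size)
        _write_json(
            {
                "genes": sig.genes,
                "integrated_auc": sig.integrated_auc,
                "best_size": sig.best_size,
                "best_auc": sig.best_auc,
                "signature": sig.genes[: sig.best_size],
            },
            out / "signature.json",
            cfg,
        )
        artifacts.append("signature.json")

        current = stage("cascade")
        features = build_features(
            matrix, sig.genes[: max(sig.best_size, cfg.cascade_panel_size)],
            use_clinical=cfg.use_clinical,
        )
        model = fit_cascade(
            features, matrix.annotations, logistic_factory(cfg.seed), seed=cfg.seed
        )
        report = evaluate_cascade(model, features, matrix.annotations)
        _write_json(report, out / "cascade_report.json", cfg)
        artifacts.append("cascade_report.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{current}' failed: {exc}") from exc

    current = stage("manifest")
    manifest = {
        "netsig_version": __version__,
        "seed": cfg.seed,
        "config": cfg.config_hash(),
        "artifacts": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in artifacts
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
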