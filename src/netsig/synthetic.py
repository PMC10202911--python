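"""Linked synthetic (network, expression, truth) benchmarks.

The generator plants exactly the structure the selection methodology is
meant to exploit:

* **disease modules** — dense Erdos-Renyi communities (edge probability
  ``p_intra``) standing in for co-functional gene complexes; members carry
  a planted expression shift and a shared latent factor;
* **bridges** — cut vertices joining two modules with a single edge into
  each (and no other edge between that module pair), so removing a bridge
  disconnects its two modules; bridges also carry a planted shift;
* **hub decoys** — high-degree nodes whose neighbours (random background
  genes) are pairwise non-adjacent (clustering coefficient exactly 0) and
  whose expression is pure noise: a degree-based ranking is attracted to
  them, a community/bottleneck-based one is not.  Decoys attach to the
  background only — wired into modules they would become genuine global
  connectors rather than decoys, and would break the bridge cut-vertex
  guarantee;
* **background genes** — sparsely wired among themselves (``p_inter``)
  with null expression.

With the default sizes the bottleneck score of a bridge is structurally
pinned: every non-bridge node of its two-module component routes one
whole module through it, so the bridge scores one point per such node,
exceeding anything achievable inside the (smaller) background/decoy
blob.

Expression follows a factor model on log2 scale:
``x_gs = mu_g + loading * F_{module(g), s} + eps_gs`` with Gaussian noise,
and informative genes (module members and bridges) are additionally
shifted *down* in cases by ``delta_module`` / ``delta_bridge`` (down-shift
as default because disease signature genes here are down-regulated;
configurable via ``effect_direction``).

All randomness derives from one seed through independent child streams, so
the graph and the expression matrix are separately reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GeneGraph

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_network",
    "generate_expression",
    "generate_linked",
]

ROLE_MODULE = "module_member"
ROLE_BRIDGE = "bridge"
ROLE_DECOY = "hub_decoy"
ROLE_BACKGROUND = "background"


@dataclass(frozen=True)
class SyntheticConfig:
    """Benchmark parameters.

    Defaults give a 61-gene network (2 modules of 15 joined by 1 bridge,
    10 hub decoys of degree 14, 20 background genes) and a 40 vs 40 cohort with a
    1.0 log2-unit down-shift in cases for informative genes, moderate
    within-module correlation (loading 0.5) and unit noise.  The decoy
    block is sized so that a degree ranking is dominated by decoys, while
    the background/decoy component stays smaller than a bridged module
    pair (keeping bridges the strongest bottlenecks); the effect size
    keeps panel AUCs away from saturation so that selection quality,
    not just selection size, drives the comparisons.
    """

    n_modules: int = 2
    module_size: int = 15
    p_intra: float = 0.6
    p_inter: float = 0.01
    n_bridges: int = 1
    n_hub_decoys: int = 10
    hub_degree: int = 14
    n_background_genes: int = 20
    n_control: int = 40
    n_case: int = 40
    delta_module: float = 1.0
    delta_bridge: float = 1.0
    factor_loading: float = 0.5
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    effect_direction: Literal["down", "up"] = "down"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_inter < self.p_intra <= 1:
            raise ValueError("need 0 <= p_inter < p_intra <= 1")
        if min(self.n_modules, self.module_size) < 0 or min(
            self.n_bridges, self.n_hub_decoys, self.n_background_genes
        ) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need >= 2 samples per group")
        if not 0 <= self.factor_loading < 1:
            raise ValueError("factor_loading must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted role, informative flag, and effect size per gene."""

    table: pd.DataFrame  # index gene; columns role, module, informative, effect

    @property
    def informative_genes(self) -> list[str]:
        return list(self.table.index[self.table["informative"]])

    @property
    def bridges(self) -> list[str]:
        return list(self.table.index[self.table["role"] == ROLE_BRIDGE])

    def genes_with_role(self, role: str) -> list[str]:
        return list(self.table.index[self.table["role"] == role])


def _gene_names(cfg: SyntheticConfig) -> dict[str, list[str]]:
    modules = [
        [f"MOD{m + 1}_{i + 1:02d}" for i in range(cfg.module_size)]
        for m in range(cfg.n_modules)
    ]
    return {
        "modules": modules,
        "bridges": [f"BRIDGE_{b + 1}" for b in range(cfg.n_bridges)],
        "decoys": [f"HUB_{h + 1}" for h in range(cfg.n_hub_decoys)],
        "background": [f"BG_{i + 1:03d}" for i in range(cfg.n_background_genes)],
    }


def generate_network(cfg: SyntheticConfig) -> tuple[GeneGraph, SyntheticTruth]:
    """Build the planted graph and its ground-truth role table."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[0])
    names = _gene_names(cfg)
    module_pairs = list(combinations(range(cfg.n_modules), 2))
    if cfg.n_bridges > len(module_pairs):
        raise ValueError(
            f"{cfg.n_bridges} bridges need {cfg.n_bridges} distinct module "
            f"pairs but only {len(module_pairs)} exist"
        )
    g = nx.Graph()
    for member_list in names["modules"]:
        g.add_nodes_from(member_list)
        for a, b in combinations(member_list, 2):
            if rng.random() < cfg.p_intra:
                g.add_edge(a, b, confidence=1.0)
    # bridges: one edge into each of two modules; those module pairs get no
    # other inter-module edge (modules are only ever joined via bridges)
    pair_order = rng.permutation(len(module_pairs))
    for b, bridge in enumerate(names["bridges"]):
        mi, mj = module_pairs[pair_order[b]]
        g.add_node(bridge)
        for m in (mi, mj):
            target = names["modules"][m][rng.integers(len(names["modules"][m]))]
            g.add_edge(bridge, target, confidence=1.0)
    # background genes: sparse wiring among themselves only
    g.add_nodes_from(names["background"])
    for a, b in combinations(names["background"], 2):
        if rng.random() < cfg.p_inter:
            g.add_edge(a, b, confidence=1.0)
    # hub decoys: pairwise non-adjacent random background targets
    candidates = names["background"]
    bg_degree = {n: sum(g.has_edge(n, o) for o in candidates) for n in candidates}
    for decoy in names["decoys"]:
        g.add_node(decoy)
        chosen: list[str] = []
        # low-degree-first greedy (degree within the background subgraph)
        # finds a maximum independent set on the sparse, forest-like
        # background; retries randomize the tie order
        for _ in range(20):
            chosen = []
            order = sorted(rng.permutation(candidates), key=bg_degree.__getitem__)
            for n in order:
                if len(chosen) == cfg.hub_degree:
                    break
                if any(g.has_edge(n, c) for c in chosen):
                    continue
                chosen.append(str(n))
            if len(chosen) == cfg.hub_degree:
                break
        if len(chosen) < cfg.hub_degree:
            raise ValueError(
                f"cannot place hub decoy of degree {cfg.hub_degree}: only "
                f"{len(chosen)} pairwise non-adjacent targets available"
            )
        for n in chosen:
            g.add_edge(decoy, n, confidence=1.0)

    rows = []
    sign = -1.0 if cfg.effect_direction == "down" else 1.0
    for m, member_list in enumerate(names["modules"]):
        for gene in member_list:
            rows.append((gene, ROLE_MODULE, m, sign * cfg.delta_module))
    for bridge in names["bridges"]:
        rows.append((bridge, ROLE_BRIDGE, -1, sign * cfg.delta_bridge))
    for decoy in names["decoys"]:
        rows.append((decoy, ROLE_DECOY, -1, 0.0))
    for gene in names["background"]:
        rows.append((gene, ROLE_BACKGROUND, -1, 0.0))
    table = pd.DataFrame(rows, columns=["gene", "role", "module", "effect"]).set_index(
        "gene"
    )
    table["informative"] = table["role"].isin([ROLE_MODULE, ROLE_BRIDGE]) & (
        table["effect"] != 0.0
    )
    return GeneGraph(g), SyntheticTruth(table=table)


def generate_expression(cfg: SyntheticConfig, truth: SyntheticTruth) -> ExpressionMatrix:
    """Simulate the case/control log2 expression matrix for the planted genes."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    genes = list(truth.table.index)
    n_samples = cfg.n_control + cfg.n_case
    sample_ids = [f"CTRL_{i + 1:03d}" for i in range(cfg.n_control)] + [
        f"CASE_{i + 1:03d}" for i in range(cfg.n_case)
    ]
    case = np.zeros(n_samples, dtype=bool)
    case[cfg.n_control :] = True

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    factors = rng.normal(0.0, 1.0, size=(max(cfg.n_modules, 1), n_samples))
    noise = rng.normal(0.0, cfg.noise_sd, size=(len(genes), n_samples))

    x = mu[:, None] + noise
    module_idx = truth.table["module"].to_numpy()
    in_module = module_idx >= 0
    if cfg.factor_loading > 0 and in_module.any():
        x[in_module] += cfg.factor_loading * factors[module_idx[in_module]]
    effects = truth.table["effect"].to_numpy()
    x[:, case] += effects[:, None]

    values = pd.DataFrame(x, index=genes, columns=sample_ids)
    ann = pd.DataFrame(
        {"group": np.where(case, "case", "control")}, index=sample_ids
    )
    return ExpressionMatrix(values, ann)


def generate_linked(
    cfg: SyntheticConfig,
) -> tuple[GeneGraph, ExpressionMatrix, SyntheticTruth]:
    """Graph + expression + truth from one seed, consistent gene namespace."""
    graph, truth = generate_network(cfg)
    matrix = generate_expression(cfg, truth)
    return graph, matrix, truth
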