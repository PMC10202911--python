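"""Shared driver comparing every metric against the brute-force oracles on
batches of random graphs."""

from __future__ import annotations

import math

import oracles
from conftest import random_gene_graph
from netsig import MetricParams
from netsig.metrics import compute_metric, epc_scores_with_se

EXACT_METRICS = ("degree", "mnc", "stress", "eccentricity", "bottleneck", "mcc")
FLOAT_METRICS = ("clustering_coefficient", "dmnc", "betweenness", "closeness", "radiality")

_ORACLES = {
    "degree": oracles.degree_oracle,
    "clustering_coefficient": oracles.clustering_oracle,
    "mnc": oracles.mnc_oracle,
    "dmnc": oracles.dmnc_oracle,
    "mcc": oracles.mcc_oracle,
    "betweenness": oracles.betweenness_oracle,
    "stress": oracles.stress_oracle,
    "closeness": oracles.closeness_oracle,
    "radiality": oracles.radiality_oracle,
    "eccentricity": oracles.eccentricity_oracle,
    "bottleneck": oracles.bottleneck_oracle,
}


def check_graph(g, seed: int, check_epc: bool = True) -> list[str]:
    """Return a list of mismatch descriptions (empty = all metrics agree)."""
    problems: list[str] = []
    params = MetricParams(seed=seed)
    for metric, oracle in _ORACLES.items():
        mine = compute_metric(g, metric, params)
        ref = oracle(g)
        for v in ref:
            if metric in EXACT_METRICS:
                ok = mine[v] == ref[v]
            else:
                ok = math.isclose(mine[v], ref[v], abs_tol=1e-9, rel_tol=1e-9)
            if not ok:
                problems.append(f"{metric}[{v}]: {mine[v]} != oracle {ref[v]}")
    if check_epc:
        # common random numbers: same seed and canonical edge order, so the
        # two implementations see identical percolation samples and must
        # agree to numerical precision (well inside 3 Monte-Carlo SEs)
        impl_mean, impl_se = epc_scores_with_se(
            g, MetricParams(epc_realizations=400, seed=seed)
        )
        ref_mean, ref_se = oracles.epc_oracle(
            g.graph, retention=0.5, realizations=400, seed=seed
        )
        for v in ref_mean:
            tol = min(1e-9, 3.0 * math.sqrt(impl_se[v] ** 2 + ref_se[v] ** 2) + 1e-12)
            if abs(impl_mean[v] - ref_mean[v]) > tol:
                problems.append(
                    f"epc[{v}]: {impl_mean[v]:.4f} vs oracle {ref_mean[v]:.4f} "
                    f"(tol {tol:.3g})"
                )
    return problems


def run_suite(n_graphs: int, check_epc: bool = True) -> list[str]:
    """Random graphs cycling n in 8..25 and p in {0.15, 0.3, 0.5}."""
    problems = []
    for i in range(n_graphs):
        n = 8 + (i * 5) % 18  # 8..25
        p = (0.15, 0.3, 0.5)[i % 3]
        g = random_gene_graph(n, p, seed=1000 + i)
        problems += [f"graph {i} (n={n}, p={p}): {msg}"
                     for msg in check_graph(g, seed=i, check_epc=check_epc)]
    return problems
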