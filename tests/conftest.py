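import numpy as np
import pandas as pd
import pytest

import spongeffects as sp


@pytest.fixture
def toy_edges_df() -> pd.DataFrame:
    """Small annotated edge table: one hub (A) plus a triangle."""
    return pd.DataFrame(
        {
            "geneA": ["A", "A", "A", "B", "B"],
            "geneB": ["B", "C", "D", "C", "E"],
            "weight": [0.2, 0.3, 0.5, 0.4, 0.15],
            "p_adj": [0.01, 0.02, 0.001, 0.03, 0.04],
            "mirnas": ["miR-1;miR-2", "miR-1", "miR-3", "miR-2", ""],
        }
    )


@pytest.fixture
def toy_network(toy_edges_df) -> sp.CeRNANetwork:
    return sp.from_edge_table(toy_edges_df)


def random_network(rng: np.random.Generator, max_nodes: int = 50) -> sp.CeRNANetwork:
    """A random canonical network with positive weights, for oracle checks."""
    n_nodes = int(rng.integers(3, max_nodes + 1))
    nodes = [f"N{i:03d}" for i in range(n_nodes)]
    max_pairs = n_nodes * (n_nodes - 1) // 2
    n_edges = min(int(rng.integers(1, max(2, 3 * n_nodes))), max_pairs)
    pairs = set()
    while len(pairs) < n_edges:
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j:
            pairs.add((min(i, j), max(i, j)))
    pairs = sorted(pairs)
    return sp.from_edge_table(
        pd.DataFrame(
            {
                "gene_a": [nodes[i] for i, _ in pairs],
                "gene_b": [nodes[j] for _, j in pairs],
                "weight": rng.uniform(0.05, 1.0, size=len(pairs)),
                "p_adj": rng.uniform(0.0, 1.0, size=len(pairs)),
            }
        )
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small planted simulation shared across tests: network, modules,
    two scored cohorts, labels, and the planted truth."""
    config = sp.SimulationConfig(
        n_genes=300, n_samples=100, n_hub_genes=5, planted_modules=3, seed=11
    )
    network = sp.simulate_cerna_network(config)
    filtered = sp.filter_network(network)
    centrality = sp.weighted_centrality(filtered)
    centers = sp.top_central_nodes(centrality, k=config.n_hub_genes)
    modules = sp.build_modules(filtered, centers)
    expr, labels = sp.simulate_expression(network, modules, config, seed=12)
    expr_test, labels_test = sp.simulate_expression(network, modules, config, seed=13)
    modules_used = sp.filter_modules(modules, set(expr.index))
    scores = sp.score_oe(expr, modules_used, seed=14)
    scores_test = sp.score_oe(expr_test, modules_used, seed=15)
    return {
        "config": config,
        "network": network,
        "filtered": filtered,
        "centrality": centrality,
        "centers": centers,
        "modules": modules,
        "modules_used": modules_used,
        "expr": expr,
        "labels": labels,
        "expr_test": expr_test,
        "labels_test": labels_test,
        "scores": scores,
        "scores_test": scores_test,
        "truth": sp.planted_assignments(modules, config),
    }


def ssgsea_oracle(values, gene_ids, members, tau=0.25) -> float:
    """Brute-force running-sum ssGSEA for one sample, written from the
    definition: average ranks, decreasing-rank walk (ties by input gene
    order), weighted in-set ECDF vs unweighted out-of-set ECDF."""
    n = len(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        eq = sum(1 for u in values if u == v)
        ranks.append(less + (eq + 1) / 2)
    order = sorted(range(n), key=lambda i: (-ranks[i], i))
    in_set = [gene_ids[i] in members for i in order]
    n_in = sum(in_set)
    n_out = n - n_in
    denom = sum(ranks[order[i]] ** tau for i in range(n) if in_set[i])
    es = 0.0
    cum_in = cum_out = 0.0
    for i in range(n):
        if in_set[i]:
            cum_in += ranks[order[i]] ** tau / denom
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es
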