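"""Synthetic ceRNA networks and expression cohorts with planted module signal.

The generator emulates the study design the scoring machinery targets: a
hub-and-spoke ceRNA network (hubs are strong sponges with many partners, so
"top central node" is well defined), a log-scale expression matrix over the
network's genes, and class labels whose signature is an additive shift of
whole modules — module genes co-shifted up or down in one class, the
transcriptional footprint of a central ceRNA gaining or losing sponge
activity there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modules import ModuleSet
from .network import CeRNANetwork, from_edge_table


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults: a 5-class cohort of 250 samples (50/class), 10 hub modules of
    which 5 carry planted signal, module shift 1.0 on the log2 scale against
    gene noise SD 0.5, and 1500 genes so the planted genes are a small
    minority of the universe that size-matched random modules draw from.
    Edge weights live in (0.1, 1) and adjusted p-values below 0.05, the
    regime of a conventionally filtered ceRNA network.
    """

    n_genes: int = 1500
    n_mirnas: int = 60
    n_samples: int = 250
    n_classes: int = 5
    n_hub_genes: int = 10
    planted_modules: int = 5
    effect_size: float = 1.0
    noise_sd: float = 0.5
    weight_range: tuple[float, float] = (0.15, 0.9)
    p_adj_range: tuple[float, float] = (1e-6, 0.045)
    hub_degree_range: tuple[int, int] = (15, 30)
    background_rounds: int = 2
    mirnas_per_edge: tuple[int, int] = (1, 3)
    baseline_mean_range: tuple[float, float] = (2.0, 12.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_mirnas", "n_samples", "n_classes", "n_hub_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.planted_modules < 0:
            raise ValueError("planted_modules must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_classes > self.n_samples:
            raise ValueError("more classes than samples")


def simulate_cerna_network(config: SimulationConfig) -> CeRNANetwork:
    """Hub-and-spoke ceRNA network with miRNA-annotated edges.

    The first ``n_hub_genes`` genes are hubs; each receives a disjoint set of
    spoke neighbors (degree drawn from ``hub_degree_range``), so hub
    neighborhoods do not overlap and module identity is unambiguous.  The
    remaining genes are wired in ``background_rounds`` rounds of random
    pairing, giving a low-degree background against which hubs dominate the
    strength ranking.  Every edge gets a weight and adjusted p-value from the
    configured ranges and 1-3 shared miRNAs from the miRNA pool.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    mirnas = [f"miR-{i:03d}" for i in range(config.n_mirnas)]
    hubs = genes[: config.n_hub_genes]

    lo, hi = config.hub_degree_range
    degrees = rng.integers(lo, hi + 1, size=config.n_hub_genes)
    if config.n_hub_genes + int(degrees.sum()) > config.n_genes:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {config.n_hub_genes} hubs "
            f"with degrees summing to {int(degrees.sum())}"
        )

    pool = list(np.array(genes[config.n_hub_genes:])[rng.permutation(
        config.n_genes - config.n_hub_genes
    )])
    pairs: list[tuple[str, str]] = []
    offset = 0
    for hub, deg in zip(hubs, degrees):
        for spoke in pool[offset: offset + int(deg)]:
            pairs.append((hub, spoke))
        offset += int(deg)

    background = pool[offset:]
    seen = {tuple(sorted(p)) for p in pairs}
    for _ in range(config.background_rounds):
        perm = rng.permutation(len(background))
        for i in range(0, len(background) - 1, 2):
            a, b = background[perm[i]], background[perm[i + 1]]
            key = tuple(sorted((a, b)))
            if key not in seen:
                seen.add(key)
                pairs.append((a, b))

    n_edges = len(pairs)
    weights = rng.uniform(*config.weight_range, size=n_edges)
    p_adj = rng.uniform(*config.p_adj_range, size=n_edges)
    n_per_edge = rng.integers(
        config.mirnas_per_edge[0], config.mirnas_per_edge[1] + 1, size=n_edges
    )
    annotations = [
        ";".join(sorted(rng.choice(mirnas, size=k, replace=False)))
        for k in n_per_edge
    ]
    table = pd.DataFrame(
        {
            "gene_a": [p[0] for p in pairs],
            "gene_b": [p[1] for p in pairs],
            "weight": weights,
            "p_adj": p_adj,
            "mirnas": annotations,
        }
    )
    return from_edge_table(table)


def planted_assignments(
    modules: ModuleSet, config: SimulationConfig
) -> list[dict]:
    """Which modules carry signal, in which class, with which sign.

    The first ``planted_modules`` modules (set iteration order) are
    informative: module *i* is shifted in class ``i mod n_classes``, with
    sign alternating (+, -, +, ...) so both activity gains and losses occur.
    """
    centers = list(modules.keys())
    if config.planted_modules > len(centers):
        raise ValueError(
            f"planted_modules={config.planted_modules} exceeds module count {len(centers)}"
        )
    return [
        {
            "module": centers[i],
            "class_index": i % config.n_classes,
            "sign": 1 if i % 2 == 0 else -1,
        }
        for i in range(config.planted_modules)
    ]


def simulate_expression(
    network: CeRNANetwork,
    modules: ModuleSet,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-scale expression for every network gene plus balanced class labels.

    Each gene gets a baseline mean drawn uniformly from
    ``baseline_mean_range`` (spreading genes across OE's expression bins) and
    i.i.d. Gaussian noise with SD ``noise_sd``.  For every planted
    (module, class, sign) triple the module's member genes are shifted by
    ``sign * effect_size`` in that class's samples.  Class sizes are balanced
    to within one sample.  ``seed`` defaults to ``config.seed``; pass a
    different one to draw an independent cohort with the same planted truth.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = network.nodes
    if not genes:
        raise ValueError("network has no nodes")
    n_genes, n_samples = len(genes), config.n_samples
    samples = [f"S{i:04d}" for i in range(n_samples)]

    base = n_samples // config.n_classes
    extra = n_samples % config.n_classes
    label_list: list[str] = []
    for c in range(config.n_classes):
        label_list.extend([f"class{c}"] * (base + (1 if c < extra else 0)))
    labels = pd.Series(label_list, index=samples, name="label")

    lo, hi = config.baseline_mean_range
    mu = rng.uniform(lo, hi, size=n_genes)
    values = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))

    gene_row = {g: i for i, g in enumerate(genes)}
    for planted in planted_assignments(modules, config):
        members = modules[planted["module"]].members
        rows = [gene_row[g] for g in sorted(members) if g in gene_row]
        cols = np.flatnonzero((labels == f"class{planted['class_index']}").to_numpy())
        values[np.ix_(rows, cols)] += planted["sign"] * config.effect_size

    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return expr, labels
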