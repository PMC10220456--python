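"""Planted-signal benchmarks exercising the whole method in simulation.

These routines run the complete workflow — synthetic ceRNA network,
filtering, centrality, module construction, OE scoring, random-forest
training — under the generator's default study conditions and measure what
the method should deliver: near-perfect external-cohort subtype recovery
from real modules, chance-level performance from size-matched random
modules and from permuted labels, recovery of the informative modules in
the importance ranking, and robustness of the planted-class score
separation to missing module genes.
"""

from __future__ import annotations

import numpy as np

from .classify import (
    ModelSpec,
    cross_validate,
    evaluate_external,
    gini_importance,
)
from .enrichment import score_oe
from .modules import build_modules, filter_modules, sample_random_modules
from .network import filter_network, top_central_nodes, weighted_centrality
from .simulate import (
    SimulationConfig,
    planted_assignments,
    simulate_cerna_network,
    simulate_expression,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _build_scored_cohorts(config: SimulationConfig, seed: int):
    """Shared front end: network → modules → two scored cohorts + labels."""
    (net_seed, expr_a, expr_b, oe_a, oe_b) = _child_seeds(seed, 5)
    config = SimulationConfig(**{**config.__dict__, "seed": net_seed})
    network = simulate_cerna_network(config)
    filtered = filter_network(network)
    centrality = weighted_centrality(filtered, alpha=1.0)
    centers = top_central_nodes(centrality, k=config.n_hub_genes)
    modules = build_modules(filtered, centers)

    expr_train, y_train = simulate_expression(network, modules, config, seed=expr_a)
    expr_test, y_test = simulate_expression(network, modules, config, seed=expr_b)
    modules_used = filter_modules(modules, set(expr_train.index))
    scores_train = score_oe(expr_train, modules_used, seed=oe_a)
    scores_test = score_oe(expr_test, modules_used, seed=oe_b)
    truth = planted_assignments(modules, config)
    return {
        "config": config,
        "network": network,
        "filtered": filtered,
        "modules": modules,
        "modules_used": modules_used,
        "expr_train": expr_train,
        "expr_test": expr_test,
        "y_train": y_train,
        "y_test": y_test,
        "scores_train": scores_train,
        "scores_test": scores_test,
        "truth": truth,
    }


def planted_recovery(
    seed: int = 1,
    config: SimulationConfig | None = None,
    folds: int = 10,
    repeats: int = 3,
    n_estimators: int = 300,
) -> dict:
    """Train on one simulated cohort, test on an independent one; compare
    real modules against the size-matched random-module null.

    Returns external subset accuracies for both module sets, CV accuracy,
    and how many informative modules land in the top-5 Gini ranking.
    """
    config = config or SimulationConfig()
    parts = _build_scored_cohorts(config, seed)
    (cv_seed, rand_seed, oe_ra, oe_rb, cv_rand_seed) = _child_seeds(seed + 1, 5)

    spec = ModelSpec(family="random_forest", fixed={"n_estimators": n_estimators})
    result = cross_validate(
        parts["scores_train"], parts["y_train"], spec=spec,
        folds=folds, repeats=repeats, seed=cv_seed,
    )
    test_acc = evaluate_external(result, parts["scores_test"], parts["y_test"])

    universe = set(parts["filtered"].nodes) & set(parts["expr_train"].index)
    random_modules = sample_random_modules(parts["modules_used"], universe, seed=rand_seed)
    rand_train = score_oe(parts["expr_train"], random_modules, seed=oe_ra)
    rand_test = score_oe(parts["expr_test"], random_modules, seed=oe_rb)
    rand_result = cross_validate(
        rand_train, parts["y_train"], spec=spec,
        folds=folds, repeats=repeats, seed=cv_rand_seed,
    )
    rand_acc = evaluate_external(rand_result, rand_test, parts["y_test"])

    informative = {t["module"] for t in parts["truth"]}
    top5 = set(gini_importance(result, top_k=5).index)
    return {
        "real_cv_accuracy": result.cv_subset_accuracy,
        "real_test_accuracy": test_acc,
        "random_cv_accuracy": rand_result.cv_subset_accuracy,
        "random_test_accuracy": rand_acc,
        "informative_in_top5": len(informative & top5),
        "n_informative": len(informative),
        "n_modules": len(parts["modules_used"]),
        "n_train": len(parts["y_train"]),
        "n_test": len(parts["y_test"]),
        "best_params": result.best_params,
    }


def null_calibration(
    seed: int = 1,
    n_reps: int = 20,
    config: SimulationConfig | None = None,
    folds: int = 5,
    n_estimators: int = 200,
) -> dict:
    """CV subset accuracy under label permutation: the chance floor.

    Real pipeline scores are computed once on a simulated cohort; labels are
    then permuted uniformly ``n_reps`` times and a forest cross-validated on
    each permutation.  With k balanced classes the accuracies should sit in
    the binomial band around 1/k.
    """
    config = config or SimulationConfig(n_genes=600, n_samples=150)
    parts = _build_scored_cohorts(config, seed)
    scores, labels = parts["scores_train"], parts["y_train"]
    k = config.n_classes
    n = len(labels)

    rng = np.random.default_rng(_child_seeds(seed + 2, 1)[0])
    spec = ModelSpec(
        family="random_forest",
        grid={"mtry": [max(1, round(np.sqrt(len(scores.values))))]},
        fixed={"n_estimators": n_estimators},
    )
    accuracies = []
    for _ in range(n_reps):
        permuted = labels.iloc[rng.permutation(n)]
        permuted.index = labels.index
        cv_seed = int(rng.integers(0, 2**31))
        res = cross_validate(scores, permuted, spec=spec, folds=folds,
                             repeats=1, seed=cv_seed)
        accuracies.append(res.cv_subset_accuracy)

    p = 1.0 / k
    half_width = 2.5758 * np.sqrt(p * (1 - p) / n)  # 99% normal band at one rep's n
    return {
        "accuracies": accuracies,
        "mean_accuracy": float(np.mean(accuracies)),
        "chance": p,
        "band": (p - half_width, p + half_width),
        "n_samples": n,
        "n_reps": n_reps,
    }


def missing_gene_robustness(
    seed: int = 1,
    n_trials: int = 100,
    drop_fraction: float = 0.3,
    config: SimulationConfig | None = None,
    min_size: int = 10,
) -> dict:
    """Does planted-class score separation survive missing module genes?

    Per trial, a fresh cohort is simulated and a random ``drop_fraction`` of
    each planted module's genes is deleted from the expression matrix
    (keeping at least ``min_size``); after OE scoring, a trial counts as a
    flip if any planted module's class-vs-rest mean-score difference has the
    wrong sign.  Returns the flip rate over ``n_trials``.
    """
    config = config or SimulationConfig(
        n_genes=400, n_samples=100, n_hub_genes=5, planted_modules=3
    )
    base_seed, *trial_seeds = _child_seeds(seed + 3, n_trials + 1)
    config = SimulationConfig(**{**config.__dict__, "seed": base_seed})
    network = simulate_cerna_network(config)
    filtered = filter_network(network)
    centrality = weighted_centrality(filtered, alpha=1.0)
    centers = top_central_nodes(centrality, k=config.n_hub_genes)
    modules = build_modules(filtered, centers)
    truth = planted_assignments(modules, config)

    flips = 0
    for t_seed in trial_seeds:
        rng = np.random.default_rng(t_seed)
        expr, labels = simulate_expression(network, modules, config, seed=int(
            rng.integers(0, 2**31)
        ))
        drop: set[str] = set()
        for planted in truth:
            members = sorted(modules[planted["module"]].members)
            n_drop = min(
                int(round(drop_fraction * len(members))),
                max(0, len(members) - min_size),
            )
            if n_drop > 0:
                drop.update(
                    np.array(members)[rng.choice(len(members), n_drop, replace=False)]
                )
        expr_reduced = expr.drop(index=[g for g in drop if g in expr.index])
        modules_used = filter_modules(modules, set(expr_reduced.index),
                                      min_size=min_size)
        scores = score_oe(expr_reduced, modules_used,
                          seed=int(rng.integers(0, 2**31)))

        flipped = False
        for planted in truth:
            if planted["module"] not in modules_used:
                continue
            row = scores.values.loc[planted["module"]]
            in_class = labels == f"class{planted['class_index']}"
            sep = row[in_class.to_numpy()].mean() - row[~in_class.to_numpy()].mean()
            if np.sign(sep) != planted["sign"]:
                flipped = True
        flips += int(flipped)

    return {
        "n_trials": n_trials,
        "flips": flips,
        "flip_rate": flips / n_trials,
        "drop_fraction": drop_fraction,
    }
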