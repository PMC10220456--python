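"""End-to-end orchestration: filter → centrality → modules → scores → model.

The pipeline reads plain-text inputs (edge TSV, expression TSV/CSV, label
TSV, optional gene-class TSV), writes every intermediate as a plain-text
artifact (TSV/GMT/JSON) into a run directory, and records a manifest with
parameter values, derived seeds, stage attrition counts and SHA-256
checksums of inputs and outputs, so a run can be audited and reproduced
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    ModelSpec,
    cross_validate,
    evaluate_external,
    gini_importance,
    save_model,
)
from .enrichment import (
    read_expression,
    score_oe,
    score_ssgsea,
    standardize_scores,
    validate_expression,
    write_scores,
)
from .modules import (
    build_modules,
    filter_modules,
    sample_random_modules,
    verify_modules,
    write_gmt,
)
from .network import (
    filter_network,
    read_edge_table,
    top_central_nodes,
    weighted_centrality,
    write_edge_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; round-trips through YAML."""

    edges: str
    expression_train: str
    labels_train: str | None = None
    expression_test: str | None = None
    labels_test: str | None = None
    gene_classes: str | None = None
    center_class: str | None = None

    weight_col: str | None = None
    p_adj_max: float = 0.05
    weight_min: float = 0.1
    alpha: float = 1.0
    top_k: int = 750
    include_center: bool = True
    min_module_size: int = 10
    max_module_size: int = 200

    method: str = "oe"
    n_bins: int = 50
    n_control_draws: int = 100
    tau: float = 0.25
    standardize: bool = False

    model: str = "random_forest"
    folds: int = 10
    repeats: int = 3
    importance_top_k: int = 20
    randomize: bool = False

    seed: int = 42
    outdir: str = "spongeffects_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"label table {path} needs sample_id and label columns")
    return pd.Series(
        df.iloc[:, 1].astype(str).to_numpy(),
        index=df.iloc[:, 0].astype(str),
        name="label",
    )


def _derived_seeds(seed: int) -> dict[str, int]:
    """Independent per-stage seeds, all below 2**31, reproducible from the
    master seed."""
    ss = np.random.SeedSequence(seed)
    names = ("score_train", "score_test", "cv", "randomize", "score_random_train",
             "score_random_test", "cv_random")
    children = ss.spawn(len(names))
    return {
        n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)
    }


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _score(expr, modules, config: RunConfig, seed: int):
    if config.method == "oe":
        sm = score_oe(
            expr, modules, n_bins=config.n_bins,
            n_control_draws=config.n_control_draws, seed=seed,
        )
    elif config.method == "ssgsea":
        sm = score_ssgsea(expr, modules, tau=config.tau)
    else:
        raise ValueError(f"unknown enrichment method {config.method!r}")
    if config.standardize:
        sm = standardize_scores(sm)
    return sm


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow and return the run directory.

    Stages (each writes its artifact before the next starts, so partial
    output survives a failure): network filtering, weighted centrality,
    center selection, module construction, size filtering against each
    cohort, enrichment scoring, cross-validated training, external
    evaluation, Gini importance, and — when ``randomize`` is on — the same
    scoring/training protocol on size-matched random modules.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _derived_seeds(config.seed)
    manifest: dict = {
        "tool": "spongeffects",
        "version": __version__,
        "config": asdict(config),
        "seeds": seeds,
        "inputs": {},
        "outputs": {},
        "counts": {},
        "results": {},
    }
    for key in ("edges", "expression_train", "labels_train", "expression_test",
                "labels_test", "gene_classes"):
        path = getattr(config, key)
        if path:
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(Path(path))}

    def emit(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "load"
    try:
        network = read_edge_table(config.edges, weight_col=config.weight_col)
        manifest["counts"]["edges_input"] = network.n_edges

        stage = "filter_network"
        filtered = filter_network(network, config.p_adj_max, config.weight_min)
        manifest["counts"]["edges_kept"] = filtered.n_edges
        path = outdir / "filtered_edges.tsv"
        write_edge_table(filtered, path)
        emit("filtered_edges", path)

        stage = "centrality"
        centrality = weighted_centrality(filtered, alpha=config.alpha)
        path = outdir / "centrality.tsv"
        centrality.to_csv(path, sep="\t")
        emit("centrality", path)

        stage = "select_centers"
        restrict = None
        if config.center_class:
            if not config.gene_classes:
                raise ValueError("center_class set but no gene_classes table given")
            ann = pd.read_csv(config.gene_classes, sep="\t")
            restrict = set(
                ann.loc[ann.iloc[:, 1].astype(str) == config.center_class]
                .iloc[:, 0].astype(str)
            )
        centers = top_central_nodes(centrality, k=config.top_k, restrict_to=restrict)
        manifest["counts"]["centers"] = len(centers)

        stage = "build_modules"
        modules = build_modules(filtered, centers, include_center=config.include_center)
        verify_modules(modules, filtered)
        path = outdir / "modules.gmt"
        write_gmt(modules, path)
        emit("modules", path)

        stage = "expression_train"
        expr_train = validate_expression(read_expression(config.expression_train))

        stage = "filter_modules"
        expressed = set(expr_train.index)
        expr_test = None
        if config.expression_test:
            expr_test = validate_expression(read_expression(config.expression_test))
            # cross-cohort protocol: a module must be scoreable in both
            # cohorts, so size filtering applies per cohort and the
            # intersection of survivors is used
            modules_used = filter_modules(
                filter_modules(modules, expressed, config.min_module_size,
                               config.max_module_size),
                set(expr_test.index), config.min_module_size, config.max_module_size,
            )
        else:
            modules_used = filter_modules(
                modules, expressed, config.min_module_size, config.max_module_size
            )
        if len(modules_used) == 0:
            raise ValueError("no module passed the size filter")
        manifest["counts"]["modules_kept"] = len(modules_used)
        path = outdir / "modules_filtered.gmt"
        write_gmt(modules_used, path)
        emit("modules_filtered", path)

        stage = "score_train"
        scores_train = _score(expr_train, modules_used, config, seeds["score_train"])
        path = outdir / "scores_train.tsv"
        write_scores(scores_train, path)
        emit("scores_train", path)

        scores_test = None
        if expr_test is not None:
            stage = "score_test"
            scores_test = _score(expr_test, modules_used, config, seeds["score_test"])
            path = outdir / "scores_test.tsv"
            write_scores(scores_test, path)
            emit("scores_test", path)

        results: dict = {}
        result = None
        if config.labels_train:
            stage = "train"
            y_train = _read_labels(config.labels_train)
            spec = ModelSpec(family=config.model)
            result = cross_validate(
                scores_train, y_train, spec=spec,
                folds=config.folds, repeats=config.repeats, seed=seeds["cv"],
            )
            save_model(result, outdir / "model.joblib")
            results["best_params"] = result.best_params
            results["cv_subset_accuracy"] = result.cv_subset_accuracy
            results["train_subset_accuracy"] = result.train_subset_accuracy

            if config.model == "random_forest":
                stage = "importance"
                imp = gini_importance(
                    result, top_k=min(config.importance_top_k, len(modules_used))
                )
                path = outdir / "importance.tsv"
                imp.rename_axis("module").to_csv(path, sep="\t")
                emit("importance", path)
                results["top_modules"] = list(imp.index)

            if scores_test is not None and config.labels_test:
                stage = "evaluate_external"
                y_test = _read_labels(config.labels_test)
                results["test_subset_accuracy"] = evaluate_external(
                    result, scores_test, y_test
                )

        if config.randomize:
            stage = "randomize"
            universe = set(modules.gene_universe or []) & set(expr_train.index)
            if expr_test is not None:
                universe &= set(expr_test.index)
            random_modules = sample_random_modules(
                modules_used, universe, seed=seeds["randomize"]
            )
            path = outdir / "modules_random.gmt"
            write_gmt(random_modules, path)
            emit("modules_random", path)

            stage = "score_random"
            rand_train = _score(expr_train, random_modules, config,
                                seeds["score_random_train"])
            path = outdir / "scores_random_train.tsv"
            write_scores(rand_train, path)
            emit("scores_random_train", path)

            if config.labels_train:
                stage = "train_random"
                rand_result = cross_validate(
                    rand_train, _read_labels(config.labels_train),
                    spec=ModelSpec(family=config.model),
                    folds=config.folds, repeats=config.repeats,
                    seed=seeds["cv_random"],
                )
                results["random_cv_subset_accuracy"] = rand_result.cv_subset_accuracy
                if expr_test is not None and config.labels_test:
                    rand_test = _score(expr_test, random_modules, config,
                                       seeds["score_random_test"])
                    path = outdir / "scores_random_test.tsv"
                    write_scores(rand_test, path)
                    emit("scores_random_test", path)
                    results["random_test_subset_accuracy"] = evaluate_external(
                        rand_result, rand_test, _read_labels(config.labels_test)
                    )

        manifest["results"] = results
        stage = "manifest"
        results_path = outdir / "results.json"
        with open(results_path, "w", encoding="utf-8") as fh:
            json.dump(results, fh, indent=2)
        emit("results", results_path)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        raise StageError(f"[stage {stage}] {exc}") from exc

    return outdir
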