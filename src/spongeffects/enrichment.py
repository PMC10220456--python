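"""Sample-specific module activity scores via single-sample enrichment.

Two engines turn a genes × samples expression matrix plus a set of ceRNA
modules into a modules × samples score matrix:

* **OE (Overall Expression)** — the default.  Expression is centered per
  gene across samples; genes are grouped into equal-frequency bins by mean
  expression; the module score of a sample is the mean centered expression
  of the module genes minus the average of bin-matched random control gene
  sets.  The control subtraction removes the technical component shared by
  genes of similar abundance.

* **ssGSEA** — a rank statistic computed within each sample: the sum over
  the expression-ordered gene list of the difference between the
  tau-weighted in-set cumulative distribution and the unweighted out-of-set
  cumulative distribution.

Both are unsupervised and single-sample: no phenotype labels enter the
scores, and a module can be scored even when some of its genes (including
the central ceRNA) are missing from the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .modules import ModuleSet

logger = logging.getLogger(__name__)


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes × samples expression matrix and apply the missing-data
    policy: genes with any missing value are dropped (count logged).

    Raises on duplicate gene or sample identifiers and on non-finite values
    that are not NaN.
    """
    if expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
    if expr.columns.duplicated().any():
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
    values = expr.to_numpy(dtype=float)
    has_nan = np.isnan(values).any(axis=1)
    if has_nan.any():
        logger.warning(
            "dropping %d gene(s) with missing values", int(has_nan.sum())
        )
        expr = expr.loc[~has_nan]
        values = values[~has_nan]
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    return expr


@dataclass
class ScoreMatrix:
    """Modules × samples enrichment scores with method provenance."""

    values: pd.DataFrame
    method: str
    params: dict = field(default_factory=dict)

    @property
    def module_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _mean_expression_bins(expr: pd.DataFrame, n_bins: int) -> np.ndarray:
    """Equal-frequency bin label per gene, binned on mean expression.

    Genes are ordered by (mean, gene id) — the id tie-break makes the
    assignment deterministic — and split into n_bins contiguous chunks of
    near-equal size.
    """
    n_genes = len(expr)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > n_genes:
        raise ValueError(f"n_bins={n_bins} exceeds the number of genes ({n_genes})")
    means = expr.mean(axis=1)
    order = np.lexsort((np.asarray(expr.index, dtype=object), means.to_numpy()))
    ranks = np.empty(n_genes, dtype=np.intp)
    ranks[order] = np.arange(n_genes)
    return (ranks * n_bins) // n_genes


def score_oe(
    expr: pd.DataFrame,
    modules: ModuleSet,
    n_bins: int = 50,
    n_control_draws: int = 100,
    seed: int = 0,
) -> ScoreMatrix:
    """Overall Expression scores: centered module mean minus bin-matched
    random controls.

    For each module gene, every control draw samples one gene from the same
    mean-expression bin (uniformly, with replacement); the score of sample
    *j* is ``mean(centered module genes in j) - mean over draws of
    mean(centered control genes in j)``.  With expression constant across
    samples all centered values — module and control alike — are zero, so
    scores are exactly zero.

    Modules must already have been size-filtered against ``expr``'s genes;
    a module with no measured member is an error.
    """
    expr = validate_expression(expr)
    genes = list(expr.index)
    gene_index = {g: i for i, g in enumerate(genes)}
    values = expr.to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    # a gene constant across samples has zero relative expression by
    # definition; enforce it exactly rather than leave rounding residue
    constant = values.max(axis=1) == values.min(axis=1)
    centered[constant] = 0.0

    bins = _mean_expression_bins(expr, n_bins)
    bin_pools = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}

    rng = np.random.default_rng(seed)
    rows = []
    index = []
    for mod in modules:
        measured = sorted(mod.members & gene_index.keys())
        if not measured:
            raise ValueError(
                f"module {mod.center!r} has no member measured in the "
                "expression matrix; size-filter modules first"
            )
        idx = np.fromiter((gene_index[g] for g in measured), dtype=np.intp)
        module_score = centered[idx].mean(axis=0)

        # bin-matched controls: (n_control_draws, n_members) gene indices
        control = np.empty((n_control_draws, len(idx)), dtype=np.intp)
        for j, gi in enumerate(idx):
            pool = bin_pools[bins[gi]]
            control[:, j] = pool[rng.integers(0, len(pool), size=n_control_draws)]
        control_score = centered[control].mean(axis=1).mean(axis=0)

        rows.append(module_score - control_score)
        index.append(mod.center)

    frame = pd.DataFrame(rows, index=pd.Index(index, name="module"), columns=expr.columns)
    return ScoreMatrix(
        values=frame,
        method="OE",
        params={"n_bins": n_bins, "n_control_draws": n_control_draws, "seed": seed},
    )


def score_ssgsea(
    expr: pd.DataFrame,
    modules: ModuleSet,
    tau: float = 0.25,
    normalize: bool = False,
) -> ScoreMatrix:
    """ssGSEA scores: per-sample weighted in-set vs out-of-set rank ECDFs.

    Within each sample, genes get average ranks (ties shared); walking the
    gene list in decreasing-rank order, the enrichment statistic is

        ES = sum_i [ P_in(i) - P_out(i) ]

    where ``P_in`` is the cumulative sum of in-set gene weights
    ``rank**tau`` normalized by their total, and ``P_out`` the unweighted
    cumulative fraction of out-of-set genes.  Depending only on ranks, the
    score is invariant under any strictly increasing per-sample transform of
    expression.  ``normalize`` divides all scores by the global score range.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    expr = validate_expression(expr)
    genes = list(expr.index)
    n_genes = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    values = expr.to_numpy(dtype=float)
    n_samples = values.shape[1]

    member_idx: dict[str, np.ndarray] = {}
    for mod in modules:
        measured = sorted(mod.members & gene_index.keys())
        if not measured:
            raise ValueError(
                f"module {mod.center!r} has no member measured in the expression matrix"
            )
        if len(measured) == n_genes:
            raise ValueError(
                f"module {mod.center!r} covers every measured gene; the "
                "out-of-set distribution is undefined"
            )
        member_idx[mod.center] = np.fromiter(
            (gene_index[g] for g in measured), dtype=np.intp
        )

    scores = np.zeros((len(member_idx), n_samples))
    centers = list(member_idx)
    for j in range(n_samples):
        ranks = rankdata(values[:, j], method="average")
        # decreasing rank; ties between genes broken by input gene order
        order = np.lexsort((np.arange(n_genes), -ranks))
        ranked_w = ranks[order] ** tau
        for mi, center in enumerate(centers):
            in_set = np.zeros(n_genes, dtype=bool)
            in_set[member_idx[center]] = True
            in_ordered = in_set[order]
            w_in = np.where(in_ordered, ranked_w, 0.0)
            p_in = np.cumsum(w_in) / w_in.sum()
            n_out = n_genes - in_ordered.sum()
            p_out = np.cumsum(~in_ordered) / n_out
            scores[mi, j] = float(np.sum(p_in - p_out))

    frame = pd.DataFrame(
        scores, index=pd.Index(centers, name="module"), columns=expr.columns
    )
    params = {"tau": tau, "normalize": normalize}
    if normalize:
        span = frame.to_numpy().max() - frame.to_numpy().min()
        if span > 0:
            frame = frame / span
        else:
            logger.warning("score range is zero; normalization skipped")
    return ScoreMatrix(values=frame, method="ssGSEA", params=params)


def standardize_scores(scores: ScoreMatrix) -> ScoreMatrix:
    """Per-module z-scores across samples (heatmap-style preprocessing).
    Modules with zero variance map to all-zero rows."""
    frame = scores.values
    std = frame.std(axis=1, ddof=1).replace(0.0, np.nan)
    out = frame.sub(frame.mean(axis=1), axis=0).div(std, axis=0).fillna(0.0)
    return ScoreMatrix(
        values=out, method=scores.method, params={**scores.params, "standardized": True}
    )


def read_expression(path) -> pd.DataFrame:
    """Read a genes × samples expression table (TSV, or CSV when the filename
    ends in .csv/.csv.gz; first column = gene ids, header = sample ids)."""
    sep = "," if ".csv" in str(path) else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def write_scores(scores: ScoreMatrix, path) -> None:
    """Write a modules × samples score matrix as TSV."""
    scores.values.to_csv(path, sep="\t")


def read_scores(path, method: str = "unknown") -> ScoreMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ScoreMatrix(values=values, method=method)
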