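"""ceRNA network handling: edge tables, filtering, weighted degree centrality.

A ceRNA (competing endogenous RNA) network is an undirected, weighted graph
whose nodes are genes and whose edges represent inferred miRNA-mediated
cross-talk between gene pairs.  Edge weights are effect sizes such as mscor
(multiple sensitivity correlation) or plain correlation; edges may carry an
adjusted p-value and the list of miRNAs shared by the pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical internal column names of an edge table
EDGE_COLUMNS = ("gene_a", "gene_b", "weight", "p_adj", "mirnas")

_GENE_COL_ALIASES = {
    "geneA": "gene_a",
    "geneB": "gene_b",
    "genea": "gene_a",
    "geneb": "gene_b",
}

#: weight column names tried, in order, when none is given explicitly
_WEIGHT_CANDIDATES = ("weight", "mscor", "corr")


def _parse_mirnas(value) -> tuple[str, ...]:
    if isinstance(value, tuple):
        return value
    if isinstance(value, (list, set, frozenset)):
        return tuple(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ()
    if isinstance(value, str):
        return tuple(m for m in value.split(";") if m)
    raise TypeError(f"cannot interpret miRNA annotation {value!r}")


@dataclass(frozen=True)
class CeRNANetwork:
    """Undirected weighted gene-gene network stored as a canonical edge table.

    ``edges`` has columns ``gene_a``, ``gene_b``, ``weight`` and optionally
    ``p_adj`` and ``mirnas`` (tuples of miRNA identifiers).  Edges are
    canonical: ``gene_a < gene_b`` lexicographically, no self-loops, no
    duplicate pairs.  Construct via :func:`from_edge_table` or
    :func:`read_edge_table` rather than directly.
    """

    edges: pd.DataFrame

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> list[str]:
        """Sorted list of all genes incident to at least one edge."""
        if self.edges.empty:
            return []
        return sorted(
            set(self.edges["gene_a"]).union(self.edges["gene_b"])
        )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def has_p_adj(self) -> bool:
        return "p_adj" in self.edges.columns and self.edges["p_adj"].notna().all()

    @property
    def has_mirnas(self) -> bool:
        return "mirnas" in self.edges.columns and any(
            len(m) > 0 for m in self.edges["mirnas"]
        )

    def adjacency(self) -> dict[str, set[str]]:
        """Node -> set of first-degree neighbors."""
        adj: dict[str, set[str]] = {}
        for a, b in zip(self.edges["gene_a"], self.edges["gene_b"]):
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj

    def neighbors(self, gene: str) -> set[str]:
        mask_a = self.edges["gene_a"] == gene
        mask_b = self.edges["gene_b"] == gene
        return set(self.edges.loc[mask_b, "gene_a"]).union(
            self.edges.loc[mask_a, "gene_b"]
        )


def from_edge_table(
    df: pd.DataFrame,
    weight_col: str | None = None,
    p_adj_col: str = "p_adj",
    mirna_col: str = "mirnas",
) -> CeRNANetwork:
    """Build a canonical :class:`CeRNANetwork` from a raw edge table.

    Canonicalization: endpoint pairs are ordered lexicographically, self-loops
    are dropped with a warning, duplicate (undirected) pairs are collapsed
    keeping the first occurrence.  Weights must be finite; adjusted p-values,
    when present, must lie in [0, 1].

    Parameters
    ----------
    weight_col
        Name of the effect-size column (``mscor``, ``corr``, ``weight`` ...).
        When None, the first of ``weight``/``mscor``/``corr`` found is used.
    """
    df = df.rename(columns=_GENE_COL_ALIASES).copy()
    for col in ("gene_a", "gene_b"):
        if col not in df.columns:
            raise ValueError(f"edge table lacks required column {col!r} (or geneA/geneB)")

    if weight_col is None:
        for cand in _WEIGHT_CANDIDATES:
            if cand in df.columns:
                weight_col = cand
                break
        else:
            raise ValueError(
                f"no weight column found; expected one of {_WEIGHT_CANDIDATES}"
            )
    if weight_col not in df.columns:
        raise ValueError(f"weight column {weight_col!r} not in edge table")

    out = pd.DataFrame(
        {
            "gene_a": df["gene_a"].astype(str),
            "gene_b": df["gene_b"].astype(str),
            "weight": pd.to_numeric(df[weight_col]),
        }
    )
    if not np.isfinite(out["weight"]).all():
        raise ValueError("non-finite edge weights present")

    if p_adj_col in df.columns:
        p = pd.to_numeric(df[p_adj_col])
        valid = p.dropna()
        if ((valid < 0) | (valid > 1)).any():
            raise ValueError("p_adj values outside [0, 1]")
        out["p_adj"] = p
    if mirna_col in df.columns:
        out["mirnas"] = [_parse_mirnas(v) for v in df[mirna_col]]

    # canonical undirected orientation
    swap = out["gene_a"] > out["gene_b"]
    out.loc[swap, ["gene_a", "gene_b"]] = out.loc[swap, ["gene_b", "gene_a"]].values

    loops = out["gene_a"] == out["gene_b"]
    if loops.any():
        logger.warning("dropping %d self-loop edge(s)", int(loops.sum()))
        out = out[~loops]

    dup = out.duplicated(subset=["gene_a", "gene_b"])
    if dup.any():
        logger.warning("collapsing %d duplicate edge(s)", int(dup.sum()))
        out = out[~dup]

    out = out.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(drop=True)
    return CeRNANetwork(out)


def filter_network(
    network: CeRNANetwork,
    p_adj_max: float = 0.05,
    weight_min: float = 0.1,
    adjust_p: bool = False,
) -> CeRNANetwork:
    """Keep edges that are significant and have a non-negligible effect size.

    An edge survives iff ``weight > weight_min`` and, when adjusted p-values
    are available, ``p_adj < p_adj_max``.  Defaults (0.05, 0.1) are the
    conventional thresholds for SPONGE/Hermes-style ceRNA networks.  For
    correlation-only networks that carry no p-value column, only the weight
    criterion applies (logged).

    Parameters
    ----------
    adjust_p
        Treat the p-value column as *raw* p-values and apply Benjamini-
        Hochberg FDR control before thresholding.  Off by default: ceRNA
        inference tools normally report already-adjusted p-values.
    """
    if not (0 < p_adj_max <= 1):
        raise ValueError("p_adj_max must lie in (0, 1]")
    if weight_min < 0:
        raise ValueError("weight_min must be >= 0")
    edges = network.edges
    if not np.isfinite(edges["weight"]).all():
        raise ValueError("non-finite edge weights present")

    mask = edges["weight"].to_numpy() > weight_min
    if "p_adj" in edges.columns and edges["p_adj"].notna().any():
        p = edges["p_adj"].to_numpy(dtype=float)
        if np.isnan(p).any():
            raise ValueError(
                "p_adj present for some edges but missing for others; "
                "mixed significance semantics are ambiguous"
            )
        if adjust_p:
            from scipy.stats import false_discovery_control

            p = false_discovery_control(p, method="bh")
        mask &= p < p_adj_max
    else:
        logger.warning(
            "no p_adj column: filtering on effect size only (weight > %g)",
            weight_min,
        )
    kept = edges[mask].reset_index(drop=True)
    logger.info("filter_network: kept %d / %d edges", len(kept), len(edges))
    return CeRNANetwork(kept)


def weighted_centrality(network: CeRNANetwork, alpha: float = 1.0) -> pd.DataFrame:
    """Per-node degree, strength, and alpha-weighted degree centrality.

    For node *i*, degree is the number of incident edges, strength the sum of
    incident edge weights, and

        centrality_i(alpha) = degree_i**(1 - alpha) * strength_i**alpha,

    interpolating between counting edges (alpha=0) and summing weights
    (alpha=1, the default used to rank ceRNAs by total sponge cross-talk).
    Isolated nodes, should they appear, get centrality 0 by convention.

    Returns a DataFrame indexed by gene with columns ``degree``, ``strength``,
    ``centrality``, sorted by gene; ``.attrs["alpha"]`` records alpha.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    edges = network.edges
    if edges.empty:
        raise ValueError("cannot compute centrality on an empty network")
    w = edges["weight"].to_numpy(dtype=float)
    if (w < 0).any():
        raise ValueError("negative edge weights: strength assumes w_ij > 0")

    nodes = network.nodes
    index = {g: i for i, g in enumerate(nodes)}
    ia = np.fromiter((index[g] for g in edges["gene_a"]), dtype=np.intp, count=len(edges))
    ib = np.fromiter((index[g] for g in edges["gene_b"]), dtype=np.intp, count=len(edges))

    degree = np.zeros(len(nodes), dtype=np.int64)
    strength = np.zeros(len(nodes), dtype=float)
    # scatter-add all gene_a endpoints in edge order, then all gene_b endpoints;
    # summation order is part of the determinism contract
    np.add.at(degree, ia, 1)
    np.add.at(degree, ib, 1)
    np.add.at(strength, ia, w)
    np.add.at(strength, ib, w)

    centrality = np.zeros(len(nodes), dtype=float)
    pos = degree > 0
    if alpha == 0.0:
        centrality[pos] = degree[pos].astype(float)
    elif alpha == 1.0:
        centrality[pos] = strength[pos]
    else:
        centrality[pos] = degree[pos].astype(float) ** (1.0 - alpha) * strength[
            pos
        ] ** alpha

    table = pd.DataFrame(
        {"degree": degree, "strength": strength, "centrality": centrality},
        index=pd.Index(nodes, name="gene"),
    )
    table.attrs["alpha"] = alpha
    return table


def top_central_nodes(
    centrality: pd.DataFrame,
    k: int = 750,
    restrict_to: set[str] | None = None,
) -> list[str]:
    """The k nodes with the largest centrality, deterministically ordered.

    Ordering is centrality descending with gene identifier ascending as
    tie-break.  ``restrict_to`` limits the candidate universe (e.g. to
    lncRNAs when modules should be centered on non-coding sponges); ties at
    the k-th rank are cut, not included.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    table = centrality
    if restrict_to is not None:
        table = table[table.index.isin(set(restrict_to))]
        if table.empty:
            raise ValueError(
                "restrict_to shares no genes with the centrality table"
            )
    # stable sort on descending centrality after a pre-sort by gene id
    # realizes the (centrality desc, identifier asc) tie-break
    order = table.sort_index().sort_values(
        "centrality", ascending=False, kind="mergesort"
    )
    if len(order) < k:
        logger.warning(
            "requested %d central nodes but only %d candidates exist", k, len(order)
        )
    return list(order.index[:k])


def read_edge_table(path, weight_col: str | None = None) -> CeRNANetwork:
    """Read a TSV edge list (columns geneA, geneB, an effect-size column,
    optional p_adj and semicolon-separated mirnas; '#' comment lines)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"mirnas": str})
    return from_edge_table(df, weight_col=weight_col)


def write_edge_table(network: CeRNANetwork, path) -> None:
    """Write the canonical edge table as TSV (weight column named 'weight')."""
    out = network.edges.rename(columns={"gene_a": "geneA", "gene_b": "geneB"}).copy()
    if "mirnas" in out.columns:
        out["mirnas"] = [";".join(m) for m in out["mirnas"]]
    out.to_csv(path, sep="\t", index=False)
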