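"""ceRNA module construction, size filtering, randomization, miRNA ranking.

A module is the gene set formed by one high-centrality ceRNA (the center)
together with its first-degree neighbors in the filtered network.  Modules
are treated downstream as gene sets for single-sample enrichment; the
size-matched random modules built here provide the null model against which
real modules are validated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import CeRNANetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Module:
    """A gene set keyed by its central ceRNA.

    ``provenance`` is ``"real"`` for center+neighbors modules and
    ``"random"`` for size-matched null modules (whose members need not touch
    the center at all).
    """

    center: str
    members: frozenset[str]
    provenance: str = "real"

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ModuleSet:
    """Insertion-ordered mapping center -> :class:`Module`.

    ``gene_universe`` records, when known, the gene pool modules were drawn
    from or validated against (used as default for randomization).
    """

    modules: dict[str, Module] = field(default_factory=dict)
    gene_universe: frozenset[str] | None = None

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules.values())

    def __getitem__(self, center: str) -> Module:
        return self.modules[center]

    def __contains__(self, center: str) -> bool:
        return center in self.modules

    def keys(self):
        return self.modules.keys()

    def sizes(self) -> list[int]:
        return [m.size for m in self]


def build_modules(
    filtered: CeRNANetwork,
    centers: list[str],
    include_center: bool = True,
) -> ModuleSet:
    """One module per center: the center plus its first-degree neighbors.

    Neighborhoods are taken in the *filtered* network, so module membership
    reflects only significant, non-negligible ceRNA cross-talk.  Second-degree
    genes are never pulled in.  Centers absent from the network are an error
    (they cannot have a neighborhood).
    """
    adjacency = filtered.adjacency()
    modules: dict[str, Module] = {}
    for center in centers:
        if center in modules:
            raise ValueError(f"duplicate center {center!r}")
        if center not in adjacency:
            raise ValueError(f"center {center!r} is not a node of the filtered network")
        members = set(adjacency[center])
        if include_center:
            members.add(center)
        modules[center] = Module(center=center, members=frozenset(members))
    return ModuleSet(modules=modules, gene_universe=frozenset(adjacency))


def filter_modules(
    modules: ModuleSet,
    expressed_genes: set[str],
    min_size: int = 10,
    max_size: int = 200,
) -> ModuleSet:
    """Intersect each module with the measured genes and filter by size.

    Members missing from the expression matrix are removed first; a module
    survives iff its remaining size lies in ``[min_size, max_size]``
    (defaults 10-200, the conventional gene-set size window for single-sample
    enrichment).  The center itself may be unmeasured — common when modules
    are transferred to a cohort profiled on a different platform — and the
    module still survives if enough neighbors remain.
    """
    if not expressed_genes:
        raise ValueError("expressed_genes is empty")
    if min_size < 1 or max_size < min_size:
        raise ValueError("need 1 <= min_size <= max_size")
    expressed = set(expressed_genes)
    kept: dict[str, Module] = {}
    for mod in modules:
        members = frozenset(mod.members & expressed)
        if min_size <= len(members) <= max_size:
            kept[mod.center] = Module(mod.center, members, mod.provenance)
    logger.info(
        "filter_modules: kept %d / %d modules (size in [%d, %d])",
        len(kept), len(modules), min_size, max_size,
    )
    return ModuleSet(modules=kept, gene_universe=modules.gene_universe)


def sample_random_modules(
    modules: ModuleSet,
    gene_universe: set[str] | None = None,
    seed: int = 0,
) -> ModuleSet:
    """Size-matched random modules: the null model for module validation.

    For each real module one random module of identical size is drawn
    uniformly without replacement from ``gene_universe`` (with replacement
    across modules), preserving the size distribution of the real module set.
    Keys are kept so random scores align feature-wise with real scores.
    """
    universe = gene_universe if gene_universe is not None else modules.gene_universe
    if universe is None:
        raise ValueError("no gene_universe given and the module set records none")
    pool = sorted(universe)
    rng = np.random.default_rng(seed)
    out: dict[str, Module] = {}
    for mod in modules:
        if mod.size > len(pool):
            raise ValueError(
                f"module {mod.center!r} (size {mod.size}) exceeds universe size {len(pool)}"
            )
        picks = rng.choice(len(pool), size=mod.size, replace=False)
        out[mod.center] = Module(
            center=mod.center,
            members=frozenset(pool[i] for i in picks),
            provenance="random",
        )
    return ModuleSet(modules=out, gene_universe=frozenset(universe))


def rank_module_mirnas(
    modules: ModuleSet,
    network: CeRNANetwork,
    scope: str = "internal",
) -> pd.DataFrame:
    """Count, per module, how often each miRNA annotates the module's edges.

    With ``scope="internal"`` (default) only edges with *both* endpoints
    inside the module contribute; ``scope="incident"`` also counts edges with
    exactly one endpoint inside.  Rows are ordered per module by count
    descending, miRNA identifier ascending.  The counts proxy how strongly a
    miRNA is predicted to be sponged within the module.
    """
    if scope not in ("internal", "incident"):
        raise ValueError("scope must be 'internal' or 'incident'")
    if not network.has_mirnas:
        raise ValueError(
            "the network carries no miRNA annotations; miRNA ranking requires "
            "an edge table with a 'mirnas' column"
        )
    edges = network.edges
    records: list[tuple[str, str, int]] = []
    for mod in modules:
        counts: dict[str, int] = {}
        for a, b, mirnas in zip(edges["gene_a"], edges["gene_b"], edges["mirnas"]):
            if scope == "internal":
                hit = a in mod.members and b in mod.members
            else:
                hit = a in mod.members or b in mod.members
            if hit:
                for m in mirnas:
                    counts[m] = counts.get(m, 0) + 1
        for mirna, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            records.append((mod.center, mirna, count))
    return pd.DataFrame(records, columns=["module", "mirna", "count"])


def global_mirna_ranking(counts: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-module miRNA counts into a global ranking by total count
    (descending, identifier ascending)."""
    if counts.empty:
        return pd.DataFrame(columns=["mirna", "total"])
    total = counts.groupby("mirna")["count"].sum().reset_index(name="total")
    return total.sort_values(
        ["total", "mirna"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def verify_modules(modules: ModuleSet, filtered: CeRNANetwork) -> None:
    """Audit that every real module is exactly {center} ∪ neighbors(center).

    Raises AssertionError on the first violation.  Cheap; run after building
    modules to guarantee membership provenance.
    """
    adjacency = filtered.adjacency()
    for mod in modules:
        if mod.provenance != "real":
            continue
        neighbors = adjacency.get(mod.center, set())
        extra = (mod.members - {mod.center}) - neighbors
        if extra:
            raise AssertionError(
                f"module {mod.center!r} contains non-neighbor genes {sorted(extra)}"
            )


def write_gmt(modules: ModuleSet, path) -> None:
    """Write modules in GMT format: name = center, description = provenance,
    then member genes (sorted), tab-separated."""
    with open(path, "w", encoding="utf-8") as fh:
        for mod in modules:
            fields = [mod.center, mod.provenance, *sorted(mod.members)]
            fh.write("\t".join(fields) + "\n")


def read_gmt(path) -> ModuleSet:
    """Read a GMT file written by :func:`write_gmt` (or any standard GMT;
    unknown descriptions default to provenance 'real')."""
    modules: dict[str, Module] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            center, desc, members = fields[0], fields[1], fields[2:]
            provenance = desc if desc in ("real", "random") else "real"
            modules[center] = Module(center, frozenset(members), provenance)
    return ModuleSet(modules=modules)
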