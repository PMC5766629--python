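"""Gene-set over-representation analysis and pathway-impact scoring.

Over-representation uses the one-sided hypergeometric tail P[X >= k]
against an annotation-restricted universe, with Benjamini-Hochberg FDR
across all tested sets and a configurable nominal-p reporting cutoff
(0.001 by default, mirroring the headline pathway analysis this package
reproduces).  Pathway impact scores a metabolite hit set on a pathway
graph by the fraction of component-normalized betweenness centrality it
covers, as topology-aware metabolic pathway analysis (MetPA) does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network import Network, node_topology

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "hypergeom_enrich",
    "bh_fdr",
    "pathway_impact",
]


class GMTParseError(ValueError):
    """Raised for malformed GMT lines."""


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        restricted = {}
        for name, genes in self.sets.items():
            genes = frozenset(genes) & self.universe
            if not genes:
                logger.warning("dropping empty gene set %r", name)
                continue
            restricted[name] = genes
        self.sets = restricted
        self.universe = frozenset(self.universe)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(
    source: str | Path | IO[str],
    universe: Iterable[str] | None = None,
) -> GeneSetCollection:
    """Read a GMT file (``name TAB description TAB gene...`` per line).

    Unless an explicit ``universe`` is supplied, the universe is the
    union of all member genes — the annotation-restricted convention of
    over-representation tools.
    """
    close = False
    if isinstance(source, (str, Path)):
        fh: IO[str] = open(source)
        close = True
    else:
        fh = source
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"line {lineno}: GMT lines need name, description and "
                    f">=1 gene (got {len(fields)} fields)"
                )
            name, desc, *genes = fields
            sets[name] = frozenset(g.strip() for g in genes if g.strip())
            descriptions[name] = desc
    finally:
        if close:
            fh.close()
    uni = frozenset(universe) if universe is not None else frozenset().union(*sets.values())
    return GeneSetCollection(sets=sets, universe=uni, descriptions=descriptions)


def write_gmt(coll: GeneSetCollection, dest: str | Path | IO[str]) -> None:
    lines = []
    for name in sorted(coll.sets):
        desc = coll.descriptions.get(name, "na")
        genes = "\t".join(sorted(coll.sets[name]))
        lines.append(f"{name}\t{desc}\t{genes}\n")
    text = "".join(lines)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


@dataclass(frozen=True)
class EnrichmentResult:
    """One over-represented pathway row (p, FDR, overlapping genes)."""

    pathway: str
    p: float
    fdr: float
    hits: tuple[str, ...]
    k: int


def bh_fdr(pvalues: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (step-up, capped at 1)."""
    p = list(pvalues)
    if not p:
        return []
    if any((x <= 0 or x > 1) for x in p):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def hypergeom_enrich(
    query: Iterable[str],
    coll: GeneSetCollection,
    p_cutoff: float = 0.001,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation of ``query`` in every
    set of ``coll``.

    Query genes outside the universe are dropped (with a logged count).
    For each set of size K in a universe of size M, with restricted query
    of size n and overlap k, p = P[X >= k] with X ~ Hypergeometric(M, K, n).
    BH-FDR is computed across *all* tested sets; only results with
    p <= ``p_cutoff`` are returned, sorted by ascending p (ties by name).
    """
    q = frozenset(query)
    dropped = len(q - coll.universe)
    if dropped:
        logger.info("dropped %d query gene(s) outside the universe", dropped)
    q &= coll.universe
    if not q:
        raise ValueError("query is empty after restriction to the universe")
    names = sorted(coll.sets)
    M, n = len(coll.universe), len(q)
    pvals, hits = [], []
    for name in names:
        s = coll.sets[name]
        overlap = tuple(sorted(q & s))
        k = len(overlap)
        pvals.append(float(hypergeom.sf(k - 1, M, len(s), n)))
        hits.append(overlap)
    fdrs = bh_fdr([min(p, 1.0) for p in pvals])
    results = [
        EnrichmentResult(pathway=name, p=min(p, 1.0), fdr=f, hits=h, k=len(h))
        for name, p, f, h in zip(names, pvals, fdrs, hits)
        if p <= p_cutoff
    ]
    return sorted(results, key=lambda r: (r.p, r.pathway))


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (pathway, p, FDR, hit count, genes)."""
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "p": r.p,
                "fdr": r.fdr,
                "hit": r.k,
                "genes": ", ".join(r.hits),
            }
            for r in results
        ]
    )


def pathway_impact(pathway_graph: Network, matched: Iterable[str]) -> float:
    """Topology-weighted impact of matched metabolites on a pathway graph.

    Impact is the sum of component-normalized betweenness centrality over
    matched nodes divided by the sum over all nodes, in [0, 1].  When no
    node of the graph has positive betweenness (e.g. a single edge), the
    matched fraction of nodes is returned instead so that a fully matched
    pathway still scores 1.
    """
    matched = set(matched)
    missing = matched - pathway_graph.nodes
    if missing:
        raise ValueError(f"matched node(s) absent from pathway graph: {sorted(missing)}")
    if not matched:
        return 0.0
    topo = node_topology(pathway_graph)
    total = topo["betweenness"].sum()
    if total == 0:
        return len(matched) / pathway_graph.n_nodes
    return float(topo.loc[sorted(matched), "betweenness"].sum() / total)
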