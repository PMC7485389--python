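"""Pathway over-representation analysis of shared-gene lists.

Each comorbidity pair's shared-gene list is tested against every pathway
in a GMT collection with the same upper-tail hypergeometric + BH-FDR
machinery used for network edges: overlap k of a size-n list with a
size-K pathway inside a size-U universe, significant at q < alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .conet import bh_fdr, hypergeom_upper_tail

logger = logging.getLogger(__name__)

ENRICH_COLUMNS = ["pathway", "k", "n", "K", "U", "p", "q", "significant"]


@dataclass
class PathwayCollection:
    """Named gene sets plus the reference universe (union by default)."""

    pathways: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            u: set[str] = set()
            for genes in self.pathways.values():
                u |= genes
            self.universe = frozenset(u)
        for name, genes in self.pathways.items():
            if not genes <= self.universe:
                raise ValueError(f"pathway {name!r} not contained in universe")


def load_gmt(path, universe=None) -> PathwayCollection:
    """Parse a GMT file (name TAB description TAB gene...).

    Lines with fewer than three fields, or duplicate pathway names, are
    fatal. The universe defaults to the union of all pathway genes.
    """
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0].strip()
            if name in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            pathways[name] = genes
    return PathwayCollection(pathways, frozenset(universe) if universe else frozenset())


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    k: int
    n: int
    K: int
    U: int
    p: float
    q: float
    significant: bool


def enrich(genes, coll: PathwayCollection, alpha: float = 0.05) -> list[EnrichmentResult]:
    """Hypergeometric ORA of a gene list against every pathway, BH across
    the collection, sorted by q ascending (ties by p, then name).

    Genes outside the universe are dropped from the list before testing
    (logged); an empty effective list raises ``ValueError``.
    """
    gene_set = {str(g).strip().upper() for g in genes}
    effective = gene_set & set(coll.universe)
    dropped = len(gene_set) - len(effective)
    if dropped:
        logger.info("enrich: %d gene(s) outside the universe dropped", dropped)
    if not effective:
        raise ValueError("no testable genes: list does not intersect the universe")
    U, n = len(coll.universe), len(effective)
    names = sorted(coll.pathways)
    raw = []
    for name in names:
        K = len(coll.pathways[name])
        k = len(effective & coll.pathways[name])
        raw.append((name, k, K, hypergeom_upper_tail(U, K, n, k)))
    qvals = bh_fdr([p for _, _, _, p in raw])
    results = [
        EnrichmentResult(name, k, n, K, U, p, float(q), bool(q < alpha))
        for (name, k, K, p), q in zip(raw, qvals)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.pathway))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.pathway, r.k, r.n, r.K, r.U, r.p, r.q, r.significant) for r in results],
        columns=ENRICH_COLUMNS,
    )
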