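"""Disease-gene annotation joins and gene-set Jaccard overlap.

Comorbid disease pairs inside a network module are scored by the Jaccard
index of their associated gene sets, JI = |A ∩ B| / |A ∪ B|: 1 for
identical sets, 0 for disjoint ones. The annotation table emulates a
curated ClinVar-derived mapping of ICD-10 codes to gene symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .records_io import validate_icd10

logger = logging.getLogger(__name__)

OVERLAP_COLUMNS = ["code_a", "code_b", "n_shared", "n_union", "jaccard", "shared_genes"]


def load_annotations(path, sep: str = "\t") -> dict[str, frozenset[str]]:
    """Read a TSV with columns (icd10, gene) into code -> gene-set.

    Gene symbols are uppercased; rows with syntactically invalid codes are
    dropped with a logged tally; duplicate rows collapse.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in ("icd10", "gene") if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    out: dict[str, set[str]] = {}
    dropped = 0
    for raw_code, gene in zip(df["icd10"], df["gene"]):
        chk = validate_icd10(raw_code)
        gene = gene.strip().upper()
        if not chk.accepted or not gene:
            dropped += 1
            continue
        out.setdefault(chk.code, set()).add(gene)
    if dropped:
        logger.info("load_annotations: dropped %d invalid rows", dropped)
    return {c: frozenset(g) for c, g in out.items()}


def jaccard(a, b) -> float:
    """|A ∩ B| / |A ∪ B|; defined as 0 (with a warning) when both are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        logger.warning("jaccard of two empty sets: defined as 0")
        return 0.0
    return len(a & b) / len(union)


@dataclass(frozen=True)
class GeneOverlap:
    code_a: str
    code_b: str
    shared: frozenset[str]
    n_shared: int
    n_union: int
    jaccard: float


def gene_overlap(code_a: str, code_b: str, ann: dict[str, frozenset[str]]) -> GeneOverlap:
    a, b = set(ann.get(code_a, ())), set(ann.get(code_b, ()))
    shared, union = a & b, a | b
    return GeneOverlap(
        code_a, code_b, frozenset(shared), len(shared), len(union), jaccard(a, b)
    )


def module_gene_coverage(partition, hub: str, net, ann) -> tuple[int, int, int]:
    """(n_partners, n_annotated, percent) for a hub's comorbidity partners.

    Partners are the hub's network neighbors restricted to the hub's own
    module when a partition is given; "annotated" means a non-empty gene
    set. The fraction is reported as a whole percent.
    """
    g = net if isinstance(net, nx.Graph) else net.graph
    if hub not in g:
        raise ValueError(f"unknown hub code {hub!r}")
    partners = set(g.neighbors(hub))
    if partition is not None:
        m = partition.assignment[hub]
        partners &= partition.modules[m].members
    annotated = sum(1 for c in partners if ann.get(c))
    pct = round(100.0 * annotated / len(partners)) if partners else 0
    return len(partners), annotated, pct


def rank_pairs_by_jaccard(
    module_edges, ann: dict[str, frozenset[str]], top_n: int | None = None
) -> list[GeneOverlap]:
    """Rank comorbidity edges by gene-set Jaccard index.

    Only pairs with both endpoints annotated are scored. Descending
    jaccard; ties broken by n_shared (descending) then the code pair.
    """
    overlaps = [
        gene_overlap(a, b, ann)
        for a, b in module_edges
        if ann.get(a) and ann.get(b)
    ]
    overlaps.sort(key=lambda o: (-o.jaccard, -o.n_shared, (o.code_a, o.code_b)))
    return overlaps[:top_n] if top_n is not None else overlaps


def overlap_table(overlaps: list[GeneOverlap]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (o.code_a, o.code_b, o.n_shared, o.n_union, o.jaccard,
             ";".join(sorted(o.shared)))
            for o in overlaps
        ],
        columns=OVERLAP_COLUMNS,
    )
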