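"""Boolean query construction pairing each gene with each concept's keywords.

Keywords of one concept are joined with OR, then the group is ANDed with
the gene symbol, e.g. ``CHRNA5 AND (nicotine OR cocaine)``. Multi-word
keywords are double-quoted. Searches against a remote PubMed-like index go
through the :class:`SearchAdapter` contract so the pipeline is testable
offline; a pure-local mode simply scans all provided abstracts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol

from .ontology import Concept, KeywordOntology

logger = logging.getLogger(__name__)

MAX_GENES = 200

__all__ = ["BooleanQuery", "SearchAdapter", "InMemorySearchAdapter", "build_query", "build_all_queries", "MAX_GENES"]


@dataclass(frozen=True)
class BooleanQuery:
    gene: str
    concept_name: str
    query_text: str


def _quote(keyword: str) -> str:
    return f'"{keyword}"' if " " in keyword else keyword


def build_query(gene: str, concept: Concept) -> BooleanQuery:
    """``gene AND (kw1 OR kw2 OR ...)`` with multi-word keywords quoted."""
    if not gene or not gene.strip():
        raise ValueError("gene symbol must be non-empty")
    if not concept.keywords:
        raise ValueError(f"concept {concept.name!r} has no keywords")
    group = " OR ".join(_quote(k) for k in concept.keywords)
    return BooleanQuery(
        gene=gene, concept_name=concept.name, query_text=f"{gene} AND ({group})"
    )


def build_all_queries(genes: list[str], ont: KeywordOntology) -> list[BooleanQuery]:
    """One query per (unique gene, non-GWAS concept) pair.

    At most 200 genes are accepted per search; duplicates are collapsed
    with a warning. GWAS-branch concepts are excluded — they are matched
    against the catalog, not PubMed.
    """
    if not genes:
        raise ValueError("gene list is empty")
    if len(genes) > MAX_GENES:
        raise ValueError(f"at most {MAX_GENES} gene symbols per search, got {len(genes)}")
    unique: list[str] = []
    seen = set()
    for g in genes:
        if g in seen:
            logger.warning("duplicate gene symbol %r dropped", g)
            continue
        seen.add(g)
        unique.append(g)
    return [
        build_query(g, con)
        for g in unique
        for _cat, con in ont.non_gwas_concepts()
    ]


class SearchAdapter(Protocol):
    """Contract for a remote search backend: a query in, PMIDs out.

    Rate limiting and API keys are adapter concerns; the mining semantics
    never depend on the adapter, which only narrows the candidate set.
    """

    def search(self, query_text: str) -> list[str]: ...


class InMemorySearchAdapter:
    """Fake adapter for tests: returns a fixed PMID list for every query."""

    def __init__(self, pmids: list[str]):
        self._pmids = list(pmids)
        self.queries_seen: list[str] = []

    def search(self, query_text: str) -> list[str]:
        self.queries_seen.append(query_text)
        return list(self._pmids)
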