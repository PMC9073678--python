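"""End-to-end mining workflow: genes + ontology + corpus -> graph and table.

Candidate abstracts come either from scanning every provided record
(pure-local mode) or from a remote :class:`~litgene.queries.SearchAdapter`
that narrows the candidate PMID set per gene. The adapter never changes
matching semantics — mining a fixture corpus locally equals mining with a
fake adapter that returns every fixture PMID.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .corpus import AbstractRecord, GwasAssociation
from .graph import GraphDocument, build_graph, to_table
from .gwas import match_gwas
from .mining import SentenceMatch, find_matches, tally_abstracts
from .ontology import KeywordOntology, select_categories
from .queries import SearchAdapter, build_all_queries

logger = logging.getLogger(__name__)

__all__ = ["MiningResult", "run_mine"]


@dataclass
class MiningResult:
    matches: list[SentenceMatch] = field(default_factory=list)
    tallies: dict[tuple[str, str], int] = field(default_factory=dict)
    gwas_hits: dict[str, list[GwasAssociation]] = field(default_factory=dict)
    graph: GraphDocument = field(default_factory=GraphDocument)
    table: list[tuple[str, str, str, int]] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)


def run_mine(
    genes: list[str],
    ontology: KeywordOntology,
    records: list[AbstractRecord],
    catalog: list[GwasAssociation] | None = None,
    categories: list[str] | None = None,
    adapter: SearchAdapter | None = None,
    synonyms: dict[str, list[str]] | None = None,
    require_trait_keyword: bool = True,
) -> MiningResult:
    """Run the full co-occurrence search for a gene list.

    ``categories`` optionally restricts the ontology to a selection of
    its categories (including or excluding the reserved GWAS branch).
    GWAS matching runs only when a catalog is supplied and the selected
    ontology has a GWAS branch.
    """
    if categories:
        ontology = select_categories(ontology, categories)
    queries = build_all_queries(genes, ontology)  # validates size, dedups
    unique_genes = list(dict.fromkeys(genes))
    by_pmid = {r.pmid: r for r in records}

    all_matches: list[SentenceMatch] = []
    for gene in unique_genes:
        if adapter is not None:
            candidate_pmids: set[str] = set()
            for q in (q for q in queries if q.gene == gene):
                candidate_pmids.update(adapter.search(q.query_text))
            candidates = [by_pmid[p] for p in sorted(candidate_pmids) if p in by_pmid]
        else:
            candidates = records
        for rec in candidates:
            all_matches.extend(
                find_matches(rec, gene, ontology, synonyms=(synonyms or {}).get(gene))
            )
        logger.info("gene %s: %d matching sentences", gene,
                    sum(m.gene == gene for m in all_matches))

    tallies = tally_abstracts(all_matches)
    gwas_hits: dict[str, list[GwasAssociation]] = {}
    gwas_keywords = ontology.gwas_keywords()
    if catalog is not None and gwas_keywords:
        for gene in unique_genes:
            hits = match_gwas(gene, gwas_keywords, catalog,
                              require_trait_keyword=require_trait_keyword)
            if hits:
                gwas_hits[gene] = hits
    graph = build_graph(tallies, gwas_hits, unique_genes, matches=all_matches)
    table = to_table(tallies, gwas_hits, ontology)
    return MiningResult(
        matches=all_matches, tallies=tallies, gwas_hits=gwas_hits,
        graph=graph, table=table, genes=unique_genes,
    )
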