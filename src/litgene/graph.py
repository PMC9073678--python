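"""Weighted bipartite result graph and tabular report.

Genes, concepts and GWAS hits become nodes; an edge connects a gene to a
concept (weight = number of distinct abstracts with a co-occurring
sentence) or to the gene's aggregate GWAS node (weight = number of
catalog associations). Every queried gene appears as a node even when it
has no hits. The graph serializes as Cytoscape-style elements JSON;
category names are carried as grouping labels, rendering (colors, layout)
is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .corpus import GwasAssociation
from .mining import SentenceMatch, collect_evidence
from .ontology import GWAS_CATEGORY, KeywordOntology

__all__ = ["GraphNode", "GraphEdge", "GraphDocument", "build_graph", "to_table", "table_to_tsv"]

NODE_KINDS = ("gene", "concept", "gwas_trait")


@dataclass(frozen=True)
class GraphNode:
    id: str
    label: str
    node_kind: str
    category_name: str = ""

    def __post_init__(self) -> None:
        if self.node_kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.node_kind!r}")


@dataclass(frozen=True)
class GraphEdge:
    source: str
    target: str
    weight: int
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValueError("edge weight must be >= 1")
        if self.evidence and len(set(self.evidence)) != self.weight:
            raise ValueError(
                f"edge {self.source}->{self.target}: weight {self.weight} "
                f"!= {len(set(self.evidence))} distinct evidence refs"
            )


@dataclass
class GraphDocument:
    nodes: list[GraphNode] = field(default_factory=list)
    edges: list[GraphEdge] = field(default_factory=list)

    def to_cytoscape_json(self, indent: int | None = 2) -> str:
        elements = {
            "nodes": [
                {
                    "data": {
                        "id": n.id,
                        "label": n.label,
                        "node_kind": n.node_kind,
                        "category": n.category_name,
                    }
                }
                for n in self.nodes
            ],
            "edges": [
                {
                    "data": {
                        "source": e.source,
                        "target": e.target,
                        "weight": e.weight,
                        "evidence": list(e.evidence),
                    }
                }
                for e in self.edges
            ],
        }
        return json.dumps({"elements": elements}, indent=indent)

    @classmethod
    def from_cytoscape_json(cls, text: str) -> "GraphDocument":
        doc = json.loads(text)
        nodes = [
            GraphNode(
                id=d["data"]["id"],
                label=d["data"]["label"],
                node_kind=d["data"]["node_kind"],
                category_name=d["data"].get("category", ""),
            )
            for d in doc["elements"]["nodes"]
        ]
        edges = [
            GraphEdge(
                source=d["data"]["source"],
                target=d["data"]["target"],
                weight=d["data"]["weight"],
                evidence=tuple(d["data"].get("evidence", ())),
            )
            for d in doc["elements"]["edges"]
        ]
        return cls(nodes=nodes, edges=edges)


def build_graph(
    tallies: dict[tuple[str, str], int],
    gwas_hits: dict[str, list[GwasAssociation]],
    queried_genes: list[str],
    matches: list[SentenceMatch] = (),
) -> GraphDocument:
    """Assemble the bipartite result graph.

    ``tallies`` come from :func:`litgene.mining.tally_abstracts`;
    ``gwas_hits`` maps gene -> matched catalog rows; ``matches`` supplies
    per-edge evidence PMIDs and concept categories (weights are checked
    against the tallies). GWAS associations are aggregated into one gray
    "GWAS" node per gene with hits, with catalog row ids as evidence.
    """
    evidence = collect_evidence(list(matches))
    nodes: list[GraphNode] = [
        GraphNode(id=f"gene:{g}", label=g, node_kind="gene") for g in queried_genes
    ]
    edges: list[GraphEdge] = []
    seen_concepts: set[str] = set()
    for (gene, concept), count in sorted(tallies.items()):
        ev = evidence.get((gene, concept), {"category": "", "pmids": []})
        if ev["pmids"] and len(ev["pmids"]) != count:
            raise ValueError(
                f"tally for ({gene}, {concept}) is {count} but evidence has "
                f"{len(ev['pmids'])} distinct abstracts"
            )
        cid = f"concept:{concept}"
        if concept not in seen_concepts:
            nodes.append(
                GraphNode(
                    id=cid,
                    label=concept,
                    node_kind="concept",
                    category_name=ev["category"],
                )
            )
            seen_concepts.add(concept)
        edges.append(
            GraphEdge(
                source=f"gene:{gene}",
                target=cid,
                weight=count,
                evidence=tuple(ev["pmids"]),
            )
        )
    for gene in queried_genes:
        rows = gwas_hits.get(gene, [])
        if not rows:
            continue
        gid = f"gwas:{gene}"
        nodes.append(
            GraphNode(id=gid, label="GWAS", node_kind="gwas_trait", category_name=GWAS_CATEGORY)
        )
        refs = tuple(dict.fromkeys(f"row:{r.row_id}" for r in rows))
        edges.append(
            GraphEdge(source=f"gene:{gene}", target=gid, weight=len(refs), evidence=refs)
        )
    return GraphDocument(nodes=nodes, edges=edges)


def to_table(
    tallies: dict[tuple[str, str], int],
    gwas_hits: dict[str, list[GwasAssociation]],
    ontology: KeywordOntology | None = None,
) -> list[tuple[str, str, str, int]]:
    """Rows (gene, category, concept, count), sorted by gene, count desc, concept.

    The ordering is deterministic and invariant under input permutation.
    GWAS hits appear as (gene, "GWAS", "GWAS", association count).
    """
    concept_cat: dict[str, str] = {}
    if ontology is not None:
        for cat, con in ontology.non_gwas_concepts():
            concept_cat[con.name] = cat.name
    rows = [
        (gene, concept_cat.get(concept, ""), concept, count)
        for (gene, concept), count in tallies.items()
    ]
    rows.extend(
        (gene, GWAS_CATEGORY, GWAS_CATEGORY, len(hits))
        for gene, hits in gwas_hits.items()
        if hits
    )
    rows.sort(key=lambda r: (r[0], -r[3], r[2]))
    return rows


def table_to_tsv(rows: list[tuple[str, str, str, int]]) -> str:
    """Serialize table rows as TSV with a header."""
    out = ["gene\tcategory\tconcept\tn"]
    out.extend(f"{g}\t{cat}\t{con}\t{n}" for g, cat, con, n in rows)
    return "\n".join(out) + "\n"
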