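"""Match queried genes against GWAS catalog associations.

A catalog row is returned for a gene when the gene equals (case-
insensitively) an entry of the row's reported or mapped gene lists AND one
of the keywords under the ontology's reserved GWAS branch occurs as a
whole word in the row's disease/trait or mapped-trait text. The keyword
requirement can be disabled (``require_trait_keyword=False``) to show all
phenotypic associations of a gene regardless of trait wording.

No p-value thresholding is applied: all matching rows pass, with the
p-value retained for display.
"""

from __future__ import annotations

from .corpus import GwasAssociation
from .mining import contains_word

__all__ = ["match_gwas"]


def match_gwas(
    gene: str,
    gwas_keywords: list[str],
    catalog: list[GwasAssociation],
    require_trait_keyword: bool = True,
) -> list[GwasAssociation]:
    """Catalog rows linking ``gene`` to a trait matching the GWAS keywords.

    Returns a subset of ``catalog`` in input order; idempotent and
    permutation-invariant. With an empty catalog, returns ``[]``.
    """
    if require_trait_keyword and not gwas_keywords:
        raise ValueError("gwas_keywords must be non-empty when the trait-keyword filter is on")
    g = gene.strip().casefold()
    hits = []
    for row in catalog:
        symbols = {s.casefold() for s in row.reported_genes} | {
            s.casefold() for s in row.mapped_genes
        }
        if g not in symbols:
            continue
        if require_trait_keyword:
            trait_text_hit = any(
                contains_word(row.disease_trait, kw) or contains_word(row.mapped_trait, kw)
                for kw in gwas_keywords
            )
            if not trait_text_hit:
                continue
        hits.append(row)
    return hits
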