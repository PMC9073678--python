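"""Readers and writers for abstract records and the GWAS catalog table.

Abstracts come either from PubMed efetch-style article-set XML or from a
JSON-lines fixture format (one ``{"pmid":..., "title":..., "abstract":...}``
object per line) that stands in for a local PubMed store in tests and
offline runs. The GWAS catalog is the NHGRI-EBI "all associations v1.0.2"
tab-separated download.
"""

from __future__ import annotations

import io
import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbstractRecord",
    "GwasAssociation",
    "read_abstracts_xml",
    "read_abstracts_fixture",
    "write_abstracts_fixture",
    "read_gwas_catalog",
]

GWAS_REQUIRED_COLUMNS = (
    "PUBMEDID",
    "DISEASE/TRAIT",
    "MAPPED_TRAIT",
    "REPORTED GENE(S)",
    "MAPPED_GENE",
    "SNPS",
    "P-VALUE",
)


@dataclass(frozen=True)
class AbstractRecord:
    """One PubMed-style record: a PMID, a title, and an (optionally empty) abstract."""

    pmid: str
    title: str
    abstract: str = ""

    def __post_init__(self) -> None:
        if not self.pmid or not self.pmid.isdigit():
            raise ValueError(f"pmid must be a non-empty digit string, got {self.pmid!r}")
        if not self.title:
            raise ValueError(f"record {self.pmid}: title must be non-empty")


@dataclass(frozen=True)
class GwasAssociation:
    """One parsed GWAS catalog row.

    Gene symbols are trimmed; ``p_value`` is kept as the raw catalog text
    (the catalog mixes exponent strings and annotations) with
    :meth:`p_value_float` as an optional numeric view. ``row_id`` is the
    0-based data-row index in the source table, used as an evidence
    reference in result graphs.
    """

    pubmed_id: str
    disease_trait: str
    mapped_trait: str
    reported_genes: tuple[str, ...]
    mapped_genes: tuple[str, ...]
    snps: str
    p_value: str
    row_id: int = field(default=-1, compare=False)

    def p_value_float(self) -> float | None:
        try:
            return float(self.p_value)
        except (TypeError, ValueError):
            return None


def read_abstracts_xml(stream: str | io.TextIOBase) -> list[AbstractRecord]:
    """Parse PubMed efetch article-set XML into records.

    Abstract text is the concatenation of all ``AbstractText`` blocks in
    document order, joined by single spaces (structured abstracts have one
    block per section). Articles without a PMID are skipped with a warning;
    malformed XML raises ``xml.etree.ElementTree.ParseError``.
    """
    text = stream.read() if hasattr(stream, "read") else stream
    root = ET.fromstring(text)
    records: list[AbstractRecord] = []
    articles = root.iter("PubmedArticle")
    for art in articles:
        pmid_el = art.find(".//MedlineCitation/PMID")
        if pmid_el is None:
            pmid_el = art.find(".//PMID")
        pmid = (pmid_el.text or "").strip() if pmid_el is not None else ""
        if not pmid:
            logger.warning("skipping article without PMID")
            continue
        title_el = art.find(".//ArticleTitle")
        title = "".join((title_el.itertext()) if title_el is not None else "").strip()
        parts = [
            " ".join(t.strip() for t in el.itertext() if t.strip())
            for el in art.findall(".//Abstract/AbstractText")
        ]
        abstract = " ".join(p for p in parts if p)
        records.append(AbstractRecord(pmid=pmid, title=title or "(untitled)", abstract=abstract))
    return records


def read_abstracts_fixture(stream: str | io.TextIOBase) -> list[AbstractRecord]:
    """Read the JSON-lines fixture format, preserving line order.

    Each non-blank line must be an object with ``pmid``, ``title`` and
    (optionally) ``abstract`` fields; a missing ``pmid`` raises a
    ``ValueError`` naming the line number.
    """
    text = stream.read() if hasattr(stream, "read") else stream
    records: list[AbstractRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ValueError(f"line {lineno}: not valid JSON: {exc}") from exc
        if "pmid" not in obj:
            raise ValueError(f"line {lineno}: missing 'pmid' field")
        if "title" not in obj:
            raise ValueError(f"line {lineno}: missing 'title' field")
        records.append(
            AbstractRecord(
                pmid=str(obj["pmid"]),
                title=str(obj["title"]),
                abstract=str(obj.get("abstract", "")),
            )
        )
    return records


def write_abstracts_fixture(records: list[AbstractRecord]) -> str:
    """Serialize records to the JSON-lines fixture format (round-trip stable)."""
    return "".join(
        json.dumps(
            {"pmid": r.pmid, "title": r.title, "abstract": r.abstract},
            ensure_ascii=False,
            sort_keys=False,
        )
        + "\n"
        for r in records
    )


def _split_reported(cell: str) -> tuple[str, ...]:
    return tuple(g.strip() for g in cell.split(",") if g.strip())


def _split_mapped(cell: str) -> tuple[str, ...]:
    # " - " separates flanking genes of intergenic hits, ", " separates lists
    parts: list[str] = []
    for chunk in cell.split(" - "):
        for g in chunk.split(","):
            if g.strip():
                parts.append(g.strip())
    return tuple(parts)


def read_gwas_catalog(stream: str | io.TextIOBase) -> list[GwasAssociation]:
    """Read the GWAS catalog associations TSV.

    Requires the catalog's spellings of the extracted columns
    (``REPORTED GENE(S)``, ``MAPPED_GENE``, ...). Rows are never dropped;
    empty gene cells yield empty tuples.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GWAS_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS catalog is missing required columns: {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        out.append(
            GwasAssociation(
                pubmed_id=rec["PUBMEDID"].strip(),
                disease_trait=rec["DISEASE/TRAIT"].strip(),
                mapped_trait=rec["MAPPED_TRAIT"].strip(),
                reported_genes=_split_reported(rec["REPORTED GENE(S)"]),
                mapped_genes=_split_mapped(rec["MAPPED_GENE"]),
                snps=rec["SNPS"].strip(),
                p_value=rec["P-VALUE"].strip(),
                row_id=i,
            )
        )
    return out
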