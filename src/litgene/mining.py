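"""Sentence-level co-occurrence mining.

Abstracts (title included, as the first text block) are split into
sentences with a rule-based splitter pinned to a fixed biomedical
abbreviation list, so segmentation is reproducible across environments.
A sentence is evidence for a (gene, concept) pair when it contains the
gene symbol and at least one of the concept's keywords, both as
case-insensitive whole words — word boundaries are transitions to
non-alphanumeric characters, so "stress-induced" contains the word
"stress" but "CNRs" does not contain the gene symbol "CNR". Evidence is
counted per *abstract*: an abstract with three matching sentences for the
same pair contributes one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .corpus import AbstractRecord
from .ontology import KeywordOntology

__all__ = [
    "SentenceMatch",
    "split_sentences",
    "find_matches",
    "tally_abstracts",
    "highlight",
    "contains_word",
    "find_word_spans",
    "load_synonym_table",
]

# tokens after which a period never ends a sentence (lowercased, no trailing dot)
_ABBREVIATIONS = frozenset(
    {
        "al", "fig", "figs", "ref", "refs", "eq", "eqs", "vol", "pp",
        "dr", "prof", "mr", "mrs", "ms", "jr", "sr", "st",
        "vs", "etc", "cf", "ca", "approx", "resp", "no", "nos",
        "e.g", "i.e", "viz", "sp", "spp", "subsp", "var", "cv",
        "min", "max", "sec", "hr", "mo", "wk",
    }
)

_BOUNDARY = re.compile(r"([.!?]+)(\s+)")


def _is_abbreviation(prefix: str) -> bool:
    """True if the text ending just before a period ends in a known abbreviation
    or a single-letter initial (as in "J. Smith")."""
    m = re.search(r"([A-Za-z][A-Za-z.]*)$", prefix)
    if not m:
        return False
    token = m.group(1).rstrip(".").lower()
    if token in _ABBREVIATIONS:
        return True
    return len(token) == 1 and m.group(1)[0].isupper()


def split_sentences(text: str) -> list[str]:
    """Split text into sentences; empty input yields an empty list.

    A run of ``.!?`` followed by whitespace ends a sentence unless the
    preceding token is a pinned abbreviation or a single-letter initial,
    or the next character is lowercase (mid-sentence period).
    """
    if not text or not text.strip():
        return []
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        end = m.end(1)  # include the punctuation, not the whitespace
        nxt = text[m.end() : m.end() + 1]
        if nxt and not (nxt.isupper() or nxt.isdigit() or nxt in "\"'(["):
            continue
        if "." in m.group(1) and _is_abbreviation(text[start : m.start()]):
            continue
        chunk = text[start:end].strip()
        if chunk:
            sentences.append(chunk)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def _word_pattern(term: str) -> re.Pattern[str]:
    # boundaries are transitions to non-alphanumeric; internal whitespace flexible
    body = re.escape(term.strip()).replace(r"\ ", r"\s+")
    return re.compile(rf"(?<![A-Za-z0-9]){body}(?![A-Za-z0-9])", re.IGNORECASE)


def contains_word(text: str, term: str) -> bool:
    """Case-insensitive whole-word containment."""
    return bool(_word_pattern(term).search(text))


def find_word_spans(text: str, term: str) -> list[tuple[int, int]]:
    """(start, end) spans of all whole-word occurrences of term in text."""
    return [m.span() for m in _word_pattern(term).finditer(text)]


@dataclass(frozen=True)
class SentenceMatch:
    """One sentence containing a queried gene and >=1 keyword of one concept."""

    pmid: str
    sentence: str
    gene: str
    concept_name: str
    category_name: str
    matched_keywords: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.matched_keywords:
            raise ValueError("matched_keywords must be non-empty")


def find_matches(
    rec: AbstractRecord,
    gene: str,
    ont: KeywordOntology,
    synonyms: list[str] | None = None,
) -> list[SentenceMatch]:
    """All (sentence, concept) co-occurrence matches for one abstract.

    The title is searched as the first sentence-bearing text block. Gene
    synonyms are only matched when explicitly supplied (secondary
    searches); the primary search uses the symbol alone. A sentence
    matching several concepts yields one match per concept, each listing
    every keyword of that concept found in the sentence.
    """
    gene_terms = [gene] + list(synonyms or [])
    matches: list[SentenceMatch] = []
    for sentence in split_sentences(rec.title) + split_sentences(rec.abstract):
        if not any(contains_word(sentence, g) for g in gene_terms):
            continue
        for cat, con in ont.non_gwas_concepts():
            found = tuple(kw for kw in con.keywords if contains_word(sentence, kw))
            if found:
                matches.append(
                    SentenceMatch(
                        pmid=rec.pmid,
                        sentence=sentence,
                        gene=gene,
                        concept_name=con.name,
                        category_name=cat.name,
                        matched_keywords=found,
                    )
                )
    return matches


def tally_abstracts(matches: list[SentenceMatch]) -> dict[tuple[str, str], int]:
    """Distinct-abstract counts per (gene, concept_name).

    The count is the number of distinct PMIDs contributing at least one
    matching sentence, not the number of sentences.
    """
    pmids: dict[tuple[str, str], set[str]] = {}
    for m in matches:
        pmids.setdefault((m.gene, m.concept_name), set()).add(m.pmid)
    return {key: len(v) for key, v in pmids.items()}


def collect_evidence(
    matches: list[SentenceMatch],
) -> dict[tuple[str, str], dict]:
    """Per (gene, concept_name): sorted distinct PMIDs and the category name."""
    out: dict[tuple[str, str], dict] = {}
    for m in matches:
        entry = out.setdefault(
            (m.gene, m.concept_name), {"category": m.category_name, "pmids": set()}
        )
        entry["pmids"].add(m.pmid)
    return {
        k: {"category": v["category"], "pmids": sorted(v["pmids"])}
        for k, v in out.items()
    }


def highlight(sentence: str, keywords: list[str], marker: str = "**") -> str:
    """Wrap whole-word keyword occurrences in markup (default ``**...**``).

    Overlapping matches are resolved longest-first (then leftmost), so
    with keywords ["stress", "oxidative stress"] the longer span wins and
    markup never nests. Original casing is preserved.
    """
    spans: list[tuple[int, int]] = []
    for kw in keywords:
        spans.extend(find_word_spans(sentence, kw))
    spans.sort(key=lambda s: (-(s[1] - s[0]), s[0]))
    chosen: list[tuple[int, int]] = []
    for s in spans:
        if all(s[1] <= c[0] or s[0] >= c[1] for c in chosen):
            chosen.append(s)
    out = sentence
    for start, end in sorted(chosen, reverse=True):
        out = out[:start] + marker + out[start:end] + marker + out[end:]
    return out


def load_synonym_table(text: str) -> dict[str, list[str]]:
    """Parse the 2-column synonym TSV: symbol <tab> pipe-separated synonyms."""
    table: dict[str, list[str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"synonym table line {lineno}: expected 2 tab-separated columns")
        symbol, syns = parts
        table[symbol.strip()] = [s.strip() for s in syns.split("|") if s.strip()]
    return table
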