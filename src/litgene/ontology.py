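"""Three-level keyword ontology: category -> concept -> keywords.

The top level names categories a user can include or omit from a search.
The middle level names concepts, which are the display/grouping unit in
results. The third level holds the actual keywords used to build queries
and to match sentences. One category name, ``"GWAS"`` (exact match), is
reserved: its keywords are matched against GWAS catalog trait text instead
of abstract sentences.

The on-disk format is YAML, a list of category mappings so that duplicate
names are detectable (plain YAML mappings silently collapse duplicate
keys)::

    - category: drugs
      concepts:
        - concept: nicotine
          keywords: [nicotine, smoking]
        - concept: opioids
          keywords: [morphine, heroin]
    - category: GWAS
      concepts:
        - concept: smoking
          keywords: [smoking, tobacco]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import yaml

GWAS_CATEGORY = "GWAS"

__all__ = [
    "GWAS_CATEGORY",
    "Concept",
    "Category",
    "KeywordOntology",
    "OntologyError",
    "parse_ontology",
    "serialize_ontology",
    "select_categories",
    "concept_keywords",
]


class OntologyError(ValueError):
    """Raised when an ontology document violates the format or its invariants."""


@dataclass(frozen=True)
class Concept:
    """A level-2 concept with its level-3 keywords.

    The concept name is display-only; it is *not* implicitly a search term.
    """

    name: str
    keywords: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise OntologyError("concept name must be non-empty")
        if not self.keywords:
            raise OntologyError(f"concept {self.name!r} has no keywords")
        cleaned = []
        seen = set()
        for kw in self.keywords:
            if not isinstance(kw, str) or not kw.strip():
                raise OntologyError(f"concept {self.name!r} has an empty keyword")
            k = kw.strip()
            if k.casefold() in seen:
                raise OntologyError(
                    f"concept {self.name!r} has duplicate keyword {k!r}"
                )
            seen.add(k.casefold())
            cleaned.append(k)
        object.__setattr__(self, "keywords", tuple(cleaned))


@dataclass(frozen=True)
class Category:
    name: str
    concepts: tuple[Concept, ...]

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise OntologyError("category name must be non-empty")
        names = [c.name for c in self.concepts]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise OntologyError(
                f"category {self.name!r} has duplicate concepts: {sorted(dupes)}"
            )

    @property
    def is_gwas(self) -> bool:
        return self.name == GWAS_CATEGORY


@dataclass(frozen=True)
class KeywordOntology:
    categories: tuple[Category, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [c.name for c in self.categories]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise OntologyError(f"duplicate category names: {sorted(dupes)}")
        # keywords should live under exactly one (category, concept) path;
        # cross-concept duplicates are suspicious but legal -> warn only
        seen: dict[str, tuple[str, str]] = {}
        for cat in self.categories:
            for con in cat.concepts:
                for kw in con.keywords:
                    key = kw.casefold()
                    if key in seen and seen[key] != (cat.name, con.name):
                        warnings.warn(
                            f"keyword {kw!r} appears under both "
                            f"{seen[key]} and {(cat.name, con.name)}",
                            stacklevel=2,
                        )
                    seen.setdefault(key, (cat.name, con.name))

    @property
    def category_names(self) -> list[str]:
        return [c.name for c in self.categories]

    def category(self, name: str) -> Category:
        for c in self.categories:
            if c.name == name:
                return c
        raise KeyError(name)

    def non_gwas_concepts(self) -> list[tuple[Category, Concept]]:
        """(category, concept) pairs outside the reserved GWAS branch, in author order."""
        return [
            (cat, con)
            for cat in self.categories
            if not cat.is_gwas
            for con in cat.concepts
        ]

    def gwas_keywords(self) -> list[str]:
        """All level-3 keywords under the reserved GWAS branch (empty if absent)."""
        out: list[str] = []
        for cat in self.categories:
            if cat.is_gwas:
                for con in cat.concepts:
                    out.extend(con.keywords)
        return out


def parse_ontology(doc: str) -> KeywordOntology:
    """Parse a YAML ontology document into a validated :class:`KeywordOntology`.

    Author order of categories, concepts and keywords is preserved.
    Raises :class:`OntologyError` naming the offending node on an empty
    document, duplicate category/concept names, or a concept with no
    keywords.
    """
    if not doc or not doc.strip():
        raise OntologyError("empty ontology document")
    try:
        data = yaml.safe_load(doc)
    except yaml.YAMLError as exc:
        raise OntologyError(f"not valid YAML: {exc}") from exc
    if not isinstance(data, list):
        raise OntologyError("top level must be a list of categories")
    categories = []
    for entry in data:
        if not isinstance(entry, dict) or "category" not in entry:
            raise OntologyError(f"malformed category entry: {entry!r}")
        concepts = []
        for cent in entry.get("concepts") or []:
            if not isinstance(cent, dict) or "concept" not in cent:
                raise OntologyError(
                    f"malformed concept entry under {entry['category']!r}: {cent!r}"
                )
            kws = cent.get("keywords")
            if not kws:
                raise OntologyError(
                    f"concept {cent['concept']!r} has no keywords"
                )
            concepts.append(Concept(str(cent["concept"]), tuple(str(k) for k in kws)))
        categories.append(Category(str(entry["category"]), tuple(concepts)))
    return KeywordOntology(tuple(categories))


def serialize_ontology(ont: KeywordOntology) -> str:
    """Serialize to the YAML document format accepted by :func:`parse_ontology`."""
    data = [
        {
            "category": cat.name,
            "concepts": [
                {"concept": con.name, "keywords": list(con.keywords)}
                for con in cat.concepts
            ],
        }
        for cat in ont.categories
    ]
    return yaml.safe_dump(data, sort_keys=False, allow_unicode=True)


def select_categories(ont: KeywordOntology, names: list[str]) -> KeywordOntology:
    """Sub-ontology with exactly the named categories, original order kept."""
    if not names:
        raise OntologyError("empty category selection")
    known = set(ont.category_names)
    unknown = [n for n in names if n not in known]
    if unknown:
        raise OntologyError(f"unknown categories: {unknown}")
    wanted = set(names)
    return KeywordOntology(
        tuple(c for c in ont.categories if c.name in wanted)
    )


def concept_keywords(c: Concept) -> list[str]:
    """The level-3 keywords of a concept, in author order.

    The concept's display name is deliberately not included.
    """
    return list(c.keywords)
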