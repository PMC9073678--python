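"""Weakly labeled training corpora for the stress classifier.

Instead of manual annotation, training sentences are labeled by the two
hand-crafted boolean PubMed queries shipped here as constants: abstracts
matching the systemic query (HPA-axis vocabulary, with cellular terms
excluded by a NOT group) supply *systemic* sentences, abstracts matching
the oxidative/ROS query supply *cellular* sentences; from each abstract
set, only the sentences containing the word "stress" are kept.

For offline testing the module also generates synthetic labeled corpora:
balanced sets of "stress" sentences mixing shared filler vocabulary with
class-specific marker words (restraint/cortisol-like vs oxidative/ROS-
like), with a tunable fraction of markers shared between the classes to
dial separability down from perfect.
"""

from __future__ import annotations

import logging

import numpy as np

from .corpus import AbstractRecord
from .mining import contains_word, split_sentences

logger = logging.getLogger(__name__)

__all__ = [
    "systemic_query",
    "cellular_query",
    "extract_stress_sentences",
    "generate_synthetic_corpus",
    "deduplicate_cross_class",
    "write_corpus_file",
    "read_corpus_file",
]

_SYSTEMIC_QUERY = (
    "(CRF OR AVP OR urocortin OR vasopressin OR CRH OR restraint OR stressor "
    "OR tail-shock OR (social AND defeat) OR (foot AND shock) OR immobilization "
    "OR (predator AND odor) OR intruder OR unescapable OR inescapable OR CORT "
    "OR corticosterone OR cortisol or ACTH OR prolactin OR PRL OR "
    "adrenocorticotropin OR adrenocorticotrophin) AND stress NOT (ROS OR "
    "oxidative OR redox-regulation OR nitrosative OR nitrative OR hyperglycemia "
    "OR carbonyl OR lipoxidative OR Nrf2-driven OR thiol-oxidative)"
)

_CELLULAR_QUERY = (
    "(ROS OR oxidative OR redox-regulation OR nitrosative OR nitrative OR "
    "hyperglycemia OR carbonyl OR lipoxidative OR Nrf2-driven OR "
    "thiol-oxidative) AND stress"
)


def systemic_query() -> str:
    """The systemic-stress weak-labeling query, verbatim (a fixed constant).

    The lowercase "or" before ACTH is preserved as published.
    """
    return _SYSTEMIC_QUERY


def cellular_query() -> str:
    """The cellular-stress weak-labeling query, verbatim (a fixed constant)."""
    return _CELLULAR_QUERY


def extract_stress_sentences(records: list[AbstractRecord]) -> list[str]:
    """All sentences (title included) containing the whole word "stress".

    The boundary rule counts hyphen-adjacent forms ("stress-induced") but
    not inflections ("stressed").
    """
    out: list[str] = []
    for rec in records:
        for sentence in split_sentences(rec.title) + split_sentences(rec.abstract):
            if contains_word(sentence, "stress"):
                out.append(sentence)
    return out


# marker vocabularies: organism-level stress response vs cell-level
# perturbation response; disjoint from each other and from the fillers
_SYSTEMIC_MARKERS = (
    "restraint", "corticosterone", "cortisol", "crh", "acth", "hypothalamic",
    "immobilization", "defeat", "predator", "intruder", "vasopressin",
    "urocortin", "prolactin", "adrenal", "footshock", "tailshock",
)
_CELLULAR_MARKERS = (
    "oxidative", "ros", "redox", "nitrosative", "peroxide", "glutathione",
    "nrf2", "superoxide", "hyperglycemia", "carbonyl", "antioxidant",
    "mitochondrial", "radical", "thiol", "catalase", "peroxidation",
)
_SHARED_MARKERS = (
    "exposure", "chronic", "acute", "response", "induced", "pathway",
    "signaling", "elevated", "decreased", "activation", "regulation",
    "markers", "conditions", "prolonged", "repeated", "severe",
)
_FILLERS = (
    "the role of in was examined and results showed that levels increased "
    "significantly after treatment while control animals displayed no change "
    "these data suggest a mechanism linking with altered function in brain "
    "tissue samples collected during experiments measuring behavioral "
    "outcomes across groups of adult male female rats mice subjects under "
    "different protocols including daily sessions over several weeks "
    "furthermore expression of related genes remained stable indicating "
    "specific rather than general effects on physiology observed here"
).split()


def generate_synthetic_corpus(
    n_per_class: int,
    seed: int = 0,
    n_markers: int = 10,
    marker_overlap: float = 0.0,
) -> list[tuple[str, str]]:
    """Balanced synthetic corpus of labeled "stress" sentences.

    Every sentence contains the word "stress", one to three marker words
    from its class's marker pool, and shared filler vocabulary; lengths
    are uniform on 8-30 tokens so both the padding and the truncation
    paths of the encoder are exercised. ``marker_overlap`` is the
    fraction of each class's ``n_markers``-word pool replaced by markers
    common to both classes: at 0 the classes are fully separable by
    vocabulary, near 1 they are nearly indistinguishable. Deterministic
    for fixed (seed, parameters).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not 0 <= marker_overlap < 1:
        raise ValueError("marker_overlap must be in [0, 1)")
    if not 1 <= n_markers <= min(len(_SYSTEMIC_MARKERS), len(_CELLULAR_MARKERS)):
        raise ValueError(f"n_markers must be in [1, {len(_SYSTEMIC_MARKERS)}]")
    n_shared = int(round(marker_overlap * n_markers))
    n_shared = min(n_shared, len(_SHARED_MARKERS))
    n_own = n_markers - n_shared
    pools = {
        "systemic": _SYSTEMIC_MARKERS[:n_own] + _SHARED_MARKERS[:n_shared],
        "cellular": _CELLULAR_MARKERS[:n_own] + _SHARED_MARKERS[:n_shared],
    }
    rng = np.random.default_rng(seed)
    corpus: list[tuple[str, str]] = []
    for label in ("systemic", "cellular"):
        pool = pools[label]
        for _ in range(n_per_class):
            length = int(rng.integers(8, 31))
            n_mark = int(rng.integers(1, 4))
            n_fill = max(length - 1 - n_mark, 0)
            words = ["stress"]
            words += [pool[i] for i in rng.integers(0, len(pool), size=n_mark)]
            words += [_FILLERS[i] for i in rng.integers(0, len(_FILLERS), size=n_fill)]
            order = rng.permutation(len(words))
            tokens = [words[i] for i in order]
            sentence = " ".join(tokens)
            corpus.append((sentence[0].upper() + sentence[1:] + ".", label))
    return corpus


def deduplicate_cross_class(corpus: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Drop sentences that appear verbatim in both classes (both copies).

    Weak labeling can assign the same sentence to both queries' result
    sets; such sentences carry contradictory labels and are removed.
    """
    by_class: dict[str, set[str]] = {}
    for sent, lab in corpus:
        by_class.setdefault(lab, set()).add(sent)
    labels = list(by_class)
    ambiguous: set[str] = set()
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            ambiguous |= by_class[a] & by_class[b]
    if ambiguous:
        logger.info("dropped %d cross-class duplicate sentences", len(ambiguous))
    return [(s, lab) for s, lab in corpus if s not in ambiguous]


def write_corpus_file(corpus: list[tuple[str, str]]) -> str:
    """One ``sentence<TAB>label`` line per pair."""
    return "".join(f"{s}\t{lab}\n" for s, lab in corpus)


def read_corpus_file(text: str) -> list[tuple[str, str]]:
    corpus = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rsplit("\t", 1)
        if len(parts) != 2 or parts[1] not in ("systemic", "cellular"):
            raise ValueError(f"corpus line {lineno}: expected 'sentence<TAB>systemic|cellular'")
        corpus.append((parts[0], parts[1]))
    return corpus
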