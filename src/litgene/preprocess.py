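"""Sentence preprocessing for the stress classifier.

The pipeline is: lowercase, strip punctuation (any non-alphanumeric
character becomes a token boundary), filter stopwords against the pinned
in-repo list, then Porter-stem the survivors. Stopword filtering happens
before stemming — the stopword list contains surface forms, so filtering
stems against it would be ill-defined.

The configuration is content-addressed: :attr:`PreprocessConfig.config_hash`
digests the stopword list and the flags, and is stored in persisted model
manifests so a model is never silently applied with different
preprocessing than it was trained with.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources

from .stemming import porter_stem

__all__ = ["PreprocessConfig", "load_stopwords", "tokenize", "preprocess"]

_TOKEN = re.compile(r"[a-z0-9]+")


def load_stopwords() -> frozenset[str]:
    """The pinned English stopword snapshot shipped with the package."""
    text = (
        resources.files("litgene").joinpath("data/stopwords_english.txt").read_text()
    )
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


@dataclass(frozen=True)
class PreprocessConfig:
    stopwords: frozenset[str] = field(default_factory=load_stopwords)
    lowercase: bool = True
    strip_punctuation: bool = True
    stemmer: str = "porter"

    @property
    def config_hash(self) -> str:
        h = hashlib.sha256()
        h.update("\n".join(sorted(self.stopwords)).encode())
        h.update(f"|{self.lowercase}|{self.strip_punctuation}|{self.stemmer}".encode())
        return h.hexdigest()


def tokenize(sentence: str, cfg: PreprocessConfig) -> list[str]:
    text = sentence.lower() if cfg.lowercase else sentence
    if cfg.strip_punctuation:
        return _TOKEN.findall(text.lower() if not cfg.lowercase else text)
    return text.split()


def preprocess(sentence: str, cfg: PreprocessConfig | None = None) -> list[str]:
    """Lowercased, punctuation-stripped, stopword-filtered, stemmed tokens.

    Token order is preserved; an empty or all-stopword sentence yields [].
    """
    if cfg is None:
        cfg = PreprocessConfig()
    tokens = [t for t in tokenize(sentence, cfg) if t not in cfg.stopwords]
    if cfg.stemmer == "porter":
        tokens = [porter_stem(t) for t in tokens]
    elif cfg.stemmer != "none":
        raise ValueError(f"unknown stemmer {cfg.stemmer!r}")
    return tokens
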