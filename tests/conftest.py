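"""Shared fixtures: a toy ontology, a hand-written 10-abstract corpus with
hand-counted co-occurrence tallies, a tiny GWAS catalog, and a small trained
stress model reused across tests."""

from __future__ import annotations

import pytest

import litgene as lg

TOY_ONTOLOGY_YAML = """\
- category: drugs
  concepts:
    - concept: nicotine
      keywords: [nicotine, smoking]
    - concept: cocaine
      keywords: [cocaine]
- category: stress
  concepts:
    - concept: stress
      keywords: [stress, stressor]
- category: GWAS
  concepts:
    - concept: smoking traits
      keywords: [smoking]
"""

# hand-segmented and hand-counted; see test_mining/test_acceptance for the
# expected tallies derived from these texts
TEN_ABSTRACTS = [
    ("1", "CHRNA5 and nicotine dependence.",
     "CHRNA5 variants alter nicotine intake. Smoking was frequent."),
    ("2", "Nicotine effects.",
     "We measured CHRNA5 expression. Nicotine and cocaine were "
     "co-administered with CHRNA5 agonists."),
    ("3", "BDNF and stress.",
     "Chronic stress reduced BDNF levels. BDNF was also reduced by a stressor."),
    ("4", "Oxidative stress.",
     "BDNF is elevated. Oxidative stress-induced damage was observed in "
     "BDNF knockouts."),
    ("5", "CNR imaging metrics.",
     "CNRs were computed for each scan. Smoking status did not affect CNR values."),
    ("6", "Gene in title only.",
     "BDNF regulates plasticity. Stress hormones were elevated in controls."),
    ("7", "CHRNA5 smoking study.",
     "Smith et al. reported smoking effects on CHRNA5 expression."),
    ("8", "BDNF and cocaine.",
     "Cocaine exposure increased BDNF. Repeated cocaine altered BDNF signaling."),
    ("9", "Stress and CHRNA5.",
     "CHRNA5 expression was unchanged after stress."),
    ("10", "Unrelated work.",
     "Nothing relevant here. No genes or keywords at all."),
]

GWAS_TSV = (
    "PUBMEDID\tDISEASE/TRAIT\tMAPPED_TRAIT\tREPORTED GENE(S)\tMAPPED_GENE\tSNPS\tP-VALUE\n"
    "111\tSmoking initiation\tsmoking behavior\tCHRNA5, CHRNA3\tCHRNA5\trs16969968\t2E-20\n"
    "222\tAlcohol consumption\talcohol drinking\tBDNF\tBDNF - BDNF-AS\trs6265\t1E-8\n"
    "333\tSmoking cessation\tsmoking cessation\t\tCHRNA5 - AGPHD1\trs588765\t5E-9\n"
)

# distinct-abstract counts per (gene, concept), counted by hand from TEN_ABSTRACTS
HAND_TALLIES = {
    ("CHRNA5", "nicotine"): 3,  # pmids 1, 2, 7
    ("CHRNA5", "cocaine"): 1,   # pmid 2
    ("CHRNA5", "stress"): 1,    # pmid 9
    ("BDNF", "stress"): 2,      # pmids 3, 4
    ("BDNF", "cocaine"): 1,     # pmid 8
    ("CNR", "nicotine"): 1,     # pmid 5 ("Smoking status ... CNR values.")
}


@pytest.fixture(scope="session")
def toy_ontology() -> lg.KeywordOntology:
    return lg.parse_ontology(TOY_ONTOLOGY_YAML)


@pytest.fixture(scope="session")
def fixture_records() -> list[lg.AbstractRecord]:
    return [lg.AbstractRecord(p, t, a) for p, t, a in TEN_ABSTRACTS]


@pytest.fixture(scope="session")
def gwas_catalog() -> list[lg.GwasAssociation]:
    return lg.read_gwas_catalog(GWAS_TSV)


@pytest.fixture(scope="session")
def small_trained_model():
    """A quickly trained model on a small separable synthetic corpus."""
    corpus = lg.generate_synthetic_corpus(400, seed=11)
    model, report = lg.train(corpus, seed=11, max_epochs=10)
    return model, report, corpus
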