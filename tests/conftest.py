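import pytest

import vmescan as v

# Independent transcription of the indicator table: one status token per
# management body, in BODIES order (NPFC, SPRFMO, NEAFC, NAFO_ABNJ, CCAMLR,
# SEAFO, GFCM, SIOFA).  y = indicator, n = not an indicator, q = qualified
# (restricted sub-taxa or a verbatim restriction note).  Used to enumerate
# every cell of the packaged registry against this second copy.
EXPECTED_CELLS = {
    "Actiniaria":          "n y n n y n n y",
    "Ceriantharia":        "n n q q n q y n",
    "Alcyonacea":          "y y y q y y y y",
    "Pennatulacea":        "n y y y y y y y",
    "Antipatharia":        "y y q y y y y y",
    "Scleractinia":        "y q y q y y y y",
    "Hydroidolina":        "n q n n y q y q",
    "Stylasteridae":       "n y y n y n q y",
    "Zoantharia":          "n y n n y y n y",
    "Brisingida":          "n y n n n n n n",
    "Crinoida":            "n y q q q y y q",
    "Echinoidea":          "n n n n q n n q",
    "Ophiuroidea":         "n n n n q q n q",
    "Arthropoda":          "n n q n q n n q",
    "Ascidiacea":          "n n n y y y n y",
    "Bivalvia":            "n n q n q n q n",
    "Brachiopoda":         "n n n n y n n y",
    "Bryozoa":             "n q q q y y q y",
    "Polychaeta":          "n n q n q q q q",
    "Porifera":            "n q y y q y q q",
    "Pterobranchia":       "n n n n y n n y",
    "Xenophyophoroidea":   "n n y y y n n y",
    "Chemosynthetic taxa": "n n q n y n y y",
    "Seamounts as a whole": "n n q y n n q n",
}

# Spot checks that qualified cells carry the right restriction payload.
EXPECTED_QUALIFIERS = {
    ("Ceriantharia", "NEAFC"): {"subtaxa": {"Cerianthidae"}},
    ("Ceriantharia", "NAFO_ABNJ"): {"subtaxa": {"Cerianthidae"}},
    ("Ceriantharia", "SEAFO"): {"subtaxa": {"Cerianthidae"}},
    ("Scleractinia", "SPRFMO"): {
        "subtaxa": {"Solenosmilia", "Goniocorella", "Oculina",
                    "Enallopsammia", "Madrepora", "Lophelia"},
    },
    ("Crinoida", "NEAFC"): {"note": "stalked"},
    ("Porifera", "SPRFMO"): {"subtaxa": {"Demospongiae", "Hexactinellida"}},
    ("Echinoidea", "CCAMLR"): {"subtaxa": {"Cidaroida"}},
    ("Polychaeta", "CCAMLR"): {"subtaxa": {"Serpulidae"}},
    ("Stylasteridae", "GFCM"): {"note": "Hydroidolina"},
    ("Bryozoa", "NEAFC"): {"subtaxa": {"Eucratea loricata"}},
}


@pytest.fixture(scope="session")
def registry():
    return v.load_registry()


@pytest.fixture(scope="session")
def tiny():
    return v.make_fixture("tiny")


@pytest.fixture(scope="session")
def study_like():
    return v.make_fixture("study_like", seed=20259)
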