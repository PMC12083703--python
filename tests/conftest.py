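import pytest

from mint.label_space import LabelEntry, LabelSpace, TermDictionary


@pytest.fixture
def tissue_space() -> LabelSpace:
    """A small tissue-type vocabulary (no abbreviations)."""
    return LabelSpace.from_names(
        ["bile duct", "colon", "liver", "breast", "kidney", "lung"]
    )


@pytest.fixture
def disease_space() -> LabelSpace:
    """Disease names in the 'Full Name (ABBR)' clinical convention."""
    return LabelSpace([
        LabelEntry("Phelan-McDermid syndrome", "PHMDS", 0),
        LabelEntry("Williams-Beuren syndrome", "WBS", 1),
        LabelEntry("Cornelia de Lange Syndrome", "CdLS", 2),
        LabelEntry("Simpson-golabi-behmel Syndrome, type 1", None, 3),
        LabelEntry("Kabuki syndrome", None, 4),
    ])


@pytest.fixture
def hpo_dict() -> TermDictionary:
    """Phenotype-term texts for the worked prompt-construction example."""
    return TermDictionary({
        "HP:0000486": "Strabismus",
        "HP:0001263": "Global developmental delay",
        "HP:0010864": "Intellectual disability, severe",
        "HP:0004322": "Short stature",
    })
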