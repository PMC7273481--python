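import pytest

from ihcminer.corpus_io import Report
from ihcminer.lexicon import load_lexicon
from ihcminer.synth_corpus import SynthSpec, gen_corpus


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture
def regional_report():
    return Report(
        case_id="R001",
        diagnosis_lines=[
            "Lymph node, axillary, dissection --- carcinoma, metastatic, breast origin"
        ],
        description_paragraphs=[
            "Sections show metastatic carcinoma.",
            "Immunohistochemical study shows: ER (positive, 90%), PR (negative), "
            "HER2 (negative, 1+).",
        ],
    )


@pytest.fixture
def distant_report():
    return Report(
        case_id="D001",
        diagnosis_lines=[
            "Brain, tumor, excision --- carcinoma, metastatic, breast origin"
        ],
        description_paragraphs=[
            "Sections show a metastatic adenocarcinoma.",
            "ER (positive, 80%)\nPR (positive, 30%)\nHER2 (equivocal, 2+)",
        ],
    )


@pytest.fixture
def benign_report():
    return Report(
        case_id="B001",
        diagnosis_lines=["Stomach, biopsy --- chronic gastritis"],
        description_paragraphs=["The gastric mucosa shows chronic inflammation."],
    )


@pytest.fixture(scope="session")
def clean_corpus():
    """200-report clean corpus: supported dialects only, no confounders."""
    spec = SynthSpec(
        n_regional=100,
        n_distant=60,
        n_benign=40,
        dialect_mix={"sentence": 0.4, "multirow": 0.3, "comma_block": 0.3,
                     "unsupported": 0.0},
        seed=20200523,
    )
    return gen_corpus(spec)
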