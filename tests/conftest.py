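import pytest
from importlib.resources import files

from medic.catalog import load_catalog
from medic.extractor import DictionaryTagger
from medic.factory import load_libraries, load_noise_model, load_patterns
from medic.normalizer import load_rules
from medic.schema import ComponentLabel, LabeledDirection, LabeledSpan

DATA = files("medic.data")

WORKED_TEXT = "take one tablet by mouth once daily for pain"


def _span(start, end, label, text=WORKED_TEXT):
    return LabeledSpan(start=start, end=end, label=label,
                       surface=text[start:end])


@pytest.fixture(scope="session")
def worked_example():
    """The canonical five-component direction, hand-labeled."""
    return LabeledDirection(
        record_id="worked-1",
        drug_id="d001",
        text=WORKED_TEXT,
        spans=(
            _span(0, 4, ComponentLabel.VERB),
            _span(5, 15, ComponentLabel.DOSE),
            _span(16, 24, ComponentLabel.ROUTE),
            _span(25, 35, ComponentLabel.FREQUENCY),
            _span(36, 44, ComponentLabel.AUXI_INDIC),
        ),
    )


@pytest.fixture(scope="session")
def libraries():
    return load_libraries(DATA / "libraries.json")


@pytest.fixture(scope="session")
def patterns():
    return load_patterns(DATA / "patterns.json")


@pytest.fixture(scope="session")
def vocabulary(libraries):
    return frozenset(
        tok for lib in libraries.values()
        for surface in lib.surfaces for tok in surface.lower().split()
    )


@pytest.fixture(scope="session")
def rules(vocabulary):
    return load_rules(DATA / "rules.yaml").with_vocabulary(vocabulary)


@pytest.fixture(scope="session")
def catalog():
    return load_catalog(DATA / "catalog.tsv")


@pytest.fixture(scope="session")
def noise_model():
    return load_noise_model(DATA / "noise.yaml")


@pytest.fixture(scope="session")
def dictionary_tagger(libraries):
    return DictionaryTagger(libraries)
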