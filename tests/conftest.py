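from importlib import resources
from pathlib import Path

import pytest

from narsent.annotation import annotate_utterances
from narsent.synthetic import toy_lexicons
from narsent.transcripts_io import read_token_table


def data_path(name: str) -> Path:
    return Path(resources.files("narsent").joinpath("data", name))


@pytest.fixture(scope="session")
def lexicons():
    return toy_lexicons()


@pytest.fixture(scope="session")
def sentiment_lexicon(lexicons):
    return lexicons[0]


@pytest.fixture(scope="session")
def lcm_lexicon(lexicons):
    return lexicons[1]


@pytest.fixture(scope="session")
def example_utterances():
    """The worked four-token sentence with its chosen interpretations."""
    return read_token_table(data_path("example_sentence.tsv"))


@pytest.fixture(scope="session")
def example_annotated(example_utterances, lexicons):
    sent, lcm = lexicons
    return annotate_utterances(example_utterances, sent, lcm)


@pytest.fixture
def chat_file(tmp_path):
    def _make(body: str, name: str = "sample.cha") -> Path:
        path = tmp_path / name
        path.write_text(body, encoding="utf-8")
        return path

    return _make
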