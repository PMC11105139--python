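import pytest

from charlson_nlp.config import load_pipeline_config
from charlson_nlp.matcher import compile_matchers


@pytest.fixture(scope="session")
def pipeline_config():
    return load_pipeline_config()


@pytest.fixture(scope="session")
def definitions(pipeline_config):
    return pipeline_config.definitions


@pytest.fixture(scope="session")
def matchers(definitions):
    return compile_matchers(definitions)


@pytest.fixture(scope="session")
def cue_lexicon(pipeline_config):
    return pipeline_config.cue_lexicon
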