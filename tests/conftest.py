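import pytest
from hypothesis import settings

from faerspv.cases import build_analysis_set

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")
from faerspv.meddra import toy_ontology
from faerspv.synth import SynthConfig, frames_to_tables, generate_corpus, write_corpus


@pytest.fixture(scope="session")
def toy_maps():
    return toy_ontology()


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(
        n_cases=600,
        theta={("tofacitinib", "Acne"): 8.0, ("deucravacitinib", "Rash"): 5.0},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return generate_corpus(small_config)


@pytest.fixture(scope="session")
def extract_dir(small_corpus, tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus") / "extract"
    write_corpus(small_corpus.frames, out)
    return out


@pytest.fixture(scope="session")
def analysis_set(small_corpus, small_config):
    tables = frames_to_tables(small_corpus.frames)
    return build_analysis_set(tables, small_config.cohort_config())
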