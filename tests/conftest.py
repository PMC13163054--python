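import pytest

from darktraits.io import run_corpus
from darktraits.synthetic import SyntheticSpec, generate_page_corpus


@pytest.fixture(scope="session")
def lossless_corpus():
    """Noise- and contamination-free corpus: gold must round-trip exactly."""
    spec = SyntheticSpec(
        seed=101,
        n_documents=12,
        noise_sd_log10=0.0,
        duplicate_rate=0.0,
        regression_table_rate=0.0,
        annotation_noise_rate=0.0,
        multipage_split_rate=0.0,
    )
    return generate_page_corpus(spec)


@pytest.fixture(scope="session")
def default_corpus():
    """Small corpus under the default (noisy, contaminated) conditions."""
    return generate_page_corpus(SyntheticSpec(seed=202, n_documents=40))


@pytest.fixture(scope="session")
def default_corpus_output(default_corpus):
    return run_corpus(default_corpus)
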