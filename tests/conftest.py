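import numpy as np
import pytest

from weightask.config import SyntheticConfig
from weightask.pipeline import build_asker_records, extract_corpus
from weightask.synthetic import generate_corpus, posts_to_frame, truth_to_frame


@pytest.fixture
def rng():
    return np.random.default_rng(20250927)


@pytest.fixture(scope="session")
def clean_corpus():
    """Small corpus with no omission/ambiguity: every field is recoverable."""
    cfg = SyntheticConfig(
        seed=42,
        n_askers=400,
        omission_rates={"age": 0.0, "weight": 0.0, "height": 0.0, "gender": 0.0},
        ambiguity_rate=0.0,
    )
    posts, truths = generate_corpus(cfg)
    return cfg, posts_to_frame(posts), truth_to_frame(truths)


@pytest.fixture(scope="session")
def clean_records(clean_corpus):
    cfg, posts, truth = clean_corpus
    extraction = extract_corpus(posts)
    records, accounting = build_asker_records(extraction)
    return extraction, records, accounting
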