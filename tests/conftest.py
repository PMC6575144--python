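import numpy as np
import pytest

from ltcnlp import corpus_io, synthetic_data as sd
from ltcnlp.types import CaseCategory


@pytest.fixture(scope="session")
def small_corpus():
    """Calibrated corpus, small enough for fast unit tests."""
    cfg = sd.default_config(n_records=8000, seed=101, blank_narrative_fraction=0.051)
    return sd.generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_sample(small_corpus):
    sample = corpus_io.build_analytic_sample(small_corpus.records)
    for rec in sample.records:
        corpus_io.recode(rec)
    return sample


@pytest.fixture(scope="session")
def rich_corpus():
    """Higher-prevalence corpus so positive-class statistics are stable."""
    prev = {
        CaseCategory.IN_LTC: 0.05,
        CaseCategory.TRANSITIONING: 0.04,
        CaseCategory.OTHERWISE_ASSOCIATED: 0.02,
    }
    prev[CaseCategory.NOT_ASSOCIATED] = 1 - sum(prev.values())
    cfg = sd.default_config(
        n_records=1200, seed=77, prevalence=prev, blank_narrative_fraction=0.0
    )
    return sd.generate_corpus(cfg)


def make_record(i, **kwargs):
    defaults = dict(
        id=f"R{i:04d}", state="S01", year=2008, age=70, sex="male",
        race_eth="non-Hispanic white", marital="widowed", manner="suicide",
        means="firearm", injury_location_code="house or apartment",
        death_location_code="decedent's home", flags={}, narrative="A narrative.",
    )
    defaults.update(kwargs)
    return corpus_io.NarrativeRecord(**defaults)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
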