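import pytest
from hypothesis import HealthCheck, settings

from cmapminer.corpus import Lexicon
from cmapminer.synth import SynthConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def disease_lexicon():
    return Lexicon(
        "disease",
        {"DIS:HNC": {"head and neck cancer", "oral cancer", "HNSCC"}},
    )


@pytest.fixture
def gene_lexicon():
    return Lexicon(
        "gene",
        {
            "G:EGFR": {"EGFR"},
            "G:TP53": {"TP53", "p53"},
            "G:TP53BP1": {"TP53BP1"},
        },
    )


@pytest.fixture
def drug_lexicon():
    return Lexicon("drug", {"D:CETUX": {"cetuximab"}, "D:QUERC": {"quercetin"}})


@pytest.fixture
def synth_cfg():
    return SynthConfig(seed=0)
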