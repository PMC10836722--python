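import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_sample():
    """Three-clonotype sample with counts 10/30/60."""
    from repseq import Clonotype, RepertoireSample

    clones = [
        Clonotype("TRB", "TGTGCCAGCAGCGGG", "CASSG", "TRBV7-2*01", "TRBJ2-1*01", count=10, frequency=0.1),
        Clonotype("TRB", "TGTGCCAGCAGCACC", "CASST", "TRBV5-1*01", "TRBJ2-1*01", count=30, frequency=0.3),
        Clonotype("TRB", "TGTGCCAGCAGCCTG", "CASSL", "TRBV7-2*01", "TRBJ2-7*01", count=60, frequency=0.6),
    ]
    return RepertoireSample(sample_id="S1", clonotypes=clones)
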