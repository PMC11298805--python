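import pytest

from cnvpop.io_formats import CnvCall
from cnvpop.synthetic_data import SimulationConfig, simulate_cohort


def make_call(chrom="chr1", start=100, end=200, svtype="DUP", sample="s1",
              cn=None, support=None, precise=True, caller="test"):
    return CnvCall(
        sample_id=sample, caller=caller, chrom=chrom, start=start, end=end,
        svtype=svtype, copy_number=cn, support_reads=support, precise=precise,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The standard study conditions: 11 + 10 samples, 300 regions,
    20 planted at Vst 0.8, 50 bp jitter, 5 % dropout."""
    return simulate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def noise_free_cohort():
    return simulate_cohort(SimulationConfig(seed=42, jitter_sd=0.0, dropout_rate=0.0))
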