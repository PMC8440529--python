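import numpy as np
import pytest

from mrith.core_io import MutationCall, SegmentCN, RegionProfile


def make_call(**kwargs) -> MutationCall:
    """A valid MutationCall with overridable fields."""
    defaults = dict(
        patient_id="P1",
        region_id="R1",
        chrom="1",
        pos=1_000_000,
        ref="C",
        alt="T",
        gene="TP53",
        effect="nonsilent",
        alt_reads=30,
        ref_reads=220,
        normal_alt_reads=0,
        normal_depth=250,
        population_af=0.0,
        context="ACA",
    )
    defaults.update(kwargs)
    return MutationCall(**defaults)


def make_segment(**kwargs) -> SegmentCN:
    defaults = dict(
        patient_id="P1",
        region_id="R1",
        chrom="1",
        start=1,
        end=100_000_000,
        total_cn=2.0,
        major_cn=1,
        minor_cn=1,
    )
    defaults.update(kwargs)
    return SegmentCN(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(20210914)


@pytest.fixture
def small_patient():
    """One simulated patient under default study conditions."""
    from mrith.simulate import SimConfig, simulate_patient

    return simulate_patient(SimConfig(seed=11), 0)
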