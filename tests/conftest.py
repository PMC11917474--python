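import numpy as np
import pandas as pd
import pytest

from rdnavar.io_formats import allele_counts_from_records
from rdnavar.simulate import SimConfig, progenitor_state


@pytest.fixture
def sim_config():
    """Default SX-like study conditions: 4 haplotypes, 25 SNPs, haploid 190."""
    return SimConfig()


@pytest.fixture
def progenitor(sim_config):
    return progenitor_state(sim_config)


@pytest.fixture
def counts_frame():
    """Tiny raw allele-count table spanning the filter boundaries."""
    rows = [
        # below-min allele zeroed, rest retained
        dict(sample_id="s1", region="28S", position=100, ref_base="G",
             nA=4, nC=120, nG=0, nT=3),
        # recomputed total exactly at the retention boundary
        dict(sample_id="s1", region="28S", position=200, ref_base="A",
             nA=5, nC=94, nG=0, nT=0),
        # recomputed total just below the boundary -> missing
        dict(sample_id="s1", region="28S", position=300, ref_base="A",
             nA=5, nC=93, nG=0, nT=0),
        dict(sample_id="s2", region="28S", position=100, ref_base="G",
             nA=0, nC=80, nG=70, nT=0),
        dict(sample_id="s2", region="28S", position=200, ref_base="A",
             nA=60, nC=60, nG=0, nT=0),
        dict(sample_id="s2", region="28S", position=300, ref_base="A",
             nA=150, nC=0, nG=0, nT=0),
    ]
    return allele_counts_from_records(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
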