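import numpy as np
import pytest

from isoforage.core_io import (IsotopeSample, McmcConfig, SourceGroup,
                               TrophicEnrichment)


@pytest.fixture
def tef():
    return TrophicEnrichment(delta_d15N_mean=5.2, delta_d15N_sd=0.28,
                             delta_d13C_mean=4.6, delta_d13C_sd=0.71)


@pytest.fixture
def two_sources():
    return [
        SourceGroup("A", "X", mu=(-26.0, 3.0), sigma=(0.8, 0.5),
                    conc=(40.0, 2.0), n=5),
        SourceGroup("B", "X", mu=(-14.0, 7.0), sigma=(0.9, 0.6),
                    conc=(42.0, 8.0), n=5),
    ]


@pytest.fixture
def square_sources(tef):
    """Four well-separated, low-sd sources at square corners (TEF-corrected
    positions known)."""
    corners = [(-30.0, 0.0), (-30.0, 12.0), (-10.0, 12.0), (-10.0, 0.0)]
    return [
        SourceGroup(f"S{i}", "X", mu=c, sigma=(0.3, 0.3), conc=(40.0, 5.0), n=4)
        for i, c in enumerate(corners)
    ]


def consumer_at(d13C, d15N, sample_id="c1", site="X", status="natural"):
    return IsotopeSample(sample_id=sample_id, site=site, habitat_status=status,
                         category="Armases", d13C=d13C, d15N=d15N,
                         pctC=40.0, pctN=10.0)


@pytest.fixture
def make_consumer():
    return consumer_at


@pytest.fixture
def fast_mcmc():
    return McmcConfig(chains=2, iterations=3000, burn_in=1500, thin=5, seed=0)
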