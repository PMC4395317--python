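import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

from snpanchor.genotype_bayes import BaseCompositionModel, genotype_prior
from snpanchor.genotype_matrix import load_confirmed_genotypes
from snpanchor.types import GenomicSite, PileupColumn


@pytest.fixture(scope="session")
def comp41():
    return BaseCompositionModel(0.41)


@pytest.fixture(scope="session")
def comp50():
    return BaseCompositionModel(0.50)


@pytest.fixture(scope="session")
def prior41(comp41):
    return genotype_prior(comp41)


@pytest.fixture(scope="session")
def confirmed_matrix():
    """The packaged confirmed-genotype matrix (97 cells x 18 sites)."""
    return load_confirmed_genotypes()


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def make_column(ref="A", bases=(), e=1e-3, chrom="chr1", pos=100, mapq=60):
    """Quick pileup column: bases may be a string like 'AATT'."""
    site = GenomicSite(chrom, pos, ref)
    obs = [(b, e, mapq) for b in bases]
    return PileupColumn(site, obs)
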