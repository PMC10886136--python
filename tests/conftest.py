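import numpy as np
import pytest

from cgprofiler import synth
from cgprofiler.core import DepthProfile, GenomicInterval


@pytest.fixture(scope="session")
def small_somatic_fixture():
    """Desk-scale somatic truth set: 20 SNV + 5 indel + 10 decoys on 50 kb."""
    spec = synth.SomaticSpec(
        n_snv=20, n_indel=5, n_ineligible=10, n_genes=5, coding_bases=50_000
    )
    return synth.generate_somatic_fixture(spec, seed=11)


@pytest.fixture(scope="session")
def oncospan_like_fixture():
    """228-variant (211 SNV + 17 indel) truth set at VAF >= 5%, 500X."""
    spec = synth.SomaticSpec(n_snv=211, n_indel=17, n_ineligible=40, coding_bases=200_000)
    return synth.generate_somatic_fixture(spec, seed=7)


@pytest.fixture
def flat_profile():
    """Uniform 500X over 10 kb coding + 1 kb non-coding panel."""
    panel = [
        GenomicInterval("chr1", 1000, 11000, "G1", True),
        GenomicInterval("chr1", 12000, 13000, "G1", False),
    ]
    return panel, DepthProfile(panel, np.full(11000, 500))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240209)
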