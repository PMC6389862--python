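import numpy as np
import pytest

from pirsite import fixtures, profilehmm


@pytest.fixture(scope="session")
def default_bundle():
    """A mixed family: 8 members, 2 negatives, mild indels."""
    return fixtures.generate_family(
        fixtures.FamilySpec(seed=3, negative_fraction=0.25, indel_rate=0.03))


@pytest.fixture(scope="session")
def clean_bundle():
    """5 members, no negatives, no indels: ground truth is the identity map."""
    return fixtures.generate_family(
        fixtures.FamilySpec(seed=11, n_members=5, negative_fraction=0.0,
                            indel_rate=0.0))


@pytest.fixture(scope="session")
def small_hmm():
    """A calibrated 4-node profile built from a tiny conserved alignment."""
    msa = ["ACDE", "ACDE", "ACDE", "AGDE", "ACDE", "ACDE"]
    hmm = profilehmm.build_profile(msa, pseudocount_weight=1.0,
                                   hmm_id="tiny4")
    hmm.calibration = profilehmm.calibrate(hmm, n=80, length=20, seed=5)
    return hmm


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
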