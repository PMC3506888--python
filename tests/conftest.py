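import numpy as np
import pytest

from transposcan import calibration as cal
from transposcan import synthetic as syn
from transposcan.evd import calibrate_evd


@pytest.fixture(scope="session")
def small_truth():
    """A small generative truth family shared by scan-level tests."""
    return syn.make_truth_profile("ISF9", M=40, conservation=0.9, seed=901)


@pytest.fixture(scope="session")
def calibrated_family(small_truth):
    """A rebuilt, EVD- and ROC-calibrated model set for the small family."""
    profile = syn.rebuild_profile_from_samples(small_truth, n=30, seed=902)
    calibrate_evd(profile, n_random=500, seed=903)
    pos = syn.sample_from_profile(small_truth, 30, seed=904)
    neg = syn.shuffle_negatives(pos, seed=905) + syn.shuffle_negatives(
        syn.sample_from_profile(small_truth, 70, seed=906), seed=907
    )
    labeled = cal.LabeledSet(positives=pos, negatives=neg)
    result = cal.calibrate_profile(profile, labeled, db_size=1000)
    fms = cal.FamilyModelSet(
        small_truth.family_id, [cal.FamilyCandidate(profile, result)]
    )
    return cal.select_family_models(fms)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
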