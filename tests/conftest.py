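import numpy as np
import pytest

from polcrab.behaviour import TrialRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trial(
    crab_id="crab000",
    species="C_rugosus",
    modality="polarization",
    contrast=0.25,
    order=1,
    behaviours=None,
    pre_stim=False,
):
    return TrialRecord(
        crab_id=crab_id,
        species=species,
        modality=modality,
        contrast=contrast,
        order=order,
        behaviours=behaviours or [],
        pre_stimulus_full_retreat=pre_stim,
    )
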