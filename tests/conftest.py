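import numpy as np
import pytest

from somnoval.hypnogram import Hypnogram, PairedNight, STAGES_4


def random_hypnogram(rng, n_epochs, subject_id="s0", night_id="n0",
                     group="other", p=(0.25, 0.40, 0.18, 0.17)):
    stages = tuple(rng.choice(STAGES_4, size=n_epochs, p=p))
    return Hypnogram(subject_id=subject_id, night_id=night_id, group=group,
                     epoch_s=30, stages=stages)


def random_pair(rng, n_epochs, **kw):
    ref = random_hypnogram(rng, n_epochs, **kw)
    test = random_hypnogram(rng, n_epochs, **kw)
    return PairedNight(ref=ref, test=test)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A four-group paired cohort, small enough for fast structural tests."""
    from somnoval import cohort
    presets = cohort.group_presets()
    pairs, truth = cohort.simulate_cohort(
        profiles=presets,
        n_subjects={g: 4 for g in presets},
        nights_per_subject=(1, 3),
        corruption=cohort.CorruptionModel(subject_sd=0.2),
        seed=11)
    return pairs, truth
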