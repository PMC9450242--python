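import logging

import pytest

import twophase as tp
from twophase.cohort import Participant, ScreeningProfile

logging.getLogger("twophase").setLevel(logging.ERROR)


def make_participant(pid="p1", gender="female", cohort="cohort2", **screen):
    """A minimal valid participant; cohort2 members carry the
    gambling/gaming screening questions (False/none by default)."""
    profile = ScreeningProfile(
        ever_gambled_money=False, ever_paid_in_game=False,
        gaming_hours_band="none")
    for k, v in screen.items():
        setattr(profile, k, v)
    return Participant(participant_id=pid, gender=gender, cohort=cohort,
                       screening=profile)


@pytest.fixture
def default_policy():
    return tp.CutoffPolicy()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (949 participants)."""
    cohort, truth = tp.generate_cohort(tp.GeneratorConfig(), seed=11)
    return cohort, truth


@pytest.fixture(scope="session")
def noiseless_config():
    """Perfect screening and participation: the no-noise limit."""
    return tp.GeneratorConfig(
        screen_sensitivity={"substance": 1.0, "psychiatric": 1.0,
                            "gambling": 1.0, "gaming": 1.0},
        screen_false_positive={"substance": 0.0, "psychiatric": 0.0,
                               "gambling": 0.0, "gaming": 0.0},
        participation={"female": 1.0, "male": 1.0},
        cohort1_gambling_gap=False,
    )
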