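import numpy as np
import pytest
from hypothesis import settings

from artrials import RandomizedPlayTheWinner, TrialData

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rpw_rule():
    return RandomizedPlayTheWinner()


@pytest.fixture(scope="session")
def rpw_rule_unforced():
    return RandomizedPlayTheWinner(force_split_first_two=False)


@pytest.fixture(scope="session")
def worked_history(rpw_rule):
    """A 25-patient play-the-winner realisation entered by hand.

    8 patients on arm 1 with 5 responders and 17 on arm 2 with 15
    responders; the first two patients are split between the arms as the
    forced-split urn rule requires, and the recorded allocation
    probabilities are the ones the urn produces along this ordering.
    """
    arms = [0, 1] + [0] * 7 + [1] * 16
    outcomes = [1, 1] + [1, 1, 1, 1, 0, 0, 0] + [1] * 14 + [0, 0]
    bare = TrialData(np.array(arms), np.array(outcomes), 2)
    probs = rpw_rule.probs_from_trial(bare, recorded=True)
    return TrialData(bare.arms, bare.outcomes, 2, probs)
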