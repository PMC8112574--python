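"""Shared fixtures.

The session-scoped fixtures hold the one expensive artefact of the suite:
a synthetic 25-user corpus (500 saccades each), its subject-disjoint
80/20 split, and the fine-grained (64x64, combined-loss) six-horizon
ensemble trained on it at reduced scale (15 epochs).  Several integration
tests share them so the ensemble is trained exactly once.
"""

import numpy as np
import pytest

from saccland.baselines import CenterBiasModel
from saccland.evaluation import evaluate, make_splits
from saccland.predictor import LandingPointModel
from saccland.simulate import SimulatorParams, synth_corpus

CORPUS_SEED = 42
SPLIT_SEED = 7
TRAIN_SEED = 0
TRAIN_EPOCHS = 15


@pytest.fixture(scope="session")
def corpus25():
    """25 users x 500 saccades at default simulator parameters."""
    saccades, metas = synth_corpus(25, 500, SimulatorParams(), seed=CORPUS_SEED)
    return saccades, metas


@pytest.fixture(scope="session")
def open_split(corpus25):
    saccades, _ = corpus25
    ids = sorted({s.participant_id for s in saccades})
    plan = make_splits(ids, n_repeats=1, seed=SPLIT_SEED)[0]
    train = [s for s in saccades if s.participant_id in plan.train_participants]
    test = [s for s in saccades if s.participant_id in plan.test_participants]
    return plan, train, test


@pytest.fixture(scope="session")
def results_f(open_split):
    """Approach-F-style ensemble: coordinates target, combined loss, 64x64."""
    _, train, _ = open_split
    model = LandingPointModel(train, target="coordinates", loss="l3", units=(64, 64))
    return model.fit(seed=TRAIN_SEED, epochs=TRAIN_EPOCHS)


@pytest.fixture(scope="session")
def report_f(results_f, open_split):
    plan, _, test = open_split
    return evaluate(results_f.ensemble, test,
                    allowed_participants=plan.test_participants)


@pytest.fixture(scope="session")
def report_center_bias(open_split):
    plan, train, test = open_split
    cb = CenterBiasModel.fit(train, seed=TRAIN_SEED + 1)
    return evaluate(cb, test, allowed_participants=plan.test_participants)
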