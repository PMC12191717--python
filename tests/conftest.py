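"""Shared fixtures.

The expensive fixture is ``trained_desk``: one desk-profile model trained on
a 10,000-record synthetic cohort, shared (session-scoped) by every test that
needs a well-trained model, so the suite trains it exactly once.
"""

import numpy as np
import pytest

import medisim as ms
from medisim.synthetic import GroundTruth
from medisim.training import TrainConfig, fit


@pytest.fixture(scope="session")
def gen_config():
    return ms.default_config()


@pytest.fixture(scope="session")
def vocab(gen_config):
    return gen_config.vocabulary()


@pytest.fixture(scope="session")
def ground_truth(gen_config):
    return GroundTruth(gen_config)


@pytest.fixture(scope="session")
def cohort200(gen_config):
    return ms.sample_cohort(gen_config, 200, seed=11)


@pytest.fixture()
def tiny_model(vocab):
    return ms.MediSim(vocab, ms.ModelConfig(nemb=16, n_blocks=1, n_heads=2,
                                            max_visits=11, seed=5))


@pytest.fixture(scope="session")
def trained_desk(gen_config, vocab):
    """Desk-profile model (nemb=64, 2 blocks) trained on 10k records.

    Returns a dict with the model, the train/val splits, the ground truth,
    and the generator entropy bound.
    """
    cohort = ms.sample_cohort(gen_config, 10000, seed=7)
    train, val, _ = ms.split_cohort(cohort, (0.9, 0.1, 0.0), seed=7)
    model = ms.MediSim(vocab, ms.ModelConfig(seed=3))
    tc = TrainConfig.profile("desk", seed=3)
    _, history = fit(model, train, val, tc)
    gt = GroundTruth(gen_config)
    return {
        "model": model,
        "train": train,
        "val": val,
        "history": history,
        "ground_truth": gt,
        "entropy_bound": gt.entropy_rate_bound(),
        "config": gen_config,
    }


class ConstantProbModel:
    """Stub emitting a constant probability at every position."""

    def __init__(self, vocab, p=0.5, max_visits=100):
        from medisim.model import ModelConfig
        self.vocab = vocab
        self.config = ModelConfig(max_visits=max_visits)
        self.p = p

    def predict_record_probs(self, mat):
        return np.full_like(mat.values, self.p, dtype=float)


@pytest.fixture()
def constant_model_factory(vocab):
    def make(p=0.5):
        return ConstantProbModel(vocab, p)
    return make
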