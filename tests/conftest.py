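"""Shared fixtures.

The expensive fixture is ``study``: the full training study on synthetic
ultrasound data (200 images at 64x64, RFF-U-net, 30 epochs) used by the
end-to-end acceptance checks. It is session-scoped so the network trains
once per run, and only tests that request it pay for it.
"""

import numpy as np
import pytest

from rffseg.segnets import ModelConfig, build_model, train
from rffseg.synthetic import default_config, generate_dataset

STUDY_DATA_SEED = 7
STUDY_OPT_SEED = 1


@pytest.fixture(scope="session")
def study():
    """Train an RFF-U-net on the standard synthetic study conditions."""
    cfg = default_config(64, seed=STUDY_DATA_SEED)
    pairs, splits = generate_dataset(200, cfg)
    mc = ModelConfig(architecture="unet", input_size=(64, 64), depth=3,
                     base_filters=8, use_rff=True, q_factor=8, epochs=30,
                     batch_size=32, optimizer_seed=STUDY_OPT_SEED)
    net = build_model(mc)
    net, history = train(net, pairs, splits)
    test_pairs = [p for p, s in zip(pairs, splits) if s == "test"]
    return {"net": net, "pairs": pairs, "splits": splits,
            "test_pairs": test_pairs, "history": history, "config": mc}


@pytest.fixture(scope="session")
def quick_net():
    """A briefly trained tiny network for interface-level tests."""
    cfg = default_config(32, seed=3)
    pairs, splits = generate_dataset(40, cfg)
    mc = ModelConfig(architecture="unet", input_size=(32, 32), depth=2,
                     base_filters=4, use_rff=True, q_factor=8, epochs=3,
                     batch_size=8, optimizer_seed=0)
    net = build_model(mc)
    net, _ = train(net, pairs, splits)
    return {"net": net, "pairs": pairs, "splits": splits}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
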