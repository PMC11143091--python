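import numpy as np
import pandas as pd
import pytest

from p300decode.epochs import EpochSet, epoch_times
from p300decode.layout import ChannelLayout
from p300decode import sim


@pytest.fixture(scope="session")
def layout():
    return ChannelLayout()


@pytest.fixture(scope="session")
def times():
    return epoch_times()


def tiny_sim_config(seed=0, **kwargs):
    defaults = dict(
        seed=seed,
        n_subjects=1,
        n_sessions=1,
        blocks_per_session=2,
        noise=sim.NoiseSpec(sigma=1.0, channel_correlation=0.2),
    )
    defaults.update(kwargs)
    return sim.SimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_dataset():
    """1 subject, 1 session, 2 blocks x 10 runs x 8 trials (160 epochs)."""
    return sim.generate_dataset(tiny_sim_config())


def make_epochset(data, labels, layout=None, subject=1, session=1, scenario="social"):
    """Wrap raw arrays into an EpochSet with minimal valid metadata."""
    n = len(data)
    meta = pd.DataFrame(
        {
            "subject": subject,
            "session": session,
            "scenario": scenario,
            "block": 1,
            "run": np.arange(n) // 8 + 1,
            "trial_in_run": np.arange(n) % 8,
            "true_p300_latency": np.nan,
        }
    )
    return EpochSet(data=data, labels=labels, meta=meta, layout=layout or ChannelLayout())


@pytest.fixture(scope="session")
def separable_epochs(layout):
    """Noise-free, linearly separable toy set: targets carry a Pz bump."""
    rng = np.random.default_rng(7)
    times = epoch_times()
    n = 128
    labels = (np.arange(n) % 8 == 0).astype(int)
    bump = 5.0 * np.exp(-0.5 * ((times - 400.0) / 50.0) ** 2)
    topo = layout.gaussian_topography("Pz", spread=0.3)
    data = rng.normal(0.0, 0.3, size=(n, 8, len(times)))
    data[labels == 1] += topo[:, None] * bump[None, :]
    return make_epochset(data, labels, layout)
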