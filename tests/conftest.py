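import numpy as np
import pandas as pd
import pytest

from cranesdm import synthetic as syn
from cranesdm.grid import RasterGrid
from cranesdm.sampling import TrainingDesign


@pytest.fixture(scope="session")
def small_truth():
    """A 32x32 synthetic landscape with the default response spec."""
    return syn.make_truth((32, 32), seed=7)


@pytest.fixture
def grid_2x2():
    return RasterGrid(np.array([[1.0, 2.0], [3.0, 4.0]]), 0.0, 0.0, 1000.0,
                      name="toy")


def separable_design(n=1500, seed=0, imbalance=None):
    """Design whose label is exactly (Altitude > 2800); optionally thinned
    to an imbalanced presence class."""
    rng = np.random.default_rng(seed)
    alt = rng.uniform(1000, 6000, n)
    noise = rng.uniform(0, 1, n)
    y = (alt > 2800).astype(int)
    feats = pd.DataFrame({"Altitude": alt, "Noise": noise})
    if imbalance is not None:
        pos = np.flatnonzero(y == 1)[:imbalance]
        keep = np.concatenate([pos, np.flatnonzero(y == 0)])
        feats = feats.iloc[keep].reset_index(drop=True)
        y = y[keep]
    return TrainingDesign(presence=None, pseudo_absence=None, ratio=1,
                          features=feats, labels=y, categorical=())


@pytest.fixture
def sep_design():
    return separable_design()
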