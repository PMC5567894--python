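import numpy as np
import pandas as pd
import pytest

from meld import FeatureSpace, MeldDataset


@pytest.fixture
def toy_dataset():
    """Demo-scale dataset: 3 subjects x 10 trials x 15 features (3x5 grid),
    two independent variables (a 2-level condition and a continuous one)."""
    rng = np.random.default_rng(2024)
    rows = []
    for s in range(3):
        for t in range(10):
            rows.append((f"s{s}", f"i{t:02d}", "A" if t < 5 else "B", rng.normal()))
    design = pd.DataFrame(rows, columns=["subject", "item", "beh", "cont"])
    Y = rng.standard_normal((30, 15))
    return MeldDataset(design, Y, FeatureSpace((3, 5)))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
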