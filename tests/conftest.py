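import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from foldnet.io import ExpressionMatrix, Scale
from foldnet import simulate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_matrix():
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2"],
        np.array([[1.0, 2.0], [3.0, 4.5], [0.0, 9.0]]),
        Scale.RAW,
    )


@pytest.fixture(scope="session")
def panel_sim():
    """Default synthetic four-gene severity-stage study (9/7/8/7 samples)."""
    return simulate.simulate_panel(simulate.PanelSimConfig(seed=11))


@pytest.fixture(scope="session")
def module_sim():
    """Three planted 40-gene modules plus 30 noise genes over 30 samples."""
    return simulate.simulate_background_modules(simulate.CohortSimConfig(seed=5))


def make_matrix(values, scale=Scale.LOG10, prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
        scale,
    )


@pytest.fixture
def gse1297_shaped_metadata():
    """Metadata with the study's group sizes: 9 control, 7 incipient,
    8 moderate, 7 severe."""
    rows = []
    for name, n in (("Control", 9), ("Incipient AD", 7), ("Moderate", 8), ("Severe", 7)):
        for i in range(n):
            rows.append({"sample_id": f"{name.split()[0].lower()}_{i + 1}", "group": name})
    return pd.DataFrame(rows)
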