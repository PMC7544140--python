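import numpy as np
import pytest

from pitmorph.synthetic import ObserverStudyConfig, generate_observer_study
from pitmorph.types import LandmarkConfiguration


def make_config(coords, pit_id="P1", analyst_id=None, carnivore_label=None, labels=None):
    coords = np.asarray(coords, float)
    if labels is None:
        labels = tuple(f"LM{i + 1}" for i in range(coords.shape[0]))
    return LandmarkConfiguration(
        pit_id=pit_id,
        labels=labels,
        coords=coords,
        analyst_id=analyst_id,
        carnivore_label=carnivore_label,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_study():
    """6 pits per carnivore, 3 default analysts, 17 landmarks."""
    return generate_observer_study(ObserverStudyConfig(n_pits_per_carnivore=6, seed=11))


@pytest.fixture(scope="session")
def default_study():
    """The full study design: 30 pits per carnivore x 3 analysts x LM17."""
    return generate_observer_study(ObserverStudyConfig(seed=101))
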