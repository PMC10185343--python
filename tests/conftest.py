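import numpy as np
import pytest

from qflim import simulate as sim


@pytest.fixture(scope="session")
def small_population():
    """A reproducible 30-cell equilibrium population at Kd = 6 uM."""
    return sim.simulate_cell_population(30, kd_true=6.0, seed=11)


@pytest.fixture(scope="session")
def small_scene(small_population):
    """A rendered 15-cell scene (ER-like landmark)."""
    return sim.render_scene(
        small_population.head(15).reset_index(drop=True),
        sim.SceneGeometry(),
        landmark_kind="er",
        seed=7,
    )
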