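import numpy as np
import pytest

from spvsim import scene


@pytest.fixture(scope="session")
def corridor():
    return scene.CorridorSpec()


@pytest.fixture(scope="session")
def complex_corridor():
    return scene.CorridorSpec(complexity="complex")


@pytest.fixture(scope="session")
def layouts(corridor):
    """Seven difficulty-matched layouts plus mirrors (deterministic)."""
    return scene.generate_route_layouts(7, corridor, seed=101)


@pytest.fixture(scope="session")
def single_box_layout():
    """One centered large box; not a full course (count check disabled)."""
    return scene.RouteLayout((scene.ObstacleSpec("large", 1.5, 12.0),), "one-box")


@pytest.fixture(scope="session")
def entrance_pose():
    return scene.CameraPose(position=(1.5, 0.5, 1.70))


@pytest.fixture(scope="session")
def entrance_view(corridor, layouts, entrance_pose):
    """Full-resolution plain render from the corridor entrance."""
    return scene.render_view(corridor, layouts[0], entrance_pose, resolution=480)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220201)
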