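import numpy as np
import pytest

from rivaq import exchange, macrophytes, synthetic, tin


@pytest.fixture(scope="session")
def valley():
    """Default two-reach synthetic valley (gaining + losing) with its TINs."""
    sim = synthetic.generate_valley(synthetic.ValleyConfig(seed=7))
    piezo = tin.build_tin(sim.piezo_points.to_numpy(), "piezometric")
    river = tin.build_tin(sim.river_points.to_numpy(), "river_stage")
    return sim, piezo, river


@pytest.fixture(scope="session")
def valley_diagnosis(valley):
    sim, piezo, river = valley
    estimates, summaries = exchange.run_exchange_diagnosis(
        piezo, river, [s for s in sim.segments]
    )
    return sim, estimates, summaries


@pytest.fixture(scope="session")
def community():
    return synthetic.generate_community(synthetic.CommunityConfig(seed=11))


@pytest.fixture(scope="session")
def community_profiles(community):
    return macrophytes.profile_community(community.environment, community.releves)


@pytest.fixture()
def square_surface():
    """Unit square split along the main diagonal into two triangles.

    z chosen so the two triangle planes have slopes 0.002 and 0.004.
    """
    c = 0.0036457513110645905  # solves hypot(0.002 - c, c) = 0.004
    vertices = np.array(
        [[0, 0, 0.0], [1, 0, 0.002], [1, 1, 0.002], [0, 1, c]]
    )
    triangles = np.array([[0, 1, 2], [0, 2, 3]])
    return tin.TriangulatedSurface(vertices, triangles, "piezometric")
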