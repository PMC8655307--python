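import pytest

from tiltstand.controllers import MPCConfig
from tiltstand.kinematics import SegmentModel
from tiltstand.model import FloorProfile, PendulumParams, SimulationConfig


@pytest.fixture(scope="session")
def rat() -> PendulumParams:
    """Identified mean body parameters, noise-free."""
    return PendulumParams.rat(sigma_mnm=0.0)


@pytest.fixture(scope="session")
def rat_noisy() -> PendulumParams:
    return PendulumParams.rat()


@pytest.fixture(scope="session")
def ramp() -> FloorProfile:
    """The experimental 8.8 degree / 0.25 s toes-up ramp at t = 0."""
    return FloorProfile()


@pytest.fixture(scope="session")
def window() -> SimulationConfig:
    """The identification window [-0.35, 0.45] s at 1 kHz."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def mpc_config() -> MPCConfig:
    return MPCConfig()


@pytest.fixture(scope="session")
def segment_model() -> SegmentModel:
    return SegmentModel.default()


@pytest.fixture(scope="session")
def single_link_model() -> SegmentModel:
    """Degenerate one-segment body: the whole mass on the foot-to-nose...
    rather, a single leg-like link from the MTP; the rotation-effect
    statistic is exact for this body."""
    from tiltstand.kinematics import SegmentSpec

    return SegmentModel(
        segments=(
            SegmentSpec(
                name="leg", mass_pct=100.0, ls_pct=60.0, lv_pct=0.0,
                lower_marker="mtp", upper_marker="scapula",
            ),
        )
    )
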