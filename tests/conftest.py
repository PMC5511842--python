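import numpy as np
import pytest

import petacbias as pb


@pytest.fixture(scope="session")
def default_spec() -> pb.PhantomSpec:
    return pb.PhantomSpec()


@pytest.fixture(scope="session")
def head_phantom(default_spec) -> pb.SubjectPhantom:
    return pb.build_head_phantom(default_spec)


@pytest.fixture(scope="session")
def inputs() -> pb.InputFunctionSet:
    return pb.synth_input_functions()


@pytest.fixture(scope="session")
def schedule() -> pb.FrameSchedule:
    return pb.default_frame_schedule()


@pytest.fixture(scope="session")
def small_spec() -> pb.PhantomSpec:
    """Coarse phantom for reconstruction-heavy tests (same anatomy, 4 mm pixels)."""
    return pb.PhantomSpec(grid_size=64, pixel_mm=4.0)


@pytest.fixture(scope="session")
def small_phantom(small_spec) -> pb.SubjectPhantom:
    return pb.build_head_phantom(small_spec)


@pytest.fixture(scope="session")
def gray_truth(default_spec) -> pb.KineticParams:
    return default_spec.kinetics[pb.Tissue.GRAY]


def disk_image(n: int = 64, radius_px: float = 20.0, value: float = 1.0) -> np.ndarray:
    c = n // 2
    y, x = np.mgrid[0:n, 0:n]
    return np.where((x - c) ** 2 + (y - c) ** 2 <= radius_px**2, value, 0.0)
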