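import numpy as np
import pytest

from cisubquant.phantoms import GridSpec, ImageVolume, MaterialModel
from cisubquant.pipeline import StudyConfig, run_phantom_study


@pytest.fixture(scope="session")
def materials() -> MaterialModel:
    return MaterialModel()


@pytest.fixture()
def small_grid() -> GridSpec:
    return GridSpec((4, 64, 64), (1.0, 0.5, 0.5))


def make_disk_volume(grid: GridSpec, radius_mm: float, mu: float,
                     supersample: int = 4) -> ImageVolume:
    """Uniform centred disk with area-weighted (anti-aliased) boundary."""
    s = supersample
    off = (np.arange(s) + 0.5) / s - 0.5
    ys = (grid.axis_coords(1)[:, None] + off[None, :] * grid.spacing[1]).ravel()
    xs = (grid.axis_coords(2)[:, None] + off[None, :] * grid.spacing[2]).ravel()
    X, Y = np.meshgrid(xs, ys)
    cov = ((X ** 2 + Y ** 2) <= radius_mm ** 2).astype(float)
    ny, nx = grid.shape[1], grid.shape[2]
    plane = mu * cov.reshape(ny, s, nx, s).mean(axis=(1, 3))
    vals = np.broadcast_to(plane, grid.shape).copy()
    return ImageVolume(vals, grid, "attenuation")


@pytest.fixture(scope="session")
def mini_config() -> StudyConfig:
    """Miniature but complete study configuration (fast, four scenarios)."""
    return StudyConfig(
        sim_shape=(4, 100, 100), sim_spacing=(1.0, 0.32, 0.32),
        fbp_shape=(4, 64, 64), fbp_spacing=(1.0, 0.5, 0.5),
        sirt_shape=(4, 80, 80), sirt_spacing=(1.0, 0.4, 0.4),
        n_angles=100, detector_bins=80, detector_spacing=0.5,
        sirt_iterations=40, nps_roi_size=16,
        n_replicates=2, n_sessions=1, master_seed=7)


@pytest.fixture(scope="session")
def mini_report(mini_config):
    return run_phantom_study(mini_config)


@pytest.fixture(scope="session")
def desk_report():
    """The desk-scale four-scenario study under the default conditions
    (levels 0/0.5/1/3 mg I/ml, 200 angles, I0 = 1e5, 3 replicates x
    2 sessions, master seed 42).  Session-scoped: several acceptance
    checks read different aspects of the same run."""
    return run_phantom_study(StudyConfig())
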