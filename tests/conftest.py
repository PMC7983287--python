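import numpy as np
import pytest

import laflow4d as lf


@pytest.fixture
def small_grid() -> lf.GridSpec:
    return lf.GridSpec((16, 16, 16), (2.5, 2.5, 2.5), 6, 0.1, 2)


@pytest.fixture
def small_mask(small_grid) -> lf.LAMask:
    return lf.ellipsoid_mask(small_grid, (15.0, 13.0, 13.0))


@pytest.fixture
def rotation_field(small_grid) -> lf.VelocityField4D:
    """Steady rigid rotation, Omega = 1 rad/s about z: |curl| = 2 everywhere."""
    return lf.analytic_field(
        "rigid_rotation", {"omega_rad_s": 1.0}, small_grid, venc_m_s=1.1
    )


@pytest.fixture
def uniform_field(small_grid) -> lf.VelocityField4D:
    return lf.analytic_field("uniform", {"u": (0.2, 0.0, 0.0)}, small_grid, venc_m_s=1.1)


def rescan_only_design(n: int, cv: float, seed: int) -> lf.StudyDesign:
    """Single-group study with only same-day rescan variability active."""
    return lf.StudyDesign(
        n_subjects={"SR": n},
        group_means={"SR": 0.35},
        group_sds={"SR": 0.12},
        within_cv={"intra_obs": 0.0, "inter_obs": 0.0, "rescan": cv, "interval": 0.0},
        hr_effect=0.0,
        seed=seed,
    )


def field_from_array(data: np.ndarray, grid: lf.GridSpec, venc=None) -> lf.VelocityField4D:
    return lf.VelocityField4D(data, grid, venc)
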