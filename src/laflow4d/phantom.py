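"""Analytic 4D velocity phantoms and simulated repeated-measures studies.

This module generates the synthetic inputs the rest of the package is
exercised on: closed-form velocity fields (uniform flow, rigid rotation,
Lamb-Oseen vortex) with known vorticity/stasis/vortex ground truth, the
controlled corruptions a phase-contrast acquisition would introduce
(Gaussian velocity noise, spatially affine eddy-current offsets, VENC
aliasing), and long-format scan1a/scan1b/scan2 measurement tables with
prescribed within-subject coefficients of variation.

Coordinate convention (shared with the gradient and pathline code): voxel
indices are 0-based and world positions are ``index * spacing_mm`` at voxel
centers, in millimetres. Velocities are in m/s throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Spatial and temporal sampling of a time-resolved velocity volume.

    Parameters
    ----------
    shape
        Voxel counts ``(nx, ny, nz)``.
    spacing_mm
        Voxel edge lengths in millimetres, all positive.
    n_frames
        Number of reconstructed cardiac frames (>= 2).
    frame_duration_s
        Duration of one frame; cycle length is ``n_frames * frame_duration_s``.
    mv_open_frame
        Index of the first diastolic frame (mitral-valve opening). Frames
        ``[0, mv_open_frame)`` are systolic, ``[mv_open_frame, n_frames)``
        diastolic; both blocks must be non-empty.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    n_frames: int
    frame_duration_s: float
    mv_open_frame: int

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive in all axes, got {self.spacing_mm}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_duration_s <= 0:
            raise ValueError("frame_duration_s must be positive")
        if not (1 <= self.mv_open_frame < self.n_frames):
            raise ValueError(
                f"mv_open_frame must lie in [1, n_frames) = [1, {self.n_frames}), "
                f"got {self.mv_open_frame}"
            )

    @property
    def cycle_length_s(self) -> float:
        return self.n_frames * self.frame_duration_s

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    def frame_times_s(self) -> np.ndarray:
        """Start time of each frame."""
        return np.arange(self.n_frames) * self.frame_duration_s

    def world_coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable voxel-center world coordinates (mm) along each axis."""
        x = np.arange(self.shape[0]) * self.spacing_mm[0]
        y = np.arange(self.shape[1]) * self.spacing_mm[1]
        z = np.arange(self.shape[2]) * self.spacing_mm[2]
        return (
            x[:, None, None],
            y[None, :, None],
            z[None, None, :],
        )

    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing_mm)


@dataclass
class VelocityField4D:
    """Gridded time-resolved 3-component velocity data.

    ``data`` is indexed ``(x, y, z, t, component)`` in m/s. ``venc_m_s`` is
    the velocity-encoding limit; when ``wrapped`` is set every stored value
    lies in the half-open interval ``(-venc, +venc]``.
    """

    data: np.ndarray
    grid: GridSpec
    venc_m_s: float | None = None
    wrapped: bool = False
    provenance: list = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = (*self.grid.shape, self.grid.n_frames, 3)
        if self.data.shape != expected:
            raise ValueError(f"data shape {self.data.shape} != expected {expected}")
        if self.venc_m_s is not None and self.venc_m_s <= 0:
            raise ValueError("venc_m_s must be positive")

    def copy(self) -> "VelocityField4D":
        return VelocityField4D(
            self.data.copy(), self.grid, self.venc_m_s, self.wrapped, list(self.provenance)
        )


@dataclass
class LAMask:
    """Boolean 3D segmentation of the left atrium on the velocity grid."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.shape:
            raise ValueError(f"mask shape {self.data.shape} != grid shape {self.grid.shape}")
        if not self.data.any():
            raise ValueError("mask must contain at least one voxel")

    @property
    def voxel_volume_ml(self) -> float:
        return self.grid.voxel_volume_ml

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def centroid_mm(self) -> np.ndarray:
        idx = np.argwhere(self.data)
        return idx.mean(axis=0) * np.asarray(self.grid.spacing_mm)


@dataclass(frozen=True)
class PhantomComponent:
    """One analytic primitive of a composite phantom field."""

    kind: str
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in _ANALYTIC_KINDS:
            raise ValueError(
                f"unknown analytic field kind {self.kind!r}; supported kinds: "
                f"{sorted(_ANALYTIC_KINDS)}"
            )


@dataclass
class PhantomConfig:
    """Configuration of a composite analytic phantom.

    ``components`` are summed; ``temporal_profile`` multiplies the whole
    spatial field per frame (separable space-time); ``mask_semiaxes_mm`` are
    the ellipsoid semi-axes of the LA stand-in mask, centered on the grid.
    """

    components: list[PhantomComponent]
    temporal_profile: np.ndarray | None = None
    mask_semiaxes_mm: tuple[float, float, float] = (30.0, 25.0, 25.0)
    venc_m_s: float = 1.1
    confine_to_mask: bool = False
    confine_taper_q: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("at least one phantom component is required")


@dataclass
class CorruptionConfig:
    """Controlled corruption of a clean velocity field.

    ``eddy_coeffs`` holds, per velocity component, the affine offset
    coefficients ``(a, b, c, d)`` of ``a + b*x + c*y + d*z`` with ``a`` in
    m/s and ``b, c, d`` in m/s per mm of world position.
    """

    noise_sd_m_s: float = 0.0
    eddy_coeffs: np.ndarray | None = None  # (3, 4)
    wrap_at_venc: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.noise_sd_m_s) or self.noise_sd_m_s < 0:
            raise ValueError("noise_sd_m_s must be finite and >= 0")
        if self.eddy_coeffs is not None:
            self.eddy_coeffs = np.asarray(self.eddy_coeffs, dtype=float)
            if self.eddy_coeffs.shape != (3, 4):
                raise ValueError("eddy_coeffs must have shape (3, 4)")

    @property
    def is_identity(self) -> bool:
        return (
            self.noise_sd_m_s == 0
            and (self.eddy_coeffs is None or not np.any(self.eddy_coeffs))
            and not self.wrap_at_venc
        )


@dataclass
class StudyDesign:
    """Design of a simulated scan1a/scan1b/scan2 reproducibility study.

    ``within_cv`` maps each variability source to its true proportional
    within-subject CV. ``hr_effect`` is the fractional biomarker change per
    bpm of heart-rate change at the interval scan (negative: a slower heart
    rate raises the biomarker, as reported for stasis).
    """

    n_subjects: dict = dc_field(default_factory=lambda: {"SR": 64, "AF": 22})
    biomarker: str = "stasis"
    group_means: dict = dc_field(default_factory=lambda: {"SR": 0.35, "AF": 0.55})
    group_sds: dict = dc_field(default_factory=lambda: {"SR": 0.12, "AF": 0.15})
    within_cv: dict = dc_field(
        default_factory=lambda: {
            "intra_obs": 0.03,
            "inter_obs": 0.07,
            "rescan": 0.10,
            "interval": 0.14,
        }
    )
    hr_effect: float = -0.004
    hr_mean_bpm: float = 70.0
    hr_sd_bpm: float = 10.0
    hr_change_sd_bpm: float = 8.0
    sbp_mean_mmHg: float = 130.0
    sbp_sd_mmHg: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        for src, cv in self.within_cv.items():
            if cv < 0:
                raise ValueError(f"within_cv[{src!r}] must be >= 0")
        for g, n in self.n_subjects.items():
            if n < 2:
                raise ValueError(f"n_subjects[{g!r}] must be >= 2")


# --------------------------------------------------------------------------
# Analytic fields
# --------------------------------------------------------------------------


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("axis vector must be non-zero")
    return v / n


def _relative_coords_m(grid: GridSpec, center_mm) -> tuple[np.ndarray, ...]:
    """Voxel-center coordinates relative to ``center_mm``, in metres."""
    x, y, z = grid.world_coords_mm()
    c = np.asarray(center_mm, dtype=float)
    return (x - c[0]) / 1000.0, (y - c[1]) / 1000.0, (z - c[2]) / 1000.0


def _uniform_frame(grid: GridSpec, params: dict) -> np.ndarray:
    u = np.asarray(params["u"], dtype=float)
    if u.shape != (3,):
        raise ValueError("uniform flow needs a 3-vector 'u' in m/s")
    out = np.empty((*grid.shape, 3))
    out[...] = u
    return out


def _rigid_rotation_frame(grid: GridSpec, params: dict) -> np.ndarray:
    """Solid-body rotation v = Omega x r; |curl v| = 2*Omega everywhere."""
    omega = float(params["omega_rad_s"])
    axis = _unit(params.get("axis", (0.0, 0.0, 1.0)))
    center = params.get("center_mm", grid.center_mm())
    rx, ry, rz = _relative_coords_m(grid, center)
    shp = np.broadcast_shapes(rx.shape, ry.shape, rz.shape)
    r = np.empty((*shp, 3))
    r[..., 0], r[..., 1], r[..., 2] = np.broadcast_arrays(rx, ry, rz)
    out = omega * np.cross(np.broadcast_to(axis, r.shape), r)
    return np.broadcast_to(out, (*grid.shape, 3)).copy()


def _lamb_oseen_frame(grid: GridSpec, params: dict) -> np.ndarray:
    """Lamb-Oseen vortex: v_theta(r) = Gamma/(2 pi r) * (1 - exp(-r^2/rc^2)).

    Peak vorticity magnitude at the core center is ``Gamma / (pi rc^2)``.
    """
    gamma = float(params["circulation_m2_s"])
    rc = float(params["core_radius_m"])
    if rc <= 0:
        raise ValueError("core_radius_m must be positive")
    axis = _unit(params.get("axis", (0.0, 0.0, 1.0)))
    center = params.get("center_mm", grid.center_mm())
    rx, ry, rz = _relative_coords_m(grid, center)
    shp = np.broadcast_shapes(rx.shape, ry.shape, rz.shape)
    pos = np.empty((*shp, 3))
    pos[..., 0], pos[..., 1], pos[..., 2] = np.broadcast_arrays(rx, ry, rz)
    # in-plane radius vector (remove axial component)
    axial = pos @ axis
    perp = pos - axial[..., None] * axis
    r = np.linalg.norm(perp, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vtheta = gamma / (2.0 * np.pi * r) * (1.0 - np.exp(-(r**2) / rc**2))
    vtheta = np.where(r > 0, vtheta, 0.0)
    # tangential direction = axis x r_hat
    tang = np.cross(np.broadcast_to(axis, perp.shape), perp)
    tnorm = np.linalg.norm(tang, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tang = np.where(tnorm[..., None] > 0, tang / tnorm[..., None], 0.0)
    out = vtheta[..., None] * tang
    return np.broadcast_to(out, (*grid.shape, 3)).copy()


def lamb_oseen_tangential_speed(r_m, circulation_m2_s: float, core_radius_m: float):
    """Closed-form tangential speed of a Lamb-Oseen vortex (oracle helper)."""
    r = np.asarray(r_m, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = circulation_m2_s / (2 * np.pi * r) * (1 - np.exp(-(r**2) / core_radius_m**2))
    return np.where(r > 0, v, 0.0)


_ANALYTIC_KINDS: dict[str, Callable[[GridSpec, dict], np.ndarray]] = {
    "uniform": _uniform_frame,
    "rigid_rotation": _rigid_rotation_frame,
    "lamb_oseen": _lamb_oseen_frame,
}


def analytic_field(
    kind: str,
    params: dict,
    grid: GridSpec,
    venc_m_s: float | None = None,
    temporal_profile=None,
) -> VelocityField4D:
    """Sample a closed-form velocity primitive on ``grid``.

    The spatial field is evaluated at voxel centers and replicated over
    frames; ``temporal_profile`` (length ``n_frames``, non-negative) scales
    each frame. Supported kinds: ``uniform`` (zero curl), ``rigid_rotation``
    (curl magnitude ``2*omega`` everywhere), ``lamb_oseen``.
    """
    if kind not in _ANALYTIC_KINDS:
        raise ValueError(
            f"unknown analytic field kind {kind!r}; supported kinds: {sorted(_ANALYTIC_KINDS)}"
        )
    frame = _ANALYTIC_KINDS[kind](grid, params)
    profile = _check_profile(temporal_profile, grid)
    data = frame[:, :, :, None, :] * profile[None, None, None, :, None]
    return VelocityField4D(data, grid, venc_m_s, provenance=[{"stage": "analytic_field", "kind": kind}])


def _check_profile(temporal_profile, grid: GridSpec) -> np.ndarray:
    if temporal_profile is None:
        return np.ones(grid.n_frames)
    profile = np.asarray(temporal_profile, dtype=float)
    if profile.shape != (grid.n_frames,):
        raise ValueError(f"temporal_profile must have length {grid.n_frames}")
    if not np.all(np.isfinite(profile)):
        raise ValueError("temporal_profile must be finite")
    return profile


# --------------------------------------------------------------------------
# Corruption
# --------------------------------------------------------------------------


def eddy_offset_volume(grid: GridSpec, eddy_coeffs: np.ndarray) -> np.ndarray:
    """Evaluate the affine eddy offset a + b*x + c*y + d*z on the grid, (nx,ny,nz,3)."""
    coeffs = np.asarray(eddy_coeffs, dtype=float)
    x, y, z = grid.world_coords_mm()
    out = np.empty((*grid.shape, 3))
    for comp in range(3):
        a, b, c, d = coeffs[comp]
        out[..., comp] = a + b * x + c * y + d * z
    return out


def wrap_to_venc(values: np.ndarray, venc: float) -> np.ndarray:
    """Alias values into (-venc, +venc] (the phase-wrap of velocity encoding)."""
    # map v to ((v + venc) mod 2 venc) - venc, with the boundary assigned to +venc
    wrapped = np.mod(values + venc, 2.0 * venc) - venc
    return np.where(wrapped == -venc, venc, wrapped)


def corrupt_field(
    field: VelocityField4D, cfg: CorruptionConfig, seed: int | None = None
) -> VelocityField4D:
    """Apply noise, eddy offset and VENC wrapping to a clean field.

    Order matches the physical corruption chain: i.i.d. Gaussian noise per
    component, then the time-invariant affine eddy offset, then (optionally)
    modular wrapping at the encoding limit.
    """
    if not np.all(np.isfinite(field.data)):
        raise ValueError("input field must be finite")
    out = field.copy()
    applied: dict = {"stage": "corrupt_field"}
    if cfg.noise_sd_m_s > 0:
        rng = np.random.default_rng(seed)
        out.data = out.data + rng.normal(0.0, cfg.noise_sd_m_s, size=out.data.shape)
        applied["noise_sd_m_s"] = cfg.noise_sd_m_s
        applied["seed"] = seed
    if cfg.eddy_coeffs is not None and np.any(cfg.eddy_coeffs):
        offset = eddy_offset_volume(field.grid, cfg.eddy_coeffs)
        out.data = out.data + offset[:, :, :, None, :]
        applied["eddy_coeffs"] = np.asarray(cfg.eddy_coeffs).tolist()
    if cfg.wrap_at_venc:
        if field.venc_m_s is None:
            raise ValueError("wrap_at_venc requires venc_m_s on the field")
        out.data = wrap_to_venc(out.data, field.venc_m_s)
        out.wrapped = True
        applied["wrap_at_venc"] = True
    out.provenance.append(applied)
    return out


# --------------------------------------------------------------------------
# Phantom assembly
# --------------------------------------------------------------------------


def ellipsoid_mask(grid: GridSpec, semiaxes_mm, center_mm=None) -> LAMask:
    """Ellipsoid stand-in for the segmented LA, centered on the grid by default."""
    semi = np.asarray(semiaxes_mm, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("semi-axes must be positive")
    extent = (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing_mm)
    if np.any(2 * semi > extent):
        raise ValueError(
            f"ellipsoid semi-axes {tuple(semi)} mm do not fit in grid extent {tuple(extent)} mm"
        )
    center = grid.center_mm() if center_mm is None else np.asarray(center_mm, dtype=float)
    x, y, z = grid.world_coords_mm()
    q = (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    )
    return LAMask(q <= 1.0, grid)


def make_phantom(
    cfg: PhantomConfig,
    grid: GridSpec,
    corruption: CorruptionConfig | None = None,
):
    """Build a composite phantom: corrupted field, LA mask and ground truth.

    Returns ``(field, mask, ground_truth)`` where ``ground_truth`` is the
    BiomarkerSet computed on the *uncorrupted* field (pattern classification
    skipped; it is a pathline-level call).
    """
    from .biomarkers import extract_biomarkers  # late import: avoids cycle

    profile = _check_profile(cfg.temporal_profile, grid)
    frame_sum = np.zeros((*grid.shape, 3))
    for comp in cfg.components:
        frame_sum += _ANALYTIC_KINDS[comp.kind](grid, comp.params)
    mask = ellipsoid_mask(grid, cfg.mask_semiaxes_mm)
    if cfg.confine_taper_q is not None:
        # smooth (cosine) taper to zero at the wall, mimicking no-slip decay:
        # full amplitude inside q0, zero at/beyond q1, in ellipsoid coordinate
        # q = sqrt(sum((r_i/a_i)^2)). Leaves a genuinely static background for
        # eddy fitting without a velocity discontinuity at the mask boundary.
        q0, q1 = cfg.confine_taper_q
        if not (0 < q0 < q1):
            raise ValueError("confine_taper_q must satisfy 0 < q0 < q1")
        q = ellipsoid_q(grid, cfg.mask_semiaxes_mm)
        w = np.clip((q1 - q) / (q1 - q0), 0.0, 1.0)
        window = 0.5 * (1.0 - np.cos(np.pi * w))
        frame_sum = frame_sum * window[..., None]
    elif cfg.confine_to_mask:
        # hard clip: static background at the price of a sharp mask boundary
        frame_sum = frame_sum * mask.data[..., None]
    data = frame_sum[:, :, :, None, :] * profile[None, None, None, :, None]
    clean = VelocityField4D(
        data, grid, cfg.venc_m_s, provenance=[{"stage": "make_phantom", "components": [c.kind for c in cfg.components]}]
    )
    truth = extract_biomarkers(clean, mask, classify_patterns=False)
    if corruption is None or corruption.is_identity:
        return clean, mask, truth
    corrupted = corrupt_field(clean, corruption, seed=cfg.seed)
    return corrupted, mask, truth


def ellipsoid_q(grid: GridSpec, semiaxes_mm, center_mm=None) -> np.ndarray:
    """Ellipsoid coordinate q = sqrt(sum((r_i/a_i)^2)) per voxel (q<=1 inside)."""
    semi = np.asarray(semiaxes_mm, dtype=float)
    center = grid.center_mm() if center_mm is None else np.asarray(center_mm, dtype=float)
    x, y, z = grid.world_coords_mm()
    return np.sqrt(
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    )


def static_background_mask(grid: GridSpec, cfg: PhantomConfig) -> np.ndarray:
    """Voxels where the confined phantom velocity is identically zero.

    Only meaningful for confined phantoms (hard clip or taper); used as the
    static-tissue mask of the eddy-current fit.
    """
    if cfg.confine_taper_q is not None:
        return ellipsoid_q(grid, cfg.mask_semiaxes_mm) >= cfg.confine_taper_q[1]
    if cfg.confine_to_mask:
        return ellipsoid_q(grid, cfg.mask_semiaxes_mm) > 1.0
    raise ValueError("phantom is not confined; it has no static background")


def systolic_diastolic_profile(n_frames: int) -> np.ndarray:
    """Smooth non-negative cycle profile ranging 0.4-1.3 (peak mid-cycle)."""
    k = np.arange(n_frames)
    return 0.4 + 0.9 * np.sin(np.pi * (k + 0.5) / n_frames) ** 2


def default_phantom_config(grid: GridSpec, seed: int = 0) -> PhantomConfig:
    """The default test-bed phantom: a confined Lamb-Oseen vortex.

    Circulation 0.066 m^2/s with a 10 mm core gives peak speeds ~0.7 m/s
    (physiological for trans-atrial flow) and concentrates vorticity well
    inside the analysis mask; the velocity tapers smoothly to zero outside
    the mask (no-slip-like), leaving a static background for eddy-current
    fitting. VENC 0.6 m/s makes the fastest frames alias. The mask ellipsoid
    scales with the grid (semi-axes ~0.39/0.32 of the extent).
    """
    extent = (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing_mm)
    semi = extent * np.array([0.39, 0.32, 0.32])
    return PhantomConfig(
        components=[
            PhantomComponent(
                "lamb_oseen", {"circulation_m2_s": 0.066, "core_radius_m": 0.010}
            )
        ],
        temporal_profile=systolic_diastolic_profile(grid.n_frames),
        mask_semiaxes_mm=tuple(semi),
        venc_m_s=0.6,
        confine_taper_q=(1.05, 1.45),
        seed=seed,
    )


#: default corruption: realistic velocity noise, a per-component affine
#: eddy offset of a few cm/s with mm-scale gradients, and VENC aliasing
DEFAULT_EDDY_COEFFS = np.array(
    [
        [0.08, 0.002, 0.0, 0.0],
        [0.05, 0.0, -0.001, 0.0005],
        [-0.06, 0.0005, 0.0, 0.001],
    ]
)


def default_corruption_config(noise_sd_m_s: float = 0.05) -> CorruptionConfig:
    return CorruptionConfig(
        noise_sd_m_s=noise_sd_m_s,
        eddy_coeffs=DEFAULT_EDDY_COEFFS.copy(),
        wrap_at_venc=True,
    )


# --------------------------------------------------------------------------
# Repeated-measures study simulation
# --------------------------------------------------------------------------

SESSIONS = ("scan1a", "scan1b", "scan2")


def simulate_study(design: StudyDesign) -> pd.DataFrame:
    """Simulate a long-format scan1a/scan1b/scan2 measurement table.

    Each subject carries a true biomarker value drawn from its group
    distribution. Session values are ``true * (1 + eta)`` with ``eta`` drawn
    at the session-level CV (rescan for scan1a/scan1b, interval for scan2);
    the interval value is additionally scaled by ``1 + hr_effect * dHR``.
    Observer readings of scan1a multiply in reading-level error (intra for
    the two same-observer reads, inter for the second observer). Columns:
    subject_id, group, session, observer, biomarker, value, hr_bpm,
    sbp_mmHg.
    """
    rng = np.random.default_rng(design.seed)
    cv = design.within_cv
    rows = []
    n_resampled = 0

    def positive_normal(mean, sd, size=None):
        nonlocal n_resampled
        v = rng.normal(mean, sd, size)
        tries = 0
        while np.any(v <= 0):
            bad = v <= 0
            n_resampled += int(np.count_nonzero(bad))
            v = np.where(bad, rng.normal(mean, sd, size), v)
            tries += 1
            if tries > 1000:
                raise ValueError("cannot draw positive values; SD too large for mean")
        return v

    def noisy(base, source):
        c = cv.get(source, 0.0)
        if c == 0:
            return base
        val = base * (1.0 + rng.normal(0.0, c))
        tries = 0
        while val <= 0:
            n_resampled += 1
            val = base * (1.0 + rng.normal(0.0, c))
            tries += 1
            if tries > 1000:
                raise ValueError(f"within_cv[{source!r}] too large: values non-positive")
        return val

    for group in design.n_subjects:
        n = design.n_subjects[group]
        mu = design.group_means[group]
        sd = design.group_sds[group]
        for i in range(n):
            sid = f"{group}{i:03d}"
            true = float(positive_normal(mu, sd))
            hr1 = rng.normal(design.hr_mean_bpm, design.hr_sd_bpm)
            hr2 = hr1 + rng.normal(0.0, design.hr_change_sd_bpm)
            sbp1 = rng.normal(design.sbp_mean_mmHg, design.sbp_sd_mmHg)
            sbp2 = sbp1 + rng.normal(0.0, 8.0)

            s1a = noisy(true, "rescan")
            s1b = noisy(true, "rescan")
            s2_base = true * (1.0 + design.hr_effect * (hr2 - hr1))
            s2_base = max(s2_base, 1e-12)
            s2 = noisy(s2_base, "interval")

            # scan1a read twice by observer 1 (intra) and once by observer 2 (inter)
            readings = [
                ("scan1a", "O1", noisy(s1a, "intra_obs"), hr1, sbp1),
                ("scan1a", "O1r", noisy(s1a, "intra_obs"), hr1, sbp1),
                ("scan1a", "O2", noisy(s1a, "inter_obs"), hr1, sbp1),
                ("scan1b", "O1", noisy(s1b, "intra_obs"), hr1, sbp1),
                ("scan2", "O1", noisy(s2, "intra_obs"), hr2, sbp2),
            ]
            for session, observer, value, hr, sbp in readings:
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "session": session,
                        "observer": observer,
                        "biomarker": design.biomarker,
                        "value": value,
                        "hr_bpm": hr,
                        "sbp_mmHg": sbp,
                    }
                )
    if n_resampled:
        warnings.warn(
            f"simulate_study redrew {n_resampled} non-positive values; "
            "within-subject CVs may be slightly truncated",
            stacklevel=2,
        )
    df = pd.DataFrame(rows)
    df.attrs["n_resampled"] = n_resampled
    return df


def extract_pairs(table: pd.DataFrame, contrast: str, biomarker: str | None = None) -> np.ndarray:
    """Extract paired measurements (n, 2) for a named reproducibility contrast.

    Contrasts: ``intra_obs`` (scan1a O1 vs O1r), ``inter_obs`` (scan1a O1 vs
    O2), ``rescan`` (scan1a vs scan1b, O1), ``interval`` (scan1a vs scan2,
    O1). Rows are ordered by subject_id for determinism.
    """
    t = table
    if biomarker is not None:
        t = t[t["biomarker"] == biomarker]
    selectors = {
        "intra_obs": (("scan1a", "O1"), ("scan1a", "O1r")),
        "inter_obs": (("scan1a", "O1"), ("scan1a", "O2")),
        "rescan": (("scan1a", "O1"), ("scan1b", "O1")),
        "interval": (("scan1a", "O1"), ("scan2", "O1")),
    }
    if contrast not in selectors:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {sorted(selectors)}")
    (s1, o1), (s2, o2) = selectors[contrast]
    a = t[(t.session == s1) & (t.observer == o1)].set_index("subject_id")["value"]
    b = t[(t.session == s2) & (t.observer == o2)].set_index("subject_id")["value"]
    common = sorted(set(a.index) & set(b.index))
    if not common:
        raise ValueError(f"no paired subjects for contrast {contrast!r}")
    return np.column_stack([a.loc[common].to_numpy(), b.loc[common].to_numpy()])
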