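"""Global left-atrial flow biomarkers from a preprocessed velocity field.

Five scalar biomarkers are computed over the segmented LA:

* **peak / mean velocity** (m/s) — per-voxel temporal peak and mean of speed,
  then reduced over the mask (spatial mean by default; global max available);
* **stasis** — per-voxel fraction of cardiac frames with speed strictly below
  a threshold (default 0.1 m/s); global stasis is the mask average, a
  proportion from 0 (no stasis) to 1;
* **vorticity** — volume-averaged vorticity magnitude per frame (rad/s) and
  its area under the curve over one cycle (rad);
* **lambda2 vortex volume** (ml) — voxels whose middle eigenvalue of
  S^2 + Omega^2 falls below half the cycle-mean negative lambda2; the largest
  26-connected component per frame, reported as cycle mean and
  systolic/diastolic peaks.

Spatial derivatives use central differences (one-sided at grid edges) with
spacing converted mm -> m, so vorticity and lambda2 carry s^-1 / s^-2 units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import LAMask, VelocityField4D

#: default speed threshold below which a voxel-frame counts as stasis, m/s
STASIS_THRESHOLD_M_S = 0.1


@dataclass
class StasisResult:
    per_voxel: np.ndarray  # proportion 0-1 over mask-shaped volume (NaN outside)
    n_stasis: np.ndarray  # frames below threshold, int, mask-shaped
    n_tot: int
    global_stasis: float
    threshold_m_s: float


@dataclass
class VorticityCurve:
    values_rad_s: np.ndarray  # per-frame volume-averaged |curl v|
    frame_duration_s: float

    @property
    def auc_rad(self) -> float:
        return float(self.values_rad_s.sum() * self.frame_duration_s)


@dataclass
class Lambda2Field:
    values: np.ndarray  # (nx, ny, nz, t), s^-2
    threshold: float  # s^-2, <= 0; vortex voxels are strictly below this


@dataclass
class VortexVolumes:
    per_frame_ml: np.ndarray
    mv_open_frame: int

    @property
    def mean_ml(self) -> float:
        return float(self.per_frame_ml.mean())

    @property
    def systolic_peak_ml(self) -> float:
        return float(self.per_frame_ml[: self.mv_open_frame].max())

    @property
    def diastolic_peak_ml(self) -> float:
        return float(self.per_frame_ml[self.mv_open_frame :].max())


@dataclass
class BiomarkerSet:
    """One session's global LA flow metrics."""

    peak_velocity_m_s: float
    mean_velocity_m_s: float
    global_stasis: float
    vorticity_auc_rad: float
    vortex_mean_ml: float
    vortex_systolic_peak_ml: float
    vortex_diastolic_peak_ml: float
    pattern_systole: str | None = None
    pattern_diastole: str | None = None

    def as_dict(self) -> dict:
        return {
            "peak_velocity_m_s": self.peak_velocity_m_s,
            "mean_velocity_m_s": self.mean_velocity_m_s,
            "global_stasis": self.global_stasis,
            "vorticity_auc_rad": self.vorticity_auc_rad,
            "vortex_mean_ml": self.vortex_mean_ml,
            "vortex_systolic_peak_ml": self.vortex_systolic_peak_ml,
            "vortex_diastolic_peak_ml": self.vortex_diastolic_peak_ml,
            "pattern_systole": self.pattern_systole,
            "pattern_diastole": self.pattern_diastole,
        }


# --------------------------------------------------------------------------
# Velocity magnitude metrics
# --------------------------------------------------------------------------


def speed_map(field: VelocityField4D) -> np.ndarray:
    """Euclidean speed per voxel and frame, (nx, ny, nz, t), m/s."""
    return np.linalg.norm(field.data, axis=-1)


def global_velocity_stats(
    field: VelocityField4D, mask: LAMask, peak_reduction: str = "mean"
) -> tuple[float, float]:
    """Global peak and mean velocity over the LA.

    Per-voxel temporal peak and mean speeds are computed first. The global
    mean velocity is the mask average of per-voxel means. The global peak
    velocity reduction is configurable: ``"mean"`` (default) averages the
    per-voxel temporal peaks over the mask, robust to single-voxel noise;
    ``"max"`` takes the overall maximum over mask voxels and frames.
    """
    if peak_reduction not in ("mean", "max"):
        raise ValueError("peak_reduction must be 'mean' or 'max'")
    speed = speed_map(field)[mask.data]  # (n_mask, t)
    voxel_peaks = speed.max(axis=1)
    voxel_means = speed.mean(axis=1)
    peak = voxel_peaks.max() if peak_reduction == "max" else voxel_peaks.mean()
    return float(peak), float(voxel_means.mean())


def compute_stasis(
    field: VelocityField4D, mask: LAMask, threshold_m_s: float = STASIS_THRESHOLD_M_S
) -> StasisResult:
    """Per-voxel and global stasis: fraction of frames with speed < threshold.

    The comparison is strictly below the threshold, making the integer frame
    counts bit-exact for constructed inputs.
    """
    if threshold_m_s <= 0:
        raise ValueError("stasis threshold must be positive")
    speed = speed_map(field)
    n_tot = field.grid.n_frames
    below = speed < threshold_m_s
    n_stasis_vol = below.sum(axis=-1)
    per_voxel = np.full(field.grid.shape, np.nan)
    per_voxel[mask.data] = n_stasis_vol[mask.data] / n_tot
    global_stasis = float(per_voxel[mask.data].mean())
    return StasisResult(per_voxel, n_stasis_vol, n_tot, global_stasis, threshold_m_s)


# --------------------------------------------------------------------------
# Derivative-based metrics
# --------------------------------------------------------------------------


def velocity_gradient(field: VelocityField4D) -> np.ndarray:
    """Velocity-gradient tensor J[..., i, j] = dv_i/dx_j, (nx,ny,nz,t,3,3), 1/s.

    Central differences on the full grid, one-sided at the edges; spacing in
    metres.
    """
    if any(s < 3 for s in field.grid.shape):
        raise ValueError("gradient computation requires >= 3 voxels per axis")
    spacing_m = np.asarray(field.grid.spacing_mm) / 1000.0
    J = np.empty((*field.data.shape[:4], 3, 3))
    for i in range(3):
        for j in range(3):
            J[..., i, j] = np.gradient(field.data[..., i], spacing_m[j], axis=j)
    return J


def vorticity_magnitude(field: VelocityField4D) -> np.ndarray:
    """|curl v| per voxel and frame, rad/s."""
    J = velocity_gradient(field)
    wx = J[..., 2, 1] - J[..., 1, 2]
    wy = J[..., 0, 2] - J[..., 2, 0]
    wz = J[..., 1, 0] - J[..., 0, 1]
    return np.sqrt(wx**2 + wy**2 + wz**2)


def vorticity_curve(field: VelocityField4D, mask: LAMask) -> VorticityCurve:
    """Volume-averaged vorticity magnitude per frame; AUC via rectangle rule."""
    w = vorticity_magnitude(field)
    values = w[mask.data].mean(axis=0)
    return VorticityCurve(values, field.grid.frame_duration_s)


def lambda2_field(field: VelocityField4D, mask: LAMask) -> Lambda2Field:
    """Lambda2 vortex criterion per voxel and frame.

    lambda2 is the middle eigenvalue of S^2 + Omega^2 with S and Omega the
    symmetric and antisymmetric parts of the velocity-gradient tensor;
    negative values mark vortical regions. The vortex threshold is half the
    mean of the *negative* lambda2 values over mask voxels and all frames
    (a vortex voxel must be more negative than the threshold); restricting
    the mean to vortex candidates keeps non-rotational voxels from diluting
    the threshold toward zero.
    """
    J = velocity_gradient(field)
    S = 0.5 * (J + np.swapaxes(J, -1, -2))
    O = 0.5 * (J - np.swapaxes(J, -1, -2))
    M = S @ S + O @ O  # symmetric
    eig = np.linalg.eigvalsh(M)  # ascending
    l2 = eig[..., 1]
    in_mask = l2[mask.data]  # (n_mask, t)
    neg = in_mask[in_mask < 0]
    threshold = 0.5 * float(neg.mean()) if neg.size else 0.0
    return Lambda2Field(l2, threshold)


def vortex_volumes(l2: Lambda2Field, mask: LAMask) -> VortexVolumes:
    """Largest connected vortex component per frame, in ml (26-connectivity)."""
    structure = np.ones((3, 3, 3), dtype=bool)
    n_frames = l2.values.shape[3]
    volumes = np.zeros(n_frames)
    for t in range(n_frames):
        vortex = mask.data & (l2.values[..., t] < l2.threshold)
        if l2.threshold >= 0 or not vortex.any():
            continue
        labels, n = ndimage.label(vortex, structure=structure)
        if n == 0:
            continue
        counts = np.bincount(labels.ravel())[1:]
        volumes[t] = counts.max() * mask.voxel_volume_ml
    return VortexVolumes(volumes, mask.grid.mv_open_frame)


# --------------------------------------------------------------------------
# Composite
# --------------------------------------------------------------------------


def extract_biomarkers(
    field: VelocityField4D,
    mask: LAMask,
    stasis_threshold_m_s: float = STASIS_THRESHOLD_M_S,
    peak_reduction: str = "mean",
    classify_patterns: bool = False,
    pathline_kwargs: dict | None = None,
) -> BiomarkerSet:
    """Compute the full BiomarkerSet; optionally attach flow-pattern labels.

    Pattern classification integrates pathlines from default seed planes and
    applies the winding/reach rule; it is off by default since it is a
    pathline-level computation with its own parameters.
    """
    peak, mean = global_velocity_stats(field, mask, peak_reduction)
    stasis = compute_stasis(field, mask, stasis_threshold_m_s)
    vort = vorticity_curve(field, mask)
    l2 = lambda2_field(field, mask)
    vol = vortex_volumes(l2, mask)
    pattern_sys = pattern_dia = None
    if classify_patterns:
        from .pathlines import classify_phases_default

        pattern_sys, pattern_dia = classify_phases_default(
            field, mask, **(pathline_kwargs or {})
        )
    return BiomarkerSet(
        peak_velocity_m_s=peak,
        mean_velocity_m_s=mean,
        global_stasis=stasis.global_stasis,
        vorticity_auc_rad=vort.auc_rad,
        vortex_mean_ml=vol.mean_ml,
        vortex_systolic_peak_ml=vol.systolic_peak_ml,
        vortex_diastolic_peak_ml=vol.diastolic_peak_ml,
        pattern_systole=pattern_sys,
        pattern_diastole=pattern_dia,
    )
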