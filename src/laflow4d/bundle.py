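"""NIfTI + YAML dataset bundles.

A dataset directory holds the three velocity components as 4D NIfTI-1
volumes (``vx.nii``, ``vy.nii``, ``vz.nii``, indexed x,y,z,t in m/s), the LA
segmentation ``mask.nii``, and a ``meta.yaml`` sidecar with the acquisition
metadata the arrays cannot carry (frame duration, mitral-valve-opening
frame, VENC, provenance). Uncompressed .nii keeps the bundle text-tool
friendly and diffable in size.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import GridSpec, LAMask, VelocityField4D

COMPONENT_FILES = ("vx.nii", "vy.nii", "vz.nii")
MASK_FILE = "mask.nii"
META_FILE = "meta.yaml"
REQUIRED_META = ("spacing_mm", "frame_duration_s", "mv_open_frame")


def write_bundle(path, field: VelocityField4D, mask: LAMask) -> Path:
    """Write a velocity field and mask as a NIfTI+YAML bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*field.grid.spacing_mm, 1.0])
    for c, name in enumerate(COMPONENT_FILES):
        img = nib.Nifti1Image(field.data[..., c], affine)
        img.header.set_zooms((*field.grid.spacing_mm, field.grid.frame_duration_s))
        nib.save(img, path / name)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), path / MASK_FILE)
    meta = {
        "spacing_mm": [float(s) for s in field.grid.spacing_mm],
        "frame_duration_s": float(field.grid.frame_duration_s),
        "mv_open_frame": int(field.grid.mv_open_frame),
        "venc_m_s": None if field.venc_m_s is None else float(field.venc_m_s),
        "wrapped": bool(field.wrapped),
        "provenance": field.provenance,
    }
    (path / META_FILE).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_bundle(path) -> tuple[VelocityField4D, LAMask]:
    """Read a NIfTI+YAML bundle, validating shapes and metadata completeness."""
    path = Path(path)
    meta_path = path / META_FILE
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata file: {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    for key in REQUIRED_META:
        if key not in meta or meta[key] is None:
            raise ValueError(f"sidecar {meta_path} is missing required field {key!r}")
    comps = []
    for name in COMPONENT_FILES:
        f = path / name
        if not f.exists():
            raise FileNotFoundError(f"missing velocity component file: {f}")
        comps.append(np.asanyarray(nib.load(f).dataobj, dtype=np.float64))
    mask_path = path / MASK_FILE
    if not mask_path.exists():
        raise FileNotFoundError(f"missing mask file: {mask_path}")
    mask_data = np.asanyarray(nib.load(mask_path).dataobj) > 0
    shapes = {name: c.shape for name, c in zip(COMPONENT_FILES, comps)}
    if len({c.shape for c in comps}) != 1:
        raise ValueError(f"velocity component shapes disagree: {shapes}")
    if comps[0].ndim != 4:
        raise ValueError(f"velocity volumes must be 4D (x,y,z,t), got shape {comps[0].shape}")
    if mask_data.shape != comps[0].shape[:3]:
        raise ValueError(
            f"mask shape {mask_data.shape} does not match velocity grid {comps[0].shape[:3]}"
        )
    wrapped = bool(meta.get("wrapped", False))
    venc = meta.get("venc_m_s")
    if wrapped and venc is None:
        raise ValueError("bundle is flagged wrapped but sidecar has no venc_m_s")
    grid = GridSpec(
        shape=comps[0].shape[:3],
        spacing_mm=tuple(meta["spacing_mm"]),
        n_frames=comps[0].shape[3],
        frame_duration_s=float(meta["frame_duration_s"]),
        mv_open_frame=int(meta["mv_open_frame"]),
    )
    data = np.stack(comps, axis=-1)
    field = VelocityField4D(
        data, grid, venc, wrapped, provenance=list(meta.get("provenance", []))
    )
    return field, LAMask(mask_data, grid)
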