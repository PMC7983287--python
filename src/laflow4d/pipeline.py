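"""Run configuration and end-to-end pipeline orchestration.

``RunConfig`` collects every tunable of the pipeline with declared defaults
and YAML round-trip serialization. ``run_pipeline`` composes the stages —
phantom simulation, corruption, preprocessing, biomarker extraction,
pathline classification, and study-level reproducibility statistics — per
stage toggles, logging parameters into the report so any stage can be rerun
exactly. Inputs on disk are never modified; all outputs go to the configured
output directory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .biomarkers import STASIS_THRESHOLD_M_S, extract_biomarkers
from .bundle import write_bundle
from .phantom import (
    CorruptionConfig,
    DEFAULT_EDDY_COEFFS,
    GridSpec,
    StudyDesign,
    default_phantom_config,
    extract_pairs,
    make_phantom,
    simulate_study,
    static_background_mask,
)
from .preprocess import preprocess
from .reprostats import bland_altman, compare_cv_dependent, within_subject_cv


@dataclass
class RunConfig:
    """All pipeline tunables, with defaults; round-trips through YAML."""

    out_dir: str = "laflow4d_out"
    seed: int = 0
    # phantom / grid
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    n_frames: int = 10
    frame_duration_s: float = 0.1
    mv_open_frame: int = 4
    # corruption
    noise_sd_m_s: float = 0.0
    wrap_at_venc: bool = False
    eddy_offsets: bool = False
    # preprocessing
    eddy_order: int = 1
    unwrap_max_passes: int = 3
    denoise: bool = True
    # biomarkers
    stasis_threshold_m_s: float = STASIS_THRESHOLD_M_S
    peak_reduction: str = "mean"
    classify_patterns: bool = False
    # reproducibility statistics
    n_boot_ci: int = 1000
    n_boot_dependent: int = 10000
    # stage toggles
    run_phantom: bool = True
    run_preprocess: bool = True
    run_biomarkers: bool = True
    run_study: bool = True

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k in ("grid_shape", "spacing_mm"):
            d[k] = list(d[k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("grid_shape", "spacing_mm"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def grid(self) -> GridSpec:
        return GridSpec(
            self.grid_shape,
            self.spacing_mm,
            self.n_frames,
            self.frame_duration_s,
            self.mv_open_frame,
        )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the JSON report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    field = mask = truth = None
    static = None

    try:
        if cfg.run_phantom:
            grid = cfg.grid()
            pcfg = default_phantom_config(grid, seed=cfg.seed)
            corruption = CorruptionConfig(
                noise_sd_m_s=cfg.noise_sd_m_s,
                eddy_coeffs=DEFAULT_EDDY_COEFFS.copy() if cfg.eddy_offsets else None,
                wrap_at_venc=cfg.wrap_at_venc,
            )
            field, mask, truth = make_phantom(pcfg, grid, corruption)
            if cfg.eddy_offsets:
                static = static_background_mask(grid, pcfg)
            write_bundle(out / "phantom", field, mask)
            report["stages"]["phantom"] = {
                "grid_shape": list(grid.shape),
                "noise_sd_m_s": cfg.noise_sd_m_s,
                "ground_truth": truth.as_dict(),
            }
    except Exception as e:  # noqa: BLE001 - stage name is part of the contract
        raise RuntimeError(f"stage 'phantom' failed: {e}") from e

    try:
        if cfg.run_preprocess and field is not None:
            field, _ = preprocess(
                field,
                static_mask=static,
                order=cfg.eddy_order,
                max_passes=cfg.unwrap_max_passes,
                denoise=cfg.denoise,
            )
            write_bundle(out / "preprocessed", field, mask)
            report["stages"]["preprocess"] = {
                "eddy_order": cfg.eddy_order,
                "unwrap_max_passes": cfg.unwrap_max_passes,
                "denoise": cfg.denoise,
            }
    except Exception as e:
        raise RuntimeError(f"stage 'preprocess' failed: {e}") from e

    try:
        if cfg.run_biomarkers and field is not None:
            bm = extract_biomarkers(
                field,
                mask,
                stasis_threshold_m_s=cfg.stasis_threshold_m_s,
                peak_reduction=cfg.peak_reduction,
                classify_patterns=cfg.classify_patterns,
            )
            report["stages"]["biomarkers"] = bm.as_dict()
    except Exception as e:
        raise RuntimeError(f"stage 'biomarkers' failed: {e}") from e

    try:
        if cfg.run_study:
            design = StudyDesign(seed=cfg.seed)
            table = simulate_study(design)
            table.to_csv(out / "study.csv", index=False)
            stats: dict = {}
            pairs = {
                src: extract_pairs(table, src, design.biomarker)
                for src in ("intra_obs", "inter_obs", "rescan", "interval")
            }
            for src, p in pairs.items():
                est = within_subject_cv(p, n_boot=cfg.n_boot_ci, seed=cfg.seed)
                ba = bland_altman(p)
                stats[src] = {
                    "cv": est.cv,
                    "ci": [est.ci_low, est.ci_high],
                    "bias": ba.bias,
                    "loa": [ba.loa_low, ba.loa_high],
                    "n": est.n_subjects,
                }
            cmp = compare_cv_dependent(
                pairs["rescan"], pairs["interval"],
                n_boot=cfg.n_boot_dependent, seed=cfg.seed,
            )
            stats["rescan_vs_interval"] = {
                "delta_cv": cmp.delta_cv,
                "ci": [cmp.ci_low, cmp.ci_high],
                "p": cmp.p_value,
            }
            report["stages"]["study"] = stats
    except Exception as e:
        raise RuntimeError(f"stage 'study' failed: {e}") from e

    (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
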