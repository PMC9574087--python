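"""Validation statistics, reference tables, and end-to-end orchestration.

The automatic measurements are validated against independent reference
measurements (semi-automatic thickness readings and region-growing gap
segmentations) using two statistics: Pearson's correlation coefficient rho
and the mean absolute difference.  The reference numbers ship with the
package as small CSV tables; :func:`reference_thickness_table` and
:func:`reference_gap_table` load them.

Display rounding follows the reporting convention of the measurement
protocol: thickness to whole micrometres, volumes to 0.1 mm^3, rho to three
decimals.  Full-precision values are always retained in the JSON outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import aligner_extraction, gaps as gaps_mod, phantom as phantom_mod, thickness as thickness_mod
from .registration import RigidTransform, apply_rigid, register_rigid
from .volume_io import CutPlane, VoxelVolume, read_volume

__all__ = [
    "ValidationStats",
    "PipelineConfig",
    "pearson",
    "mean_abs_diff",
    "validate_against_reference",
    "reference_thickness_table",
    "reference_gap_table",
    "run_pipeline",
]


def _as_arrays(x, y, min_len: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError(f"paired lists required, got lengths {x.size} and {y.size}")
    if x.size < min_len:
        raise ValueError(f"need at least {min_len} pairs, got {x.size}")
    return x, y


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient rho."""
    x, y = _as_arrays(x, y, 2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant input")
    return float(stats.pearsonr(x, y).statistic)


def mean_abs_diff(x, y) -> float:
    """Mean of |x_i - y_i|, in the units of the inputs."""
    x, y = _as_arrays(x, y, 1)
    return float(np.mean(np.abs(x - y)))


@dataclass
class ValidationStats:
    """Agreement between automatic and reference measurement vectors."""

    rho: float | None
    mean_abs_diff: float
    per_point_diffs: np.ndarray
    n: int

    def as_dict(self) -> dict:
        return {
            "rho": self.rho,
            "mean_abs_diff": self.mean_abs_diff,
            "per_point_diffs": np.asarray(self.per_point_diffs).tolist(),
            "n": self.n,
        }


def validate_against_reference(auto, reference) -> ValidationStats:
    """Bundle rho, mean absolute difference and signed (auto - reference) diffs.

    rho is reported as None when either vector is constant (undefined).
    """
    a, r = _as_arrays(auto, reference, 1)
    try:
        rho = pearson(a, r)
    except ValueError:
        rho = None
    return ValidationStats(
        rho=rho,
        mean_abs_diff=mean_abs_diff(a, r),
        per_point_diffs=a - r,
        n=int(a.size),
    )


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("alignfit.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def reference_thickness_table() -> pd.DataFrame:
    """Paired automatic/reference thickness readings (um) at five positions
    per specimen (NA.550 at 142 C, NA.750 at 143 C)."""
    return _load_table("table1_thickness.csv")


def reference_gap_table() -> pd.DataFrame:
    """Paired automatic/reference gap volumes (mm^3): the buccal
    central-incisor ROI per specimen and temperature, plus the whole-aligner
    total for NA.750 at 176 C."""
    return _load_table("table2_gaps.csv")


# -- display rounding -------------------------------------------------------

def round_thickness_um(v: float) -> float:
    return float(np.round(v))


def round_volume_mm3(v: float) -> float:
    return float(np.round(v, 1))


def round_rho(v: float) -> float:
    return float(np.round(v, 3))


# -- pipeline ---------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Either ``phantom`` is set (synthetic run with ground truth) or both
    volume paths are given.  ``voxel_size_um`` overrides header spacing for
    file inputs.
    """

    phantom: phantom_mod.PhantomConfig | None = None
    model_path: str | None = None
    model_plus_aligner_path: str | None = None
    voxel_size_um: float | None = None
    base_fraction: float = 0.2
    registration_levels: int = 3
    mask_closing_radius: int = 2
    gap_config: gaps_mod.GapConfig = field(default_factory=gaps_mod.GapConfig)
    nominal_foil_um: float | None = None
    n_points: int = 100
    n_reps: int = 100
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        have_files = self.model_path is not None and self.model_plus_aligner_path is not None
        if (self.phantom is None) == (not have_files):
            raise ValueError("provide either phantom parameters or both volume paths")


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Register -> subtract -> extract mask -> centre surface -> thickness
    summary -> multi-threshold gap volumetry.

    Returns a report bundle (plain dict); when ``output_dir`` is set, writes
    table-shaped CSVs and JSON files there.  Identical config and seed give
    identical outputs.
    """
    log: list[str] = []
    truth = None
    if config.phantom is not None:
        cfg = config.phantom
        model, mpa, truth = phantom_mod.generate_arch_phantom(cfg)
        plane = truth.base_plane
        log.append(f"stage=simulate seed={cfg.seed} shape={cfg.shape}")
    else:
        model = read_volume(config.model_path, voxel_size_um=config.voxel_size_um)
        mpa = read_volume(config.model_plus_aligner_path, voxel_size_um=config.voxel_size_um)
        plane = config.gap_config.plane
        log.append("stage=load")

    try:
        transform = register_rigid(
            mpa, model, region=config.base_fraction, levels=config.registration_levels
        )
        log.append(f"stage=register params={transform.to_dict()}")

        registered = apply_rigid(model, transform, interpolation="linear")
        diff = aligner_extraction.subtract_registered(mpa, registered)
        mask = aligner_extraction.extract_aligner_mask(
            diff, closing_radius_voxels=config.mask_closing_radius
        )
        log.append(
            f"stage=extract otsu={mask.otsu_threshold} voxels={mask.component_voxels}"
        )

        cs = thickness_mod.extract_center_surface(mask)
        fld = thickness_mod.measure_thickness(mask, cs)
        summary = thickness_mod.summarize_thickness(
            fld,
            n_points=min(config.n_points, fld.n_voxels),
            n_reps=config.n_reps,
            seed=config.seed,
            nominal_foil_um=config.nominal_foil_um,
        )
        log.append(f"stage=thickness n={fld.n_voxels}")

        gap_cfg = config.gap_config
        if gap_cfg.plane is None and plane is not None:
            from dataclasses import replace

            gap_cfg = replace(gap_cfg, plane=plane)
        gap_totals = gaps_mod.total_gap_volume_multithreshold(mpa, gap_cfg)
        gap_single = gaps_mod.gap_pipeline_single(mpa, gap_cfg, gap_cfg.single_threshold)
        log.append(f"stage=gaps mean={gap_totals['mean_mm3']:.6f} mm3")
    except Exception as exc:
        stage = log[-1].split()[0] if log else "stage=init"
        raise RuntimeError(f"pipeline aborted after {stage}: {exc}") from exc

    bundle = {
        "transform": transform.to_dict(),
        "thickness_summary": summary.as_dict(),
        "thickness_summary_display": {
            "minimum_um": round_thickness_um(summary.minimum),
            "median_um": round_thickness_um(summary.median),
            "mean_um": round_thickness_um(summary.mean),
            "maximum_um": round_thickness_um(summary.maximum),
            "sd_um": round_thickness_um(summary.sd),
        },
        "gap_totals": gap_totals,
        "gap_components_at_single_threshold": [
            asdict(c) for c in gap_single.components
        ],
        "seed": config.seed,
        "log": log,
    }
    if truth is not None:
        bundle["phantom_truth"] = {
            "n_gaps": len(truth.gaps),
            "analytic_gap_total_mm3": float(
                sum(g.analytic_volume_mm3 for g in truth.gaps)
            ),
            "designed_thickness_um": truth.designed_thickness_um,
            "true_offset": truth.rigid_offset.to_dict(),
        }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            np.column_stack([fld.coords, fld.values_um]),
            columns=["x", "y", "z", "d_um"],
        ).to_csv(out / "thickness_per_voxel.csv", index=False)
        pd.DataFrame({"resampled_mean_um": summary.resampled_means}).to_csv(
            out / "resampled_means.csv", index=False
        )
        _json_dump(bundle, out / "report.json")
    return bundle
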