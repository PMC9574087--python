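"""Gap volumetry between aligner and model.

Gaps — voids where the aligner inner surface fails to contact the model —
are detected directly on the model+aligner scan: the image is binarised with
a fixed gray-value threshold, the below-plane base region is sealed, the
mask is closed with a sphere of radius R (dilation, hole filling, erosion),
and gap voxels are defined as filled-but-not-material, restricted to the
region above the cut plane.  Connected components (26-neighbourhood) are
reported with volumes in mm^3.

Because foil thinning makes any single threshold imperfect, the headline
mode measures at thresholds 140, 150 and 160 and averages, with the min-max
spread serving as the uncertainty.

Choosing R: a surface slit of opening width w is closed (and hence counted
as gap volume) iff w <= 2R, so R should exceed half the widest expected gap
mouth while staying below the scale of real concavities of the dental arch.
The default is R = 10 voxels (330 um at 33 um voxels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .aligner_extraction import STRUCT_26, ball_dilate, ball_erode
from .volume_io import CutPlane, VoxelVolume

__all__ = [
    "GapConfig",
    "GapComponent",
    "GapSet",
    "binarize_fixed",
    "seal_and_crop",
    "close_fill",
    "extract_gaps",
    "total_gap_volume_multithreshold",
    "roi_gap_volume",
    "projected_gap_map",
]


@dataclass(frozen=True)
class GapConfig:
    """Parameters of the gap-volumetry stage."""

    thresholds: tuple[int, ...] = (140, 150, 160)
    closing_radius_R: int = 10
    connectivity: int = 26
    plane: CutPlane | None = None

    def __post_init__(self) -> None:
        th = tuple(self.thresholds)
        if any(not 0 < t < 255 for t in th):
            raise ValueError("thresholds must lie in (0, 255)")
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if self.closing_radius_R < 1:
            raise ValueError("closing radius R must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def single_threshold(self) -> int:
        """The fixed single-threshold default (150 when present)."""
        return 150 if 150 in self.thresholds else self.thresholds[len(self.thresholds) // 2]

    def label_structure(self) -> np.ndarray:
        order = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, order)


@dataclass
class GapComponent:
    label: int
    voxel_count: int
    volume_mm3: float
    bounding_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    centroid: tuple[float, float, float]


@dataclass
class GapSet:
    """Connected gap components at a given threshold and closing radius."""

    components: list[GapComponent]
    total_volume_mm3: float
    threshold: int
    closing_radius_R: int
    voxel_size: float
    gap_mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def total_voxels(self) -> int:
        return sum(c.voxel_count for c in self.components)


def binarize_fixed(vol: VoxelVolume, threshold: int) -> np.ndarray:
    """Material mask: voxels with value >= threshold."""
    if not 0 < threshold < 255:
        raise ValueError("threshold must lie in (0, 255)")
    return vol.data >= threshold


def seal_and_crop(mask: np.ndarray, plane: CutPlane) -> np.ndarray:
    """Seal the base: set every voxel on the discarded side of ``plane`` to
    foreground, so the hole-filling operation cannot leak through the base.
    Downstream gap extraction excludes the sealed side again.
    """
    out = np.asarray(mask, dtype=bool).copy()
    out[plane.discarded_slice(out.shape)] = True
    return out


def close_fill(mask: np.ndarray, R: int) -> np.ndarray:
    """Sphere-closing with hole filling: dilate by a discrete ball of radius
    R, fill every background component not connected to the volume border
    (6-connectivity), then erode by the same ball.  The result is a superset
    of the plain morphological closing, hence of the input.
    """
    if R < 1:
        raise ValueError("closing radius R must be >= 1")
    m = np.asarray(mask, dtype=bool)
    dil = ball_dilate(m, R)
    filled = ndimage.binary_fill_holes(dil)
    out = ball_erode(filled, R)
    out |= m  # guard exactness at the volume border; closing is extensive
    return out


def _above_plane_mask(shape, plane: CutPlane | None) -> np.ndarray | None:
    if plane is None:
        return None
    keep = np.ones(shape, dtype=bool)
    keep[plane.discarded_slice(shape)] = False
    return keep


def extract_gaps(
    binary: np.ndarray,
    filled: np.ndarray,
    config: GapConfig,
    threshold: int | None = None,
    voxel_size: float = 33.0,
) -> GapSet:
    """Label gap voxels (filled AND NOT material, above the plane).

    Components use the configured connectivity (default 26); volumes are
    voxel counts times (voxel_size mm)^3.
    """
    binary = np.asarray(binary, dtype=bool)
    filled = np.asarray(filled, dtype=bool)
    if np.any(binary & ~filled):
        raise RuntimeError("contract violation: filled mask does not cover binary mask")
    gap = filled & ~binary
    keep = _above_plane_mask(gap.shape, config.plane)
    if keep is not None:
        gap &= keep
    return _label_gapset(gap, config, threshold, voxel_size=voxel_size)


def _label_gapset(
    gap: np.ndarray, config: GapConfig, threshold: int | None, voxel_size: float = 33.0
) -> GapSet:
    labels, n = ndimage.label(gap, structure=config.label_structure())
    voxel_mm3 = (voxel_size / 1000.0) ** 3
    comps: list[GapComponent] = []
    if n:
        counts = np.bincount(labels.ravel())
        slices = ndimage.find_objects(labels)
        centroids = ndimage.center_of_mass(gap, labels, range(1, n + 1))
        for lab in range(1, n + 1):
            sl = slices[lab - 1]
            comps.append(
                GapComponent(
                    label=lab,
                    voxel_count=int(counts[lab]),
                    volume_mm3=float(counts[lab] * voxel_mm3),
                    bounding_box=tuple((s.start, s.stop) for s in sl),
                    centroid=tuple(float(c) for c in centroids[lab - 1]),
                )
            )
    return GapSet(
        components=comps,
        total_volume_mm3=float(gap.sum() * voxel_mm3),
        threshold=threshold if threshold is not None else -1,
        closing_radius_R=config.closing_radius_R,
        voxel_size=voxel_size,
        gap_mask=gap,
    )


def gap_pipeline_single(
    vol: VoxelVolume, config: GapConfig, threshold: int
) -> GapSet:
    """binarise -> seal -> close_fill -> extract for one threshold."""
    binary = binarize_fixed(vol, threshold)
    sealed = binary if config.plane is None else seal_and_crop(binary, config.plane)
    filled = close_fill(sealed, config.closing_radius_R)
    gap = filled & ~sealed
    keep = _above_plane_mask(gap.shape, config.plane)
    if keep is not None:
        gap &= keep
    gs = _label_gapset(gap, config, threshold, voxel_size=vol.voxel_size)
    gs.provenance = {"threshold": threshold, "R": config.closing_radius_R}
    return gs


def total_gap_volume_multithreshold(vol: VoxelVolume, config: GapConfig) -> dict:
    """Totals at each configured threshold, their mean, and the min-max spread.

    The spread across thresholds plays the role of an error bar on the mean
    gap volume.
    """
    per: list[dict] = []
    totals: list[float] = []
    for t in config.thresholds:
        gs = gap_pipeline_single(vol, config, t)
        totals.append(gs.total_volume_mm3)
        per.append(
            {
                "threshold": t,
                "total_mm3": gs.total_volume_mm3,
                "n_components": gs.n_components,
            }
        )
    return {
        "per_threshold": per,
        "mean_mm3": float(np.mean(totals)),
        "min_mm3": float(np.min(totals)),
        "max_mm3": float(np.max(totals)),
    }


def roi_gap_volume(vol: VoxelVolume, roi_box, config: GapConfig, transform=None) -> GapSet:
    """Gap pipeline restricted to an axis-aligned voxel box ((x0,x1),(y0,y1),(z0,z1)).

    ``roi_box`` is given in voxel coordinates of the reference grid; when a
    near-identity registration ``transform`` is supplied, the box is mapped
    into this specimen's grid first (translation rounded to whole voxels),
    mirroring the cropping of all specimens by predetermined coordinates.
    """
    if transform is not None:
        if np.max(np.abs(transform.angles_deg)) >= 5.0:
            raise ValueError("ROI transfer requires rotation < 5 degrees")
        s = vol.voxel_size
        lo = np.array([b[0] for b in roi_box], dtype=float)
        hi = np.array([b[1] for b in roi_box], dtype=float)
        shift = np.rint(
            (transform.apply_points((lo + 0.5) * s)[0] - (lo + 0.5) * s) / s
        ).astype(int)
        roi_box = tuple(
            (int(l + d), int(h + d)) for l, h, d in zip(lo, hi, shift)
        )
    (x0, x1), (y0, y1), (z0, z1) = roi_box
    shape = vol.shape
    x0, y0, z0 = max(0, x0), max(0, y0), max(0, z0)
    x1, y1, z1 = min(shape[0], x1), min(shape[1], y1), min(shape[2], z1)
    if x1 <= x0 or y1 <= y0 or z1 <= z0:
        raise ValueError(f"empty ROI crop {roi_box} for volume of shape {shape}")
    crop = VoxelVolume(
        vol.data[x0:x1, y0:y1, z0:z1].copy(), vol.voxel_size, vol.name + " ROI"
    )
    cfg = config
    if config.plane is not None and config.plane.axis == 2:
        local = config.plane.index - z0
        if 0 <= local < crop.shape[2]:
            cfg = replace(config, plane=CutPlane(2, local, config.plane.keep_side))
        elif config.plane.keep_side == "low" and config.plane.index >= z1:
            cfg = replace(config, plane=None)
        else:
            raise ValueError("ROI box lies entirely on the discarded side of the plane")
    gs = gap_pipeline_single(crop, cfg, config.single_threshold)
    gs.provenance["roi_box"] = ((x0, x1), (y0, y1), (z0, z1))
    return gs


def projected_gap_map(gaps: GapSet, axis: int = 2) -> np.ndarray:
    """Per-column projected gap extent (um): summed gap voxel count along
    ``axis`` times the voxel size.  The map total times the voxel
    cross-section equals the gap volume exactly.
    """
    if gaps.gap_mask is None:
        raise ValueError("GapSet carries no gap mask to project")
    return gaps.gap_mask.sum(axis=axis).astype(np.float64) * gaps.voxel_size
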