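"""Synthetic micro-CT phantoms of an aligner mounted on a dental-arch model.

Every pipeline stage (registration, subtraction segmentation, centre-surface
thickness, gap volumetry) is validated against these phantoms, because the
original tomograms are not redistributable.  A phantom consists of two
co-registered 8-bit volumes emulating the paired acquisitions:

* ``model`` — the printed resin model alone (substrate box, capsule-shaped
  teeth along a half-arch, convex registration bosses on the base walls),
  rendered after applying a known rigid offset;
* ``model+aligner`` — the same scene plus a closed polymer shell draped over
  the teeth, with ellipsoidal interface voids ("gaps") of exactly known
  analytic volume carved at the model-shell interface.

Model and shell materials get near-identical gray values, well above the
fixed segmentation thresholds, emulating the similar x-ray absorption of the
resin and the thermoformed foil; air lies far below.

Geometry notes
--------------
The aligner outer surface is a smooth-minimum blend of the primitive offset
surfaces.  The blend length is chosen at least as large as the default
sphere-closing radius (R = 10 voxels), so that every concave junction has a
fillet radius >= R and sphere closing of a gap-free phantom adds no spurious
gap voxels — the only voids the gap stage can find are the implanted ones.
Registration features (bosses) are placed below the ROI cut plane so they
never enter gap statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .registration import RigidTransform
from .volume_io import CutPlane, VoxelVolume

__all__ = [
    "GapSpec",
    "Intensities",
    "PhantomConfig",
    "TruthGap",
    "PhantomGroundTruth",
    "generate_arch_phantom",
    "generate_slab_phantom",
]

#: Fixed gray-value thresholds the gap stage uses by default (8-bit scale).
FIXED_THRESHOLDS = (140, 150, 160)


@dataclass(frozen=True)
class GapSpec:
    """An ellipsoidal interface void on one tooth.

    ``semi_axes`` = (horizontal-tangential, vertical-tangential, normal) in
    voxels; the void is centred on the model-shell interface at
    ``height_offset`` voxels above the gum border, on the buccal (outward) or
    lingual (inward) side of the tooth.
    """

    tooth: int
    semi_axes: tuple[float, float, float] = (10.0, 8.0, 6.0)
    side: str = "buccal"
    height_offset: float = 15.0


@dataclass(frozen=True)
class Intensities:
    """Mean gray values of the three phantom materials."""

    model: float = 200.0
    shell: float = 195.0
    air: float = 30.0


def _default_gaps() -> tuple[GapSpec, ...]:
    return (
        GapSpec(tooth=0, semi_axes=(12.0, 10.0, 7.0), side="buccal", height_offset=14.0),
        GapSpec(tooth=1, semi_axes=(10.0, 8.0, 6.0), side="buccal"),
        GapSpec(tooth=2, semi_axes=(9.0, 7.0, 5.0), side="lingual"),
        GapSpec(tooth=2, semi_axes=(8.0, 6.0, 4.0), side="buccal"),
        GapSpec(tooth=3, semi_axes=(11.0, 9.0, 7.0), side="buccal", height_offset=14.0),
        GapSpec(tooth=4, semi_axes=(8.0, 7.0, 5.0), side="lingual"),
    )


@dataclass
class PhantomConfig:
    """Full parameterisation of the arch phantom (lengths in voxels)."""

    shape: tuple[int, int, int] = (160, 140, 166)
    voxel_size: float = 33.0
    n_teeth: int = 5
    tooth_radius: float = 12.0
    tooth_height: float = 26.0
    arch_radius: float = 40.0
    arch_center: tuple[float, float] = (80.0, 92.0)
    arch_span_deg: tuple[float, float] = (18.0, 162.0)
    gum_z: float = 70.0               # substrate top = tooth-gum border
    wall_margin: float = 14.0         # air ring wider than the closing ball
    base_bottom_margin: float = 6.0
    base_thickness: float = 12.0      # shell thickness over the substrate
    occlusal_multiplier: float = 1.3
    lateral_multiplier: float = 0.85
    blend_voxels: float = 20.0        # junction fillet radius (> closing R)
    flare_top_offset: float = 10.0    # flare top this far above the cut plane
    corrugation_amplitude: float = 2.5
    corrugation_periods: tuple[float, float] = (41.0, 36.0)
    gaps: tuple[GapSpec, ...] = field(default_factory=_default_gaps)
    rigid_offset: RigidTransform | None = None
    intensities: Intensities = field(default_factory=Intensities)
    noise_sd: float = 10.0
    plane_offset_um: float = 2000.0   # cut plane 2 mm below the gum border
    base_plane: CutPlane | None = None
    seed: int = 0

    # -- derived geometry ---------------------------------------------------
    def tooth_centers(self) -> np.ndarray:
        """(n, 2) x/y centres of the tooth axes along the half-arch."""
        a0, a1 = np.deg2rad(self.arch_span_deg)
        th = np.linspace(a0, a1, self.n_teeth)
        cx, cy = self.arch_center
        return np.stack(
            [cx + self.arch_radius * np.cos(th), cy - self.arch_radius * np.sin(th)],
            axis=1,
        )

    def lateral_thickness(self) -> float:
        return self.base_thickness * self.lateral_multiplier

    def occlusal_thickness(self) -> float:
        return self.base_thickness * self.occlusal_multiplier

    def resolved_plane(self) -> CutPlane:
        if self.base_plane is not None:
            return self.base_plane
        idx = int(round(self.gum_z + self.plane_offset_um / self.voxel_size))
        return CutPlane(axis=2, index=idx, keep_side="low")


@dataclass
class TruthGap:
    """Ground truth for one implanted void."""

    center_vox: np.ndarray
    semi_axes: tuple[float, float, float]
    analytic_volume_mm3: float
    voxel_count: int
    voxelized_volume_mm3: float
    centroid_vox: np.ndarray


@dataclass
class PhantomGroundTruth:
    """Everything a test oracle needs about a generated phantom."""

    shell_mask: np.ndarray
    model_mask: np.ndarray
    material_mask: np.ndarray          # model+shell minus carved voids
    thickness_map_um: np.ndarray       # float, NaN outside the shell
    void_mask: np.ndarray              # union of all carved gap voids
    gaps: list[TruthGap]
    rigid_offset: RigidTransform
    base_plane: CutPlane
    voxel_size: float
    designed_thickness_um: dict


# ---------------------------------------------------------------------------
# signed-distance primitives (vectorised over pts of shape (..., 3))

def _sd_box(pts, lo, hi):
    q = np.maximum(lo - pts, pts - hi)
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=-1)
    inside = np.minimum(np.max(q, axis=-1), 0.0)
    return outside + inside


def _sd_capsule(pts, a, b, r):
    pa = pts - a
    ba = np.asarray(b, dtype=np.float32) - np.asarray(a, dtype=np.float32)
    h = np.clip(np.dot(pa, ba) / np.dot(ba, ba), 0.0, 1.0)
    return np.linalg.norm(pa - h[..., None] * ba, axis=-1) - r


def _sd_sphere(pts, c, r):
    return np.linalg.norm(pts - np.asarray(c, dtype=np.float32), axis=-1) - r


def _smin(a, b, r):
    """Rounded union of two SDFs: fillets the concave junction with a
    circular arc of radius exactly ``r`` and is exact away from it."""
    u = np.maximum(r - a, 0.0)
    v = np.maximum(r - b, 0.0)
    return np.maximum(r, np.minimum(a, b)) - np.sqrt(u * u + v * v)


def _bottom_face_z(cfg: PhantomConfig, x, y):
    """Corrugated bottom face of the base (voxel units).

    The corrugation lives entirely below the cut plane and plays the role
    of the structure a real printed base has — it is what makes
    intensity-based registration of the base well-posed in all six degrees
    of freedom.
    """
    nz = cfg.shape[2]
    amp = cfg.corrugation_amplitude
    px, py = cfg.corrugation_periods
    base = nz - cfg.base_bottom_margin - amp
    return base + amp * np.sin(2 * np.pi * x / px + 0.7) * np.sin(
        2 * np.pi * y / py + 1.3
    )


def _sd_flare(cfg: PhantomConfig, pts):
    """Full-footprint pedestal from just above the cut plane down to the
    corrugated bottom face.  Because it spans the whole grid in x/y, the
    seal plane lies in its interior and the sealing operation creates no
    material/air corner that sphere closing could misread as a gap."""
    z_top = cfg.resolved_plane().index - cfg.flare_top_offset
    zf = _bottom_face_z(cfg, pts[..., 0], pts[..., 1])
    return np.maximum(z_top - pts[..., 2], pts[..., 2] - zf).astype(np.float32)


def _scene_fields(cfg: PhantomConfig, pts: np.ndarray, need_outer: bool = True):
    """Model SDF and aligner outer SDF at ``pts`` (voxel units)."""
    nx, ny, nz = cfg.shape
    w, bm = cfg.wall_margin, cfg.base_bottom_margin
    lo = np.array([w, w, cfg.gum_z], dtype=np.float32)
    hi = np.array([nx - w, ny - w, nz - bm], dtype=np.float32)

    t_lat = cfg.lateral_thickness()
    occ_ext = cfg.occlusal_thickness() - t_lat

    flare = _sd_flare(cfg, pts)
    # The flare enters model and outer fields through the same blend, so the
    # two surfaces coincide there and the shell has zero thickness on the
    # base walls (the aligner is cut at the lower model edge).
    f_model = _smin(_sd_box(pts, lo, hi), flare, cfg.blend_voxels)
    f_out = None
    if need_outer:
        lo_out = lo - np.array([0.0, 0.0, cfg.base_thickness], dtype=np.float32)
        f_out = _smin(_sd_box(pts, lo_out, hi), flare, cfg.blend_voxels)

    for x, y in cfg.tooth_centers():
        root = np.array([x, y, cfg.gum_z + 3.0], dtype=np.float32)
        tip = np.array([x, y, cfg.gum_z - cfg.tooth_height], dtype=np.float32)
        f_model = np.minimum(f_model, _sd_capsule(pts, root, tip, cfg.tooth_radius))
        if need_outer:
            tip_out = tip - np.array([0.0, 0.0, occ_ext], dtype=np.float32)
            f_out = _smin(
                f_out,
                _sd_capsule(pts, root, tip_out, cfg.tooth_radius + t_lat),
                cfg.blend_voxels,
            )

    return f_model, f_out


def _grid_points(shape) -> np.ndarray:
    """Voxel-centre coordinates in voxel units, shape (nx, ny, nz, 3)."""
    ax = [np.arange(n, dtype=np.float32) + 0.5 for n in shape]
    g = np.meshgrid(*ax, indexing="ij")
    return np.stack(g, axis=-1)


def _gap_frames(cfg: PhantomConfig, spec: GapSpec):
    """Centre (voxel units) and orthonormal frame (t_h, t_v, n) of a void."""
    centers = cfg.tooth_centers()
    if not 0 <= spec.tooth < len(centers):
        raise ValueError(f"gap references tooth {spec.tooth} of {len(centers)}")
    x, y = centers[spec.tooth]
    u = np.array([x - cfg.arch_center[0], y - cfg.arch_center[1], 0.0])
    u /= np.linalg.norm(u)
    if spec.side == "lingual":
        u = -u
    elif spec.side != "buccal":
        raise ValueError("gap side must be 'buccal' or 'lingual'")
    center = np.array([x, y, cfg.gum_z - spec.height_offset]) + cfg.tooth_radius * u
    t_v = np.array([0.0, 0.0, 1.0])
    t_h = np.cross(u, t_v)
    return center, (t_h, t_v, u)


def _carve_gaps(cfg: PhantomConfig, material: np.ndarray) -> list[TruthGap]:
    """Carve ellipsoidal voids into ``material`` in place; return ground truth."""
    mm = cfg.voxel_size / 1000.0
    voxel_mm3 = mm ** 3
    truths: list[TruthGap] = []
    all_voids = np.zeros_like(material)
    pristine = material.copy()
    for spec in cfg.gaps:
        a, b, c = spec.semi_axes
        if c > cfg.lateral_thickness() - 2.0:
            raise ValueError(
                f"gap normal semi-axis {c} exceeds local shell cover "
                f"({cfg.lateral_thickness() - 2.0:.1f} voxels)"
            )
        center, (t_h, t_v, n) = _gap_frames(cfg, spec)
        rmax = max(a, b, c) + 2.0
        lo = np.maximum(np.floor(center - rmax).astype(int), 0)
        hi = np.minimum(np.ceil(center + rmax).astype(int) + 1, cfg.shape)
        sub = _grid_points(tuple(hi - lo)) + lo.astype(np.float32)
        d = sub - center
        q = (
            (np.dot(d, t_h) / a) ** 2
            + (np.dot(d, t_v) / b) ** 2
            + (np.dot(d, n) / c) ** 2
        )
        void = q <= 1.0
        box = tuple(slice(l, h) for l, h in zip(lo, hi))
        if np.any(void & ~pristine[box]):
            raise ValueError(
                f"gap on tooth {spec.tooth} extends beyond the shell-model interface"
            )
        rim = ndimage.binary_dilation(void) & ~void
        if np.any(rim & ~pristine[box]):
            raise ValueError(
                f"gap on tooth {spec.tooth} is not fully enclosed by material"
            )
        if np.any(void & all_voids[box]):
            raise ValueError("gap voids intersect each other")
        all_voids[box] |= void
        material[box] &= ~void
        count = int(void.sum())
        idx = np.argwhere(void) + lo
        truths.append(
            TruthGap(
                center_vox=center,
                semi_axes=spec.semi_axes,
                analytic_volume_mm3=4.0 / 3.0 * np.pi * a * b * c * voxel_mm3,
                voxel_count=count,
                voxelized_volume_mm3=count * voxel_mm3,
                centroid_vox=idx.mean(axis=0),
            )
        )
    return truths, all_voids


def _check_intensity_margins(intens: Intensities, noise_sd: float) -> None:
    margin = max(20.0, 2.0 * noise_sd)
    lo_mat = min(intens.model, intens.shell)
    if lo_mat < max(FIXED_THRESHOLDS) + margin:
        raise ValueError(
            f"material gray values must sit >= {margin:.0f} above the largest "
            f"fixed threshold {max(FIXED_THRESHOLDS)}"
        )
    if intens.air > min(FIXED_THRESHOLDS) - margin:
        raise ValueError(
            f"air gray value must sit >= {margin:.0f} below the smallest "
            f"fixed threshold {min(FIXED_THRESHOLDS)}"
        )


def _render(model_mask, shell_mask, intens, noise_sd, rng) -> np.ndarray:
    arr = np.full(model_mask.shape, intens.air, dtype=np.float32)
    arr[model_mask] = intens.model
    if shell_mask is not None:
        arr[shell_mask] = intens.shell
    if noise_sd > 0:
        arr += rng.normal(0.0, noise_sd, size=arr.shape).astype(np.float32)
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def generate_arch_phantom(
    config: PhantomConfig | None = None,
) -> tuple[VoxelVolume, VoxelVolume, PhantomGroundTruth]:
    """Generate the paired (model, model+aligner) arch phantom with ground truth.

    The model+aligner volume is the scene plus a closed shell draped over all
    teeth down to the base, minus the configured voids; the model volume is
    the bare scene rendered after applying the true rigid offset.  Identical
    seeds give bitwise-identical outputs.
    """
    cfg = config if config is not None else PhantomConfig()
    _check_intensity_margins(cfg.intensities, cfg.noise_sd)
    plane = cfg.resolved_plane()
    plane.validate_for(cfg.shape)
    rng = np.random.default_rng(cfg.seed)

    pts = _grid_points(cfg.shape)
    f_model, f_out = _scene_fields(cfg, pts)
    model_mask = f_model <= 0.0
    material = f_out <= 0.0
    material |= model_mask
    shell_mask = material & ~model_mask

    thickness_map = np.full(cfg.shape, np.nan, dtype=np.float32)
    thickness_map[shell_mask] = (
        (f_model[shell_mask] - f_out[shell_mask]) * cfg.voxel_size
    )

    gap_truths, void_mask = _carve_gaps(cfg, material)
    shell_after = material & ~model_mask
    thickness_map[~shell_after] = np.nan

    fixed_data = _render(
        model_mask & material, shell_after, cfg.intensities, cfg.noise_sd, rng
    )

    offset = (
        cfg.rigid_offset
        if cfg.rigid_offset is not None
        else RigidTransform.identity(
            np.asarray(cfg.shape, dtype=float) * cfg.voxel_size / 2.0
        )
    )
    if (
        np.allclose(offset.angles_deg, 0.0)
        and np.allclose(offset.translation_um, 0.0)
    ):
        moving_mask = model_mask
    else:
        pts_um = pts.reshape(-1, 3).astype(np.float64) * cfg.voxel_size
        moved = (offset.apply_points(pts_um) / cfg.voxel_size).astype(np.float32)
        f_model_mv, _ = _scene_fields(
            cfg, moved.reshape(pts.shape), need_outer=False
        )
        moving_mask = f_model_mv <= 0.0
    moving_data = _render(moving_mask, None, cfg.intensities, cfg.noise_sd, rng)

    truth = PhantomGroundTruth(
        shell_mask=shell_after,
        model_mask=model_mask,
        material_mask=material,
        thickness_map_um=thickness_map,
        void_mask=void_mask,
        gaps=gap_truths,
        rigid_offset=offset,
        base_plane=plane,
        voxel_size=cfg.voxel_size,
        designed_thickness_um={
            "lateral": cfg.lateral_thickness() * cfg.voxel_size,
            "occlusal": cfg.occlusal_thickness() * cfg.voxel_size,
            "base": cfg.base_thickness * cfg.voxel_size,
        },
    )
    vs = cfg.voxel_size
    return (
        VoxelVolume(moving_data, vs, "phantom model"),
        VoxelVolume(fixed_data, vs, "phantom model+aligner"),
        truth,
    )


def generate_slab_phantom(
    thickness_voxels: int,
    dims: tuple[int, int, int] = (48, 48, 28),
    voxel_size: float = 33.0,
    intensities: Intensities | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[VoxelVolume, VoxelVolume, PhantomGroundTruth]:
    """Flat-slab phantom: an axis-aligned shell of exactly ``thickness_voxels``
    layers resting on a flat substrate — the unit-test fixture for the
    centre-surface thickness method.
    """
    intens = intensities if intensities is not None else Intensities()
    nx, ny, nz = dims
    z_sub = (2 * nz) // 3
    if not 0 < thickness_voxels < z_sub:
        raise ValueError("thickness_voxels must be positive and fit above the substrate")
    rng = np.random.default_rng(seed)

    model_mask = np.zeros(dims, dtype=bool)
    model_mask[:, :, z_sub:] = True
    shell_mask = np.zeros(dims, dtype=bool)
    shell_mask[:, :, z_sub - thickness_voxels : z_sub] = True

    fixed_data = _render(model_mask, shell_mask, intens, noise_sd, rng)
    moving_data = _render(model_mask, None, intens, noise_sd, rng)

    thickness_map = np.full(dims, np.nan, dtype=np.float32)
    thickness_map[shell_mask] = thickness_voxels * voxel_size

    truth = PhantomGroundTruth(
        shell_mask=shell_mask,
        model_mask=model_mask,
        material_mask=model_mask | shell_mask,
        thickness_map_um=thickness_map,
        void_mask=np.zeros(dims, dtype=bool),
        gaps=[],
        rigid_offset=RigidTransform.identity(
            np.asarray(dims, dtype=float) * voxel_size / 2.0
        ),
        base_plane=CutPlane(axis=2, index=min(z_sub + 2, nz - 1), keep_side="low"),
        voxel_size=voxel_size,
        designed_thickness_um={
            "lateral": thickness_voxels * voxel_size,
            "occlusal": thickness_voxels * voxel_size,
            "base": thickness_voxels * voxel_size,
        },
    )
    return (
        VoxelVolume(moving_data, voxel_size, "slab model"),
        VoxelVolume(fixed_data, voxel_size, "slab model+shell"),
        truth,
    )
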