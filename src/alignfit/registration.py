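"""Rigid intensity-based 3D registration of paired tomograms.

The model (moving image) is aligned to the model+aligner scan (fixed image)
using only the base region — the bottom fraction of z slices, which is
aligner-free in both acquisitions, so the presence of the shell cannot bias
the alignment.  The metric is the mean squared gray-value difference,
minimised by a derivative-free Powell search over a multi-resolution pyramid
(>= 3 levels, factor-2 downsampling), starting from the identity.

A :class:`RigidTransform` maps moving-image physical coordinates to
fixed-image physical coordinates:  ``y = R (x - c) + c + t`` with ``R`` the
rotation about centre ``c`` and ``t`` the translation, all in micrometres.
Resampling the moving image onto the fixed grid therefore samples the moving
image at ``T^{-1}(y)`` for every fixed voxel centre ``y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .volume_io import CutPlane, VoxelVolume

__all__ = [
    "RigidTransform",
    "RegistrationError",
    "register_rigid",
    "apply_rigid",
    "transfer_plane",
]


class RegistrationError(RuntimeError):
    """Raised when the optimiser fails to converge at the finest level."""

    def __init__(self, message, last_params=None, last_metric=None):
        super().__init__(message)
        self.last_params = last_params
        self.last_metric = last_metric


@dataclass
class RigidTransform:
    """6-DOF rigid transform: Euler angles (deg) about a centre, plus translation.

    Angles follow the intrinsic x-y-z convention; translation and centre are
    in micrometres, physical coordinates (voxel centre ``i`` sits at
    ``(i + 0.5) * voxel_size``).
    """

    angles_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_um: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.translation_um = np.asarray(self.translation_um, dtype=float)
        self.center_um = np.asarray(self.center_um, dtype=float)

    @classmethod
    def identity(cls, center_um=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3), np.asarray(center_um, dtype=float))

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler("xyz", self.angles_deg, degrees=True)

    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    def apply_points(self, pts_um: np.ndarray) -> np.ndarray:
        """Map points (n, 3) from moving to fixed physical space (um)."""
        pts = np.atleast_2d(np.asarray(pts_um, dtype=float))
        return (pts - self.center_um) @ self.matrix().T + self.center_um + self.translation_um

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.inv()
        t_inv = -rot_inv.apply(self.translation_um)
        return RigidTransform(
            rot_inv.as_euler("xyz", degrees=True), t_inv, self.center_um.copy()
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``.

        Both must share the same centre.
        """
        if not np.allclose(self.center_um, other.center_um):
            raise ValueError("compose requires a common rotation centre")
        rot = self.rotation * other.rotation
        t = self.rotation.apply(other.translation_um) + self.translation_um
        return RigidTransform(rot.as_euler("xyz", degrees=True), t, self.center_um.copy())

    def to_dict(self) -> dict:
        return {
            "angles_deg": self.angles_deg.tolist(),
            "translation_um": self.translation_um.tolist(),
            "center_um": self.center_um.tolist(),
            "units": {"angles": "degrees", "translation": "micrometres"},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(d["angles_deg"], d["translation_um"], d["center_um"])


def _resample(
    data: np.ndarray,
    t: RigidTransform,
    voxel_size: float,
    order: int,
    output_shape=None,
    output_origin_vox=(0.0, 0.0, 0.0),
    cval: float = 0.0,
    output_stride=(1, 1, 1),
) -> np.ndarray:
    """Sample ``data`` (moving) on a fixed grid transformed by ``t``.

    ``output_origin_vox`` places the output grid inside the fixed image
    (index offset), letting a cropped region be resampled without slicing
    the moving image; ``output_stride`` decimates the output grid (used to
    cheapen metric evaluation at the finest pyramid level).
    """
    if output_shape is None:
        output_shape = data.shape
    R = t.matrix()
    s = voxel_size
    c = t.center_um
    tr = t.translation_um
    st = np.asarray(output_stride, dtype=float)
    # fixed index i = st*o + origin -> physical y = (i + 0.5) s ;
    # x = R^T (y - c - t) + c ; moving index j = x / s - 0.5
    o = np.asarray(output_origin_vox, dtype=float)
    offset = (R.T @ ((o + 0.5) * s - c - tr) + c) / s - 0.5
    matrix = R.T * st[None, :]
    return ndimage.affine_transform(
        data.astype(np.float32),
        matrix,
        offset=offset,
        output_shape=tuple(output_shape),
        order=order,
        mode="constant",
        cval=cval,
        prefilter=False,
    )


def apply_rigid(
    vol: VoxelVolume, t: RigidTransform, interpolation: str = "linear"
) -> VoxelVolume:
    """Resample ``vol`` (moving) onto the fixed grid under transform ``t``.

    Out-of-field voxels are set to the air value 0.
    """
    order = {"nearest": 0, "linear": 1}.get(interpolation)
    if order is None:
        raise ValueError("interpolation must be 'nearest' or 'linear'")
    out = _resample(vol.data, t, vol.voxel_size, order=order, cval=0.0)
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return VoxelVolume(out, vol.voxel_size, vol.name)


def _downsample(data: np.ndarray) -> np.ndarray:
    """Factor-2 block-mean downsampling (pads odd edges by replication)."""
    d = data.astype(np.float32)
    for ax in range(3):
        if d.shape[ax] % 2:
            pad = [(0, 0)] * 3
            pad[ax] = (0, 1)
            d = np.pad(d, pad, mode="edge")
    return 0.125 * (
        d[::2, ::2, ::2] + d[1::2, ::2, ::2] + d[::2, 1::2, ::2] + d[::2, ::2, 1::2]
        + d[1::2, 1::2, ::2] + d[1::2, ::2, 1::2] + d[::2, 1::2, 1::2]
        + d[1::2, 1::2, 1::2]
    )


def _base_region_bounds(shape, region) -> tuple[int, int]:
    """z-slice bounds [z0, z1) of the registration region."""
    nz = shape[2]
    if isinstance(region, CutPlane):
        if region.axis != 2:
            raise ValueError("base region plane must cut the z axis")
        z0 = region.index
    elif isinstance(region, float):
        z0 = int(round((1.0 - region) * nz))
    else:
        raise TypeError("region must be a CutPlane or a bottom fraction (float)")
    z0 = max(0, min(z0, nz - 1))
    return z0, nz


def register_rigid(
    fixed: VoxelVolume,
    moving: VoxelVolume,
    region=0.2,
    levels: int = 3,
    max_iters: int = 30,
    tol: float = 0.01,
) -> RigidTransform:
    """Rigidly register ``moving`` (model) to ``fixed`` (model+aligner).

    ``region`` selects the base: either a bottom fraction of z slices
    (default 0.2), a :class:`CutPlane` (keep the high-z side), or a boolean
    mask on the fixed grid.  Returns the 6-parameter transform minimising the
    mean squared gray-value difference over that region, found by Powell
    search through a ``levels``-deep factor-2 pyramid starting at identity.
    """
    if abs(fixed.voxel_size - moving.voxel_size) > 1e-9:
        raise ValueError("fixed and moving volumes must share a voxel size")
    s = fixed.voxel_size

    if isinstance(region, np.ndarray):
        zs = np.where(region.any(axis=(0, 1)))[0]
        if zs.size == 0:
            raise ValueError("empty registration region")
        z0, z1 = int(zs[0]), int(zs[-1]) + 1
        region_mask = region[:, :, z0:z1]
    else:
        z0, z1 = _base_region_bounds(fixed.shape, region)
        region_mask = None
    if z1 - z0 < 1:
        raise ValueError("empty registration region")

    center = fixed.physical_center_um()
    fixed_crop = fixed.data[:, :, z0:z1].astype(np.float32)
    moving_full = moving.data.astype(np.float32)

    # Pyramid (coarse last); crop and moving are downsampled together so the
    # physical transform parameters are level-independent.
    pyr: list[tuple[np.ndarray, np.ndarray, np.ndarray | None, float, float]] = []
    fc, mv, msk, vs, zoff = fixed_crop, moving_full, region_mask, s, float(z0)
    for _ in range(max(1, levels)):
        pyr.append((fc, mv, msk, vs, zoff))
        if min(fc.shape) < 8:
            break
        fc = _downsample(fc)
        mv = _downsample(mv)
        msk = None if msk is None else _downsample(msk.astype(np.float32)) > 0.5
        vs *= 2.0
        zoff /= 2.0

    sentinel = -1e4

    def make_cost(fc, mv, msk, vs, zoff, stride=(1, 1, 1)):
        origin = np.array([0.0, 0.0, zoff])
        sx, sy, sz = stride
        fc = fc[::sx, ::sy, ::sz]
        if msk is not None:
            msk = msk[::sx, ::sy, ::sz]

        def cost(p):
            t = RigidTransform(p[:3], p[3:] * s, center)
            res = _resample(mv, t, vs, order=1, output_shape=fc.shape,
                            output_origin_vox=origin, cval=sentinel,
                            output_stride=stride)
            valid = res > sentinel / 2
            if msk is not None:
                valid &= msk
            n = int(valid.sum())
            if n == 0:
                return np.inf
            diff = res[valid] - fc[valid]
            return float(np.mean(diff * diff))

        return cost

    # parameters: (rx, ry, rz) degrees, (tx, ty, tz) in fine-level voxels
    p = np.zeros(6)
    metric = None
    for li in range(len(pyr) - 1, -1, -1):
        # Fine-level metric on a 2x-decimated grid: full-resolution sampling
        # at a quarter of the cost, with no loss of optimum location.
        stride = (2, 2, 1) if li == 0 and min(fixed_crop.shape[:2]) >= 64 else (1, 1, 1)
        cost = make_cost(*pyr[li], stride=stride)
        res = optimize.minimize(
            cost,
            p,
            method="Powell",
            options={
                "maxiter": max_iters,
                "xtol": tol if li == 0 else tol * 5,
                "ftol": 1e-5,
            },
        )
        if li == 0 and not res.success:
            raise RegistrationError(
                f"registration did not converge: {res.message}",
                last_params=res.x,
                last_metric=res.fun,
            )
        p, metric = res.x, res.fun
        final_cost = cost

    # Metric-decrease guard: never return something worse than identity.
    if metric is not None and final_cost(np.zeros(6)) < metric:
        p = np.zeros(6)

    return RigidTransform(p[:3].copy(), p[3:] * s, center)


def transfer_plane(plane: CutPlane, t: RigidTransform, voxel_size: float = 33.0,
                   plane_center_xy_um=(0.0, 0.0)) -> CutPlane:
    """Transfer an axis-aligned cut plane through a near-identity transform.

    The transformed reference-plane centre is rounded to the nearest slice.
    Rotations >= 5 degrees invalidate the axis-aligned transfer and raise.
    """
    if np.max(np.abs(t.angles_deg)) >= 5.0:
        raise ValueError("transfer_plane requires rotation < 5 degrees")
    pt = np.zeros(3)
    pt[plane.axis] = (plane.index + 0.5) * voxel_size
    others = [a for a in range(3) if a != plane.axis]
    pt[others[0]], pt[others[1]] = plane_center_xy_um
    moved = t.apply_points(pt)[0]
    new_index = int(np.floor(moved[plane.axis] / voxel_size))
    return CutPlane(plane.axis, new_index, plane.keep_side)
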