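"""Volumetric image I/O with voxel-size bookkeeping.

All pipeline processing happens on 8-bit gray values because the fixed
segmentation thresholds (140/150/160) are 8-bit-scale numbers; 16-bit inputs
are linearly windowed to [0, 255] at load time.

Conventions
-----------
* Grid axes are ordered ``(x, y, z)`` with ``z`` the occluso-gingival axis;
  the model base sits at high ``z``.
* Voxel indices are 0-based; the physical position of the centre of voxel
  ``i`` along an axis is ``(i + 0.5) * voxel_size``.
* MHD/NIfTI headers store spacing in millimetres; TIFF stacks carry spacing
  in a JSON sidecar (``<stem>.json``) holding ``{"voxel_size_um": ...}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

__all__ = [
    "VoxelVolume",
    "CutPlane",
    "read_volume",
    "write_volume",
    "crop_at_plane",
    "SUPPORTED_FORMATS",
]

SUPPORTED_FORMATS = ("mhd", "nifti", "tiff")

_SUFFIX_TO_FORMAT = {
    ".mhd": "mhd",
    ".nii": "nifti",
    ".gz": "nifti",  # .nii.gz
    ".tif": "tiff",
    ".tiff": "tiff",
}


@dataclass
class VoxelVolume:
    """A 3D 8-bit gray-value grid with isotropic voxel size.

    Parameters
    ----------
    data:
        3D ``uint8`` array, axes ordered ``(x, y, z)``.
    voxel_size:
        Isotropic voxel edge length in micrometres (33 um for the reference
        acquisitions).
    name:
        Free-text specimen label, e.g. ``"NA.750 @ 176C"``.
    """

    data: np.ndarray
    voxel_size: float = 33.0
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("VoxelVolume requires a 3D grid with positive dimensions")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive (micrometres)")
        if self.data.dtype != np.uint8:
            arr = np.asarray(self.data)
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("gray values must lie in [0, 255]")
            self.data = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.voxel_size, self.name)

    def physical_center_um(self) -> np.ndarray:
        """Physical coordinates (um) of the grid centre."""
        return np.asarray(self.shape, dtype=float) * self.voxel_size / 2.0


@dataclass(frozen=True)
class CutPlane:
    """An axis-aligned plane used to crop or seal a volume.

    ``keep_side`` names the side of the plane that is retained: ``"low"``
    keeps indices ``< index`` (the occlusal/tooth side under the default
    axis convention), ``"high"`` keeps indices ``>= index``.
    """

    axis: int = 2
    index: int = 0
    keep_side: str = "low"

    def __post_init__(self) -> None:
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1, or 2")
        if self.keep_side not in ("low", "high"):
            raise ValueError("keep_side must be 'low' or 'high'")

    def validate_for(self, shape: tuple[int, int, int]) -> None:
        if not 0 <= self.index < shape[self.axis]:
            raise ValueError(
                f"plane index {self.index} outside extent {shape[self.axis]} "
                f"along axis {self.axis}"
            )

    def discarded_slice(self, shape: tuple[int, int, int]):
        """Index expression selecting the discarded side."""
        self.validate_for(shape)
        sl = [slice(None)] * 3
        if self.keep_side == "low":
            sl[self.axis] = slice(self.index, None)
        else:
            sl[self.axis] = slice(0, self.index)
        return tuple(sl)


def _infer_format(path: Path, format_hint: str | None) -> str:
    if format_hint is not None:
        fmt = format_hint.lower()
        if fmt not in SUPPORTED_FORMATS:
            raise ValueError(
                f"unsupported format {format_hint!r}; supported: {SUPPORTED_FORMATS}"
            )
        return fmt
    fmt = _SUFFIX_TO_FORMAT.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(
            f"cannot infer format from {path.name!r}; supported: {SUPPORTED_FORMATS}"
        )
    return fmt


def _window_to_uint8(arr: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    """Linearly map ``window`` (default min-max) to [0, 255]."""
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(np.float64)
    lo, hi = window if window is not None else (arr.min(), arr.max())
    if hi <= lo:
        raise ValueError("degenerate intensity window")
    out = (arr - lo) / (hi - lo) * 255.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def read_volume(
    path,
    format_hint: str | None = None,
    voxel_size_um: float | None = None,
    window: tuple[float, float] | None = None,
    name: str | None = None,
) -> VoxelVolume:
    """Read a volume from MHD/RAW, NIfTI-1, or a multipage TIFF stack.

    16-bit payloads are linearly windowed to [0, 255] (``window`` or min-max).
    ``voxel_size_um`` overrides or supplies spacing when the container does
    not encode it (e.g. a TIFF stack without a sidecar).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    fmt = _infer_format(path, format_hint)

    if fmt in ("mhd", "nifti"):
        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:  # pragma: no cover - corrupt file path
            raise IOError(f"failed to read volume {path}: {exc}") from exc
        spacing_mm = img.GetSpacing()
        if max(spacing_mm) - min(spacing_mm) > 1e-9 * max(spacing_mm):
            raise ValueError(
                f"anisotropic voxels {spacing_mm} in {path}; pipeline assumes isotropy"
            )
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        data = np.transpose(arr, (2, 1, 0))
        # headers store float32 mm; round to 0.1 nm to undo representation noise
        header_um = round(spacing_mm[0] * 1000.0, 4)
        vs = voxel_size_um if voxel_size_um is not None else header_um
    else:  # tiff
        arr = tifffile.imread(str(path))  # (z, y, x) pages
        if arr.ndim == 2:
            arr = arr[None]
        data = np.transpose(arr, (2, 1, 0))
        vs = voxel_size_um
        sidecar = path.with_suffix(".json")
        if vs is None and sidecar.exists():
            vs = json.loads(sidecar.read_text()).get("voxel_size_um")
        if vs is None:
            raise ValueError(
                f"voxel size not recoverable for TIFF stack {path}; "
                "supply voxel_size_um or a JSON sidecar"
            )

    data = _window_to_uint8(data, window)
    return VoxelVolume(data, float(vs), name if name is not None else path.stem)


def write_volume(vol: VoxelVolume, path, format: str | None = None) -> None:
    """Write a volume as MHD/RAW, NIfTI-1, or multipage TIFF (+ sidecar).

    The written file is readable by :func:`read_volume`; formats that encode
    spacing preserve the voxel size (TIFF uses a JSON sidecar).
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    fmt = _infer_format(path, format)

    if fmt in ("mhd", "nifti"):
        img = sitk.GetImageFromArray(np.transpose(vol.data, (2, 1, 0)))
        mm = vol.voxel_size / 1000.0
        img.SetSpacing((mm, mm, mm))
        sitk.WriteImage(img, str(path))
    else:
        tifffile.imwrite(str(path), np.transpose(vol.data, (2, 1, 0)))
        path.with_suffix(".json").write_text(
            json.dumps({"voxel_size_um": vol.voxel_size})
        )


def crop_at_plane(vol: VoxelVolume, plane: CutPlane, fill_value: int = 0) -> VoxelVolume:
    """Replace voxels on the discarded side of ``plane`` by ``fill_value``.

    Dimensions are unchanged; this mirrors the reference protocol of removing
    image content below a plane set 2 mm below the tooth-gingiva border.
    """
    if not 0 <= fill_value <= 255:
        raise ValueError("fill_value must be an 8-bit gray value")
    out = vol.copy()
    out.data[plane.discarded_slice(vol.shape)] = fill_value
    return out
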