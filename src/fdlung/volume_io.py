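"""Reading and writing 3D attenuation volumes and binary masks.

Supported formats: NIfTI-1 (``.nii``/``.nii.gz``, via nibabel), MetaImage
(``.mha``/``.mhd``, via SimpleITK) and raw binary with a JSON sidecar header.

Conventions
-----------
* Arrays are indexed ``[x, y, z]`` with 0-based voxel indices.
* Raw files store x fastest (Fortran order relative to the ``[x, y, z]``
  indexing); the sidecar schema is
  ``{"shape": [nx, ny, nz], "spacing_um": [sx, sy, sz], "dtype": "...",
  "byte_order": "little"|"big"}``.
* Voxel spacing is kept in micrometres. Raw files without a spacing entry
  default to 54 um isotropic, the scale of the micro-CT reconstructions this
  method was developed on.
* Attenuation values are relative Hounsfield units and are handled as real
  numbers throughout; no integer quantisation happens on load.
* Masks are serialised as 0/1 volumes in the same formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError, VolumeFormatError

__all__ = [
    "AttenuationVolume",
    "VoxelMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]

DEFAULT_SPACING_UM = (54.0, 54.0, 54.0)


@dataclass
class AttenuationVolume:
    """A 3D grid of attenuation values (relative HU) with voxel geometry.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Attenuation values, real-valued, finite.
    spacing : tuple of float
        Per-axis voxel edge length in micrometres, all positive.
    origin : tuple of float
        Physical offset of voxel (0, 0, 0), micrometres.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING_UM
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(
                f"attenuation volume must be 3D with all dims >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive lengths, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValidationError(f"volume contains {n_bad} non-finite voxel value(s)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class VoxelMask:
    """A 3D boolean occupancy grid, same shape as its parent volume."""

    data: np.ndarray = field()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValidationError(f"mask must be 3D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        """Number of voxels set in the mask."""
        return int(self.data.sum())


def _sniff_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    if name.endswith(".raw"):
        return "raw"
    raise VolumeFormatError(f"cannot infer volume format from file name: {path}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_volume(path: str | Path, format: str = "auto") -> AttenuationVolume:
    """Read a 3D attenuation volume.

    Parameters
    ----------
    path : path-like
        Input file. For ``raw``, a JSON sidecar ``<stem>.json`` must sit next
        to it.
    format : {"auto", "nifti", "metaimage", "raw"}
        ``auto`` sniffs from the file extension.

    Raises
    ------
    VolumeFormatError
        Unreadable/ill-formed file or metadata inconsistent with the payload.
    ValidationError
        The volume contains NaN/Inf voxels.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such volume file: {path}")
    fmt = _sniff_format(path) if format == "auto" else format

    if fmt == "nifti":
        import nibabel as nib

        try:
            img = nib.load(str(path))
        except Exception as exc:  # pragma: no cover - nibabel error text varies
            raise VolumeFormatError(f"could not read NIfTI file {path}: {exc}") from exc
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        zooms = img.header.get_zooms()[:3]
        return AttenuationVolume(data, spacing=tuple(float(z) for z in zooms))

    if fmt == "metaimage":
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:
            raise VolumeFormatError(f"could not read MetaImage file {path}: {exc}") from exc
        # SimpleITK arrays come back (z, y, x); transpose to our (x, y, z).
        data = sitk.GetArrayFromImage(img).astype(np.float64).transpose(2, 1, 0)
        spacing = tuple(float(s) for s in img.GetSpacing())
        origin = tuple(float(o) for o in img.GetOrigin())
        return AttenuationVolume(data, spacing=spacing, origin=origin)

    if fmt == "raw":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise VolumeFormatError(f"raw volume {path} is missing its JSON sidecar {sidecar}")
        try:
            header = json.loads(sidecar.read_text())
            shape = tuple(int(n) for n in header["shape"])
            dtype = np.dtype(header.get("dtype", "float32"))
        except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
            raise VolumeFormatError(f"bad sidecar header {sidecar}: {exc}") from exc
        if len(shape) != 3:
            raise VolumeFormatError(f"sidecar shape must have 3 entries, got {shape}")
        if header.get("byte_order", "little") == "big":
            dtype = dtype.newbyteorder(">")
        payload = np.fromfile(path, dtype=dtype)
        if payload.size != int(np.prod(shape)):
            raise VolumeFormatError(
                f"raw payload of {path} holds {payload.size} values, "
                f"sidecar shape {shape} needs {int(np.prod(shape))}"
            )
        data = payload.astype(np.float64).reshape(shape, order="F")
        spacing = tuple(float(s) for s in header.get("spacing_um", DEFAULT_SPACING_UM))
        return AttenuationVolume(data, spacing=spacing)

    raise VolumeFormatError(f"unknown volume format {fmt!r}")


def write_volume(volume: AttenuationVolume, path: str | Path, format: str = "auto") -> None:
    """Write a volume so that :func:`read_volume` round-trips values, shape
    and spacing to at least 32-bit float precision."""
    path = Path(path)
    fmt = _sniff_format(path) if format == "auto" else format
    data32 = volume.data.astype(np.float32)

    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag([*volume.spacing, 1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(data32, affine), str(path))
        return
    if fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(data32.transpose(2, 1, 0)))
        img.SetSpacing(tuple(volume.spacing))
        img.SetOrigin(tuple(volume.origin))
        sitk.WriteImage(img, str(path))
        return
    if fmt == "raw":
        header = {
            "shape": list(volume.shape),
            "spacing_um": list(volume.spacing),
            "dtype": "float32",
            "byte_order": "little",
        }
        data32.astype("<f4").ravel(order="F").tofile(path)
        _sidecar_path(path).write_text(json.dumps(header, indent=1))
        return
    raise VolumeFormatError(f"unknown volume format {fmt!r}")


def read_mask(path: str | Path, format: str = "auto") -> VoxelMask:
    """Read a 0/1 volume as a boolean mask (any value > 0.5 counts as set)."""
    vol = read_volume(path, format=format)
    return VoxelMask(vol.data > 0.5)


def write_mask(
    mask: VoxelMask,
    path: str | Path,
    format: str = "auto",
    spacing: tuple[float, float, float] = DEFAULT_SPACING_UM,
) -> None:
    """Write a mask as a 0/1 volume."""
    write_volume(AttenuationVolume(mask.data.astype(np.float64), spacing=spacing), path, format=format)
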