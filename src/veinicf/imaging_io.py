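"""Volume I/O, mask dilation and cross-section extraction.

Coordinate convention: volumes are indexed ``data[x, y, z]`` with voxel
centers at integer coordinates and grid lines at half-integers.  A
cross-section extracted along ``slice_axis`` keeps the two remaining axes in
order, so its local ``(px, py)`` plus the recorded crop offset reproduce the
global in-slice position exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .icf_core import CrossSection, MaskError

__all__ = [
    "Volume3D",
    "read_volume",
    "write_volume",
    "dilate_mask",
    "extract_sections",
    "principal_slice_axis",
]


@dataclass
class Volume3D:
    """A 3-D scalar volume with isotropic voxel size (mm)."""

    data: np.ndarray
    voxel_size: float = 1.0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume3D requires a 3-D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")


def read_volume(path) -> Volume3D:
    """Read a NIfTI-1 volume; warns when the voxels are anisotropic."""
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise IOError(f"could not read NIfTI volume {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise IOError(f"{path!r} is not a 3-D volume (shape {data.shape})")
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-3):
        warnings.warn(
            f"anisotropic voxels {zooms} in {path!r}: the cylindrical fit "
            "assumes isotropic voxels",
            RuntimeWarning,
            stacklevel=2,
        )
    return Volume3D(data=data, voxel_size=float(zooms[0]), affine=img.affine)


def write_volume(volume: Volume3D, path) -> None:
    """Write a volume as NIfTI-1, preserving data and voxel size."""
    affine = volume.affine
    if affine is None:
        affine = np.diag([volume.voxel_size] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data), affine)
    img.header.set_zooms((volume.voxel_size,) * 3)
    nib.save(img, str(path))


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connected


def dilate_mask(mask: np.ndarray, n_voxels: int) -> np.ndarray:
    """``n_voxels`` iterations of 6-connected binary dilation (0 = identity)."""
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("dilate_mask expects a 3-D mask")
    if n_voxels < 0:
        raise ValueError("n_voxels must be >= 0")
    if n_voxels == 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=_STRUCT6, iterations=n_voxels)


def principal_slice_axis(mask: np.ndarray) -> int:
    """Axis of the mask's longest extent — the default slicing direction."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise MaskError("empty mask")
    idx = np.argwhere(mask)
    extents = idx.max(axis=0) - idx.min(axis=0)
    return int(np.argmax(extents))


def extract_sections(
    volume: np.ndarray,
    vein_mask: np.ndarray,
    *,
    slice_axis: int = 2,
    dilate: int = 3,
    margin: int = 6,
) -> list[CrossSection]:
    """Cut per-slice crops around a vein for the cylindrical fit.

    The vein mask is dilated (3-D, 6-connected, ``dilate`` iterations); every
    slice along ``slice_axis`` that intersects the *undilated* mask yields one
    :class:`CrossSection` cropped to the dilated mask's bounding box plus
    ``margin`` voxels, clipped at the volume edge (flagged via
    ``edge_clipped``).  The dilated mask becomes the initial partial-volume
    support; everything else in the crop is background ROI.
    """
    volume = np.asarray(volume)
    vein_mask = np.asarray(vein_mask).astype(bool)
    if volume.shape != vein_mask.shape:
        raise ValueError("volume and mask shapes differ")
    if volume.ndim != 3:
        raise ValueError("expected 3-D inputs")
    if not vein_mask.any():
        raise MaskError("vein mask does not intersect the volume")

    dil = dilate_mask(vein_mask, dilate)
    vol = np.moveaxis(volume, slice_axis, 2)
    msk = np.moveaxis(vein_mask, slice_axis, 2)
    dmk = np.moveaxis(dil, slice_axis, 2)

    sections: list[CrossSection] = []
    for k in range(vol.shape[2]):
        if not msk[:, :, k].any():
            continue
        d2 = dmk[:, :, k]
        idx = np.argwhere(d2)
        x_lo, y_lo = idx.min(axis=0)
        x_hi, y_hi = idx.max(axis=0)
        x0 = x_lo - margin
        y0 = y_lo - margin
        x1 = x_hi + margin + 1
        y1 = y_hi + margin + 1
        clipped = x0 < 0 or y0 < 0 or x1 > d2.shape[0] or y1 > d2.shape[1]
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, d2.shape[0]), min(y1, d2.shape[1])
        init = d2[x0:x1, y0:y1]
        sections.append(
            CrossSection(
                pixels=vol[x0:x1, y0:y1, k],
                init_mask=init,
                background_roi=~init,
                offset=(int(x0), int(y0)),
                slice_index=int(k),
                edge_clipped=bool(clipped),
            )
        )
    if not sections:
        raise MaskError("vein mask does not intersect any slice")
    return sections
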