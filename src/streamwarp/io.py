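"""Readers/writers for streamlines, volumes, displacement fields and labels.

All conversions into the canonical frame (world RAS mm, voxel-center
affines) happen here and only here:

* TRK stores points in corner-offset voxel-mm with an arbitrary voxel
  order; nibabel's streamline API resolves both on load/save, and this
  module additionally cross-checks the header's voxel order against its
  affine instead of silently trusting one of them.
* TCK stores points directly in RAS mm but carries no reference image;
  pass ``reference`` to attach grid metadata.
* Displacement fields saved by LPS-convention tools (ITK/ANTs lineage)
  have their first two vector components negated on read
  (``dialect="lps_mm"``).
"""

from __future__ import annotations

import os
import warnings

import nibabel as nib
import numpy as np
from nibabel.orientations import aff2axcodes
from nibabel.streamlines import TckFile, TrkFile
from nibabel.streamlines.tractogram import Tractogram as NibTractogram

from .core import DimensionError, FormatError, Tractogram, VolumeGrid
from .transforms import DisplacementField

__all__ = [
    "read_tractogram",
    "write_tractogram",
    "read_volume",
    "write_volume",
    "read_displacement_field",
    "write_displacement_field",
]

_DIALECTS = {"trk": TrkFile, "tck": TckFile}


def _infer_dialect(path) -> str:
    ext = os.path.splitext(str(path))[1].lower().lstrip(".")
    if ext not in _DIALECTS:
        raise FormatError(f"cannot infer streamline dialect from extension {ext!r}")
    return ext


def read_tractogram(path, dialect: str | None = None,
                    reference: VolumeGrid | None = None,
                    space_tag: str = "native") -> Tractogram:
    """Load a TRK or TCK file as a Tractogram in world RAS mm.

    ``dialect`` defaults to the file extension.  A file whose on-disk magic
    does not match the requested dialect, or a TRK header whose voxel-order
    field disagrees with its voxel-to-RAS affine, raises :class:`FormatError`.
    A file with zero streamlines is returned (with valid metadata) under a
    warning rather than an error.
    """
    dialect = dialect or _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown streamline dialect {dialect!r}")
    cls = _DIALECTS[dialect]
    with open(path, "rb") as f:
        if not cls.is_correct_format(f):
            raise FormatError(
                f"{path} is not a valid {dialect.upper()} file (magic/header "
                "field mismatch)"
            )
    sf = nib.streamlines.load(str(path))
    header = sf.header
    if dialect == "trk":
        affine = np.asarray(header["voxel_to_rasmm"], dtype=float)
        shape = tuple(int(d) for d in header["dimensions"])
        stored_order = header.get("voxel_order", b"")
        if isinstance(stored_order, bytes):
            stored_order = stored_order.decode("latin1").strip("\x00")
        if stored_order:
            expected = "".join(aff2axcodes(affine))
            if stored_order.upper() != expected:
                raise FormatError(
                    f"TRK header field 'voxel_order' is {stored_order!r} but "
                    f"the 'voxel_to_ras' affine implies {expected!r}"
                )
    else:
        if reference is not None:
            affine, shape = reference.affine, reference.shape
        else:
            affine, shape = np.eye(4), (1, 1, 1)
    if reference is not None:
        affine, shape = reference.affine, reference.shape
    streamlines = [np.asarray(s, dtype=np.float64)
                   for s in sf.tractogram.streamlines]
    if not streamlines:
        warnings.warn(f"{path} contains zero streamlines", stacklevel=2)
    return Tractogram(streamlines, space_tag=space_tag,
                      reference_affine=affine, reference_shape=shape)


def write_tractogram(t: Tractogram, path, dialect: str | None = None):
    """Write a Tractogram as TRK or TCK; round-trips within 1e-5 mm.

    Points are handed to nibabel in RAS mm; the TRK writer derives voxel
    sizes, dimensions and voxel order from the tractogram's reference grid.
    Streamline files store float32, so the round-trip guarantee assumes
    coordinates of laboratory magnitude (|x| < ~1e2 mm).
    """
    dialect = dialect or _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown streamline dialect {dialect!r}")
    nt = NibTractogram(t.streamlines, affine_to_rasmm=np.eye(4))
    if dialect == "trk":
        affine = t.reference_affine
        header = {
            "voxel_to_rasmm": affine.astype(np.float32),
            "voxel_sizes": np.linalg.norm(affine[:3, :3], axis=0).astype(
                np.float32),
            "dimensions": np.asarray(t.reference_shape, dtype=np.int16),
            "voxel_order": "".join(aff2axcodes(affine)),
        }
        TrkFile(nt, header=header).save(str(path))
    else:
        TckFile(nt).save(str(path))
    return path


def read_volume(path, space_tag: str = "native") -> VolumeGrid:
    """Load a 3-D NIfTI volume; the affine maps voxel centers to RAS mm."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    # tolerate trailing singleton dims (some tools save 3-D as (X, Y, Z, 1))
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionError(
            f"{path}: expected a 3-D volume, got shape {data.shape}"
        )
    return VolumeGrid(data, np.asarray(img.affine, dtype=float),
                      space_tag=space_tag)


def write_volume(grid: VolumeGrid, path):
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, grid.affine), str(path))
    return path


def read_displacement_field(path, dialect: str = "ras_mm") -> DisplacementField:
    """Load a dense displacement field from a 4-D (or 5-D ITK-style) NIfTI.

    The last axis must hold exactly 3 vector components per voxel; a
    singleton "time" axis (ITK writes (X, Y, Z, 1, 3)) is squeezed.  With
    ``dialect="lps_mm"`` the first two components are negated to convert
    LPS-mm vectors to canonical RAS mm.
    """
    if dialect not in ("ras_mm", "lps_mm"):
        raise FormatError(f"unknown displacement dialect {dialect!r}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 5 and data.shape[3] == 1:
        data = data[:, :, :, 0, :]
    if data.ndim != 4:
        raise FormatError(
            f"{path}: displacement field must be 4-D, got shape {data.shape}"
        )
    if data.shape[-1] != 3:
        raise FormatError(
            f"{path}: expected 3 vector components per voxel, got "
            f"{data.shape[-1]}"
        )
    if dialect == "lps_mm":
        data = data.copy()
        data[..., 0] *= -1.0
        data[..., 1] *= -1.0
    return DisplacementField(data, np.asarray(img.affine, dtype=float))


def write_displacement_field(field: DisplacementField, path,
                             dialect: str = "ras_mm"):
    if dialect not in ("ras_mm", "lps_mm"):
        raise FormatError(f"unknown displacement dialect {dialect!r}")
    data = field.vectors
    if dialect == "lps_mm":
        data = data.copy()
        data[..., 0] *= -1.0
        data[..., 1] *= -1.0
    nib.save(nib.Nifti1Image(data.astype(np.float64), field.affine), str(path))
    return path
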