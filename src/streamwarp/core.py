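"""Core containers and conventions shared by every streamwarp module.

Everything downstream works in one canonical frame: world RAS millimeters,
0-based voxel indices, and voxel-to-world affines that map voxel *centers*.
File-format quirks (TRK's corner offset, LPS-stored vectors) are resolved at
I/O time and never leak past :mod:`streamwarp.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StreamwarpError",
    "FormatError",
    "DimensionError",
    "OutOfBoundsError",
    "ConvergenceError",
    "SpaceMismatchError",
    "round_half_away",
    "VolumeGrid",
    "LabelTable",
    "Tractogram",
]


class StreamwarpError(Exception):
    """Base class for all streamwarp errors."""


class FormatError(StreamwarpError):
    """A file violates its declared dialect (names the offending field)."""


class DimensionError(StreamwarpError):
    """Array dimensionality does not match what the operation expects."""


class OutOfBoundsError(StreamwarpError):
    """A point left the interpolation hull of a displacement field."""


class ConvergenceError(StreamwarpError):
    """An iterative procedure failed to reach its tolerance."""


class SpaceMismatchError(StreamwarpError):
    """Objects tagged with different coordinate spaces were combined."""


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero.

    This is the pinned rounding rule for continuous-voxel-coordinate to
    voxel-index conversion throughout the package (label transfer, endpoint
    assignment, rasterization).  Unlike banker's rounding it is symmetric
    about zero and independent of any locale or FPU mode.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _check_affine(affine: np.ndarray, name: str = "affine") -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise DimensionError(f"{name} must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise ValueError(f"{name} contains non-finite entries")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise np.linalg.LinAlgError(f"{name} is singular")
    return affine


@dataclass
class VolumeGrid:
    """A scalar or integer 3-D image: data array + voxel-to-world affine.

    The affine maps 0-based voxel centers to world RAS mm.  ``space_tag``
    records which coordinate space the grid lives in (``"native"`` or
    ``"template"``); it is carried along so that mixing spaces is caught
    early instead of producing silently wrong connectomes.
    """

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionError(
                f"VolumeGrid needs 3-D data, got {self.data.ndim}-D"
            )
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def like(self, data: np.ndarray, space_tag: str | None = None) -> "VolumeGrid":
        """A new grid with the same geometry but different voxel data."""
        return VolumeGrid(data, self.affine.copy(),
                          space_tag=self.space_tag if space_tag is None else space_tag)

    def padded(self, pad: int, space_tag: str | None = None) -> "VolumeGrid":
        """An empty grid extended by ``pad`` voxels on every face.

        The world position of existing voxels is unchanged (the origin
        shifts by ``-pad`` voxels).  Used to build template grids whose
        field of view covers content that a warp pushes past the source
        FOV.
        """
        if pad < 0:
            raise ValueError("pad must be >= 0")
        affine = self.affine.copy()
        affine[:3, 3] -= affine[:3, :3] @ np.full(3, float(pad))
        shape = tuple(s + 2 * pad for s in self.shape)
        return VolumeGrid(np.zeros(shape, dtype=self.data.dtype), affine,
                          space_tag=self.space_tag if space_tag is None
                          else space_tag)


@dataclass
class LabelTable:
    """Region lookup: positive integer label ids with names, 0 = background."""

    ids: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        if self.ids.ndim != 1 or len(self.ids) != len(self.names):
            raise ValueError("ids and names must be parallel 1-D sequences")
        if np.any(self.ids <= 0):
            raise ValueError("label ids must be positive (0 is background)")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("label ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, label: int) -> bool:
        return bool(np.isin(label, self.ids))

    @classmethod
    def sequential(cls, n_regions: int, prefix: str = "region") -> "LabelTable":
        ids = np.arange(1, n_regions + 1)
        return cls(ids, [f"{prefix}_{i:03d}" for i in ids])

    @classmethod
    def from_tsv(cls, path) -> "LabelTable":
        df = pd.read_csv(path, sep="\t")
        missing = {"label_id", "name"} - set(df.columns)
        if missing:
            raise FormatError(f"label table missing columns: {sorted(missing)}")
        return cls(df["label_id"].to_numpy(), df["name"].astype(str).tolist())

    def to_tsv(self, path) -> None:
        pd.DataFrame({"label_id": self.ids, "name": self.names}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class Tractogram:
    """An ordered collection of streamlines in world RAS mm.

    Each streamline is an (n_i, 3) float64 array with n_i >= 2.  The
    reference affine/shape describe the image grid that defines the space
    the streamlines live in (used for endpoint assignment and
    rasterization); they are metadata, not a bounding constraint.
    """

    streamlines: list[np.ndarray]
    space_tag: str = "native"
    reference_affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    reference_shape: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        cleaned = []
        for i, sl in enumerate(self.streamlines):
            arr = np.asarray(sl, dtype=np.float64)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise DimensionError(f"streamline {i} is not an (n, 3) array")
            if arr.shape[0] < 2:
                raise ValueError(f"streamline {i} has fewer than 2 points")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"streamline {i} contains non-finite coordinates")
            cleaned.append(arr)
        self.streamlines = cleaned
        self.reference_affine = _check_affine(self.reference_affine,
                                              "reference_affine")
        shape = tuple(int(s) for s in self.reference_shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError("reference_shape must be 3 positive integers")
        self.reference_shape = shape

    def __len__(self) -> int:
        return len(self.streamlines)

    @property
    def n_points(self) -> int:
        return sum(len(sl) for sl in self.streamlines)

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends): the first and last point of every streamline."""
        if not self.streamlines:
            empty = np.empty((0, 3))
            return empty, empty.copy()
        starts = np.array([sl[0] for sl in self.streamlines])
        ends = np.array([sl[-1] for sl in self.streamlines])
        return starts, ends

    def concatenated(self) -> tuple[np.ndarray, np.ndarray]:
        """All points stacked (total, 3) plus per-streamline offsets for
        splitting back (`np.split(points, offsets[1:-1])`)."""
        lengths = [len(sl) for sl in self.streamlines]
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        if not self.streamlines:
            return np.empty((0, 3)), offsets
        return np.vstack(self.streamlines), offsets
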