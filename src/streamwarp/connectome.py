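"""Streamline-count connectomes and edge density images.

Endpoints (the exact first and last point of each streamline — no search
radius) are mapped to parcellation labels by voxel lookup; every streamline
whose two endpoints fall in two *different* regions increments the
symmetric count matrix M_ij = M_ji.  Streamlines with an endpoint in
background/outside the grid, or with both endpoints in one region,
contribute nothing.  Streamlines are unoriented, so the matrix is
undirected with a zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    LabelTable,
    SpaceMismatchError,
    StreamwarpError,
    Tractogram,
    VolumeGrid,
    round_half_away,
)
from .labels import Parcellation
from .transforms import voxel_from_world

__all__ = [
    "EndpointAssignment",
    "ConnectivityMatrix",
    "assign_endpoints",
    "build_connectivity_matrix",
    "edge_density_image",
]


@dataclass
class EndpointAssignment:
    """Per-streamline (start, end) region labels; 0 means unassigned."""

    start_labels: np.ndarray
    end_labels: np.ndarray

    def __post_init__(self) -> None:
        self.start_labels = np.asarray(self.start_labels, dtype=np.int64)
        self.end_labels = np.asarray(self.end_labels, dtype=np.int64)
        if self.start_labels.shape != self.end_labels.shape:
            raise ValueError("start/end label arrays must have equal length")

    def __len__(self) -> int:
        return len(self.start_labels)


@dataclass
class ConnectivityMatrix:
    """N x N symmetric nonnegative-integer streamline counts M_ij."""

    counts: np.ndarray
    node_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        n = len(self.node_ids)
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{n} node ids"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise TypeError("connectivity counts must be integers")
        if np.any(self.counts < 0):
            raise ValueError("connectivity counts must be nonnegative")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("connectivity diagonal must be zero")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts, index=self.node_ids,
                     columns=self.node_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=np.int64),
                   np.asarray(df.index, dtype=np.int64))


def _labels_at(points: np.ndarray, p: Parcellation) -> np.ndarray:
    """Label of the voxel containing each world point (0 if outside)."""
    if len(points) == 0:
        return np.zeros(0, dtype=np.int64)
    voxel = round_half_away(
        voxel_from_world(points, p.labels.affine)
    ).astype(np.int64)
    shape = np.asarray(p.labels.shape)
    inside = np.all((voxel >= 0) & (voxel < shape), axis=1)
    out = np.zeros(len(points), dtype=np.int64)
    if inside.any():
        v = voxel[inside]
        out[inside] = p.labels.data[v[:, 0], v[:, 1], v[:, 2]]
    return out


def assign_endpoints(t: Tractogram, p: Parcellation) -> EndpointAssignment:
    """Map each streamline's first and last point to a region label.

    Requires tractogram and parcellation to carry the same space tag — the
    guard that stops native-space streamlines from being counted against a
    template-space parcellation.
    """
    if t.space_tag != p.space_tag:
        raise SpaceMismatchError(
            f"tractogram is in {t.space_tag!r} space but parcellation is in "
            f"{p.space_tag!r} space"
        )
    starts, ends = t.endpoints()
    return EndpointAssignment(_labels_at(starts, p), _labels_at(ends, p))


def build_connectivity_matrix(
    a: EndpointAssignment, nodes: LabelTable
) -> ConnectivityMatrix:
    """Count streamlines per region pair into a symmetric N x N matrix.

    Only streamlines with both endpoints assigned to two different regions
    are counted (once in M_ij and once in M_ji); the off-diagonal sum is
    therefore exactly twice the number of counted streamlines.
    """
    node_ids = np.asarray(nodes.ids, dtype=np.int64)
    index = {int(lab): i for i, lab in enumerate(node_ids)}
    n = len(node_ids)
    counts = np.zeros((n, n), dtype=np.int64)
    used = np.unique(np.concatenate([a.start_labels, a.end_labels]))
    unknown = np.setdiff1d(used[used != 0], node_ids)
    if unknown.size:
        raise StreamwarpError(
            f"endpoint labels {unknown.tolist()} are not in the node table"
        )
    keep = (a.start_labels != 0) & (a.end_labels != 0) & \
        (a.start_labels != a.end_labels)
    if keep.any():
        i = np.array([index[int(l)] for l in a.start_labels[keep]])
        j = np.array([index[int(l)] for l in a.end_labels[keep]])
        np.add.at(counts, (i, j), 1)
        np.add.at(counts, (j, i), 1)
    return ConnectivityMatrix(counts, node_ids)


def edge_density_image(
    t: Tractogram,
    a: EndpointAssignment,
    grid: VolumeGrid,
    edge_filter: tuple[int, int] | None = None,
) -> VolumeGrid:
    """Voxel map of how many network-edge streamlines traverse each voxel.

    Only streamlines with both endpoints assigned to distinct regions
    (optionally restricted to one unordered region pair) contribute; each
    contributes at most 1 per voxel regardless of how many of its points
    fall there.  Paths are rasterized by marking the voxel of every
    streamline point, so point spacing at or below half a voxel keeps the
    trace near-contiguous.
    """
    if len(a) != len(t):
        raise ValueError("assignment length does not match streamline count")
    if t.space_tag != grid.space_tag:
        raise SpaceMismatchError(
            f"tractogram space {t.space_tag!r} != grid space "
            f"{grid.space_tag!r}"
        )
    density = np.zeros(grid.shape, dtype=np.int64)
    shape = np.asarray(grid.shape)
    wanted = None
    if edge_filter is not None:
        wanted = frozenset(int(x) for x in edge_filter)
        if len(wanted) != 2:
            raise ValueError("edge_filter must name two distinct regions")
    for sl, s_lab, e_lab in zip(t.streamlines, a.start_labels, a.end_labels):
        if s_lab == 0 or e_lab == 0 or s_lab == e_lab:
            continue
        if wanted is not None and {int(s_lab), int(e_lab)} != wanted:
            continue
        voxel = round_half_away(
            voxel_from_world(sl, grid.affine)
        ).astype(np.int64)
        inside = np.all((voxel >= 0) & (voxel < shape), axis=1)
        if not inside.any():
            continue
        uniq = np.unique(voxel[inside], axis=0)
        density[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    return grid.like(density)
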