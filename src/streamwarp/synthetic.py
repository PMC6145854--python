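"""Seeded synthetic phantoms: bundles, block parcellations, smooth warps.

Real evaluation of streamline normalization needs tractography, an
anatomical parcellation and a registration warp.  This module fabricates
all three with known ground truth so every other module is testable
offline:

* **Block parcellations** tile the grid into rectangular regions
  (default 129, the size of the Lausanne scale-60 atlas used for
  structural connectomes).
* **Fiber phantoms** are bundles of jittered quadratic Bezier curves whose
  endpoints sit exactly on voxel centers inside two designated regions —
  so the ground-truth connectivity matrix is known by construction.
* **Synthetic warps** are separable sinusoidal displacement fields
  ``d_c(x) = a sin(k x_c + phi_c)``; the bound ``a * k < 1`` makes the
  Jacobian ``prod_c (1 + a k cos(...))`` positive everywhere, so the warp
  is guaranteed diffeomorphic by construction rather than by post-hoc
  checking.

Everything is driven by explicit integer seeds; the same spec always
reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import ConnectivityMatrix
from .core import LabelTable, StreamwarpError, Tractogram, VolumeGrid
from .labels import Parcellation
from .transforms import AffineTransform, DisplacementField, world_from_voxel

__all__ = [
    "PhantomSpec",
    "WarpSpec",
    "SpecError",
    "make_block_parcellation",
    "make_phantom_tractogram",
    "make_synthetic_warp",
    "jacobian_determinant",
]


class SpecError(StreamwarpError):
    """A synthetic-data specification is unsatisfiable."""


def _spacing_affine(spacing) -> np.ndarray:
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), 3)
    if np.any(spacing <= 0):
        raise SpecError("voxel spacing must be positive")
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    return aff


@dataclass
class PhantomSpec:
    """Recipe for a multi-bundle fiber phantom with known connectivity.

    Sizes default to a desk-scale stand-in for a whole-brain dataset: a
    48^3 grid at 1.25 mm isotropic spacing (a typical high-resolution
    diffusion voxel size), 129 block regions, and bundles of a few hundred
    streamlines.  ``jitter_sd`` (mm) perturbs interior curve points only;
    endpoints stay exactly on voxel centers inside their designated
    regions, which is what makes exact connectome recovery possible under
    a collision-free warp.
    """

    n_bundles: int = 5
    streamlines_per_bundle: int = 200
    jitter_sd: float = 0.5
    arc_fraction: float = 0.25
    endpoint_margin: int = 2
    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: float = 1.25
    n_regions: int = 129
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bundles < 1 or self.streamlines_per_bundle < 1:
            raise SpecError("need at least one bundle and one streamline")
        if self.jitter_sd < 0:
            raise SpecError("jitter_sd must be >= 0")


@dataclass
class WarpSpec:
    """Recipe for a guaranteed-diffeomorphic synthetic displacement field.

    ``kind="sinusoidal"``: per-component sinusoid with amplitude (mm),
    spatial frequency (1/mm) and seeded random phases; requires
    ``amplitude * frequency < 1``.  ``kind="affine"``: the affine's
    displacement ``A x - x`` sampled on the grid (a translation gives a
    constant field).  ``kind="composed"``: affine plus sinusoid.
    """

    kind: str = "sinusoidal"
    amplitude: float = 2.0
    frequency: float = 0.1
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: float = 1.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("affine", "sinusoidal", "composed"):
            raise SpecError(f"unknown warp kind {self.kind!r}")
        if self.kind in ("sinusoidal", "composed"):
            if self.amplitude < 0 or self.frequency <= 0:
                raise SpecError("need amplitude >= 0 and frequency > 0")
            if self.amplitude * self.frequency >= 1.0:
                raise SpecError(
                    "amplitude * frequency must be < 1 for a guaranteed "
                    f"diffeomorphism (got {self.amplitude * self.frequency:g})"
                )


def _block_splits(shape: tuple[int, ...], n_regions: int) -> tuple[int, int, int]:
    """Most-cubic axis split (a, b, c) with a*b*c >= n_regions."""
    best = None
    for a in range(1, min(shape[0], n_regions) + 1):
        need_bc = -(-n_regions // a)
        for b in range(1, min(shape[1], n_regions) + 1):
            c = -(-need_bc // b)
            if c > shape[2] or c < 1:
                continue
            # balance tiling economy (few surplus blocks) against block
            # isotropy; slab-thin regions make poor phantom endpoints
            sizes = (shape[0] / a, shape[1] / b, shape[2] / c)
            key = a * b * c * (max(sizes) / min(sizes))
            if best is None or key < best[0]:
                best = (key, (a, b, c))
    if best is None:
        raise SpecError(
            f"cannot tile {n_regions} regions onto a grid of shape {shape}"
        )
    return best[1]


def make_block_parcellation(
    shape: tuple[int, int, int],
    n_regions: int = 129,
    spacing: float = 1.25,
    affine: np.ndarray | None = None,
    space_tag: str = "native",
) -> Parcellation:
    """Tile the grid into ``n_regions`` rectangular blocks, labels 1..n.

    When the best tiling produces more blocks than regions, the surplus
    blocks stay background (0), so the label histogram has exactly
    ``n_regions`` nonzero bins.
    """
    shape = tuple(int(s) for s in shape)
    if n_regions < 1 or n_regions > int(np.prod(shape)):
        raise SpecError(
            f"cannot fit {n_regions} regions into {np.prod(shape)} voxels"
        )
    a, b, c = _block_splits(shape, n_regions)
    edges = [np.linspace(0, s, k + 1).astype(int)
             for s, k in zip(shape, (a, b, c))]
    labels = np.zeros(shape, dtype=np.int32)
    label = 1
    for i in range(a):
        for j in range(b):
            for k in range(c):
                if label > n_regions:
                    break
                labels[edges[0][i]:edges[0][i + 1],
                       edges[1][j]:edges[1][j + 1],
                       edges[2][k]:edges[2][k + 1]] = label
                label += 1
    if affine is None:
        affine = _spacing_affine(spacing)
    grid = VolumeGrid(labels, affine, space_tag=space_tag)
    return Parcellation(grid, LabelTable.sequential(n_regions))


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
            n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * t * (1 - t) * p1 + (t ** 2) * p2


def make_phantom_tractogram(
    spec: PhantomSpec,
) -> tuple[Tractogram, ConnectivityMatrix, Parcellation]:
    """Generate bundles between designated region pairs + ground truth.

    Each bundle connects one unordered pair of regions (pairs sampled
    without replacement); each of its streamlines runs from a random voxel
    center inside the first region to one inside the second along a curved
    (quadratic Bezier) path with Gaussian jitter on interior points.
    Endpoint voxels are sampled at least ``endpoint_margin`` voxels away
    from their region's faces (termination zones well inside the region);
    with margin m, no differently labeled source voxel can be carried onto
    an endpoint's target voxel by any warp whose compression stays below
    m/(m+1) per axis — the construction that makes exact connectome
    recovery after warping achievable.
    Point spacing is at most half a voxel.  The returned ground-truth
    matrix counts ``streamlines_per_bundle`` for every bundle pair — by
    construction it equals what endpoint assignment + matrix building
    recover in native space.
    """
    rng = np.random.default_rng(spec.seed)
    parc = make_block_parcellation(spec.shape, spec.n_regions, spec.spacing)
    affine = parc.labels.affine
    n = spec.n_regions
    n_pairs_all = n * (n - 1) // 2
    if spec.n_bundles > n_pairs_all:
        raise SpecError("more bundles than distinct region pairs")
    iu = np.triu_indices(n, k=1)
    chosen = rng.choice(n_pairs_all, size=spec.n_bundles, replace=False)
    pairs = [(int(parc.table.ids[iu[0][c]]), int(parc.table.ids[iu[1][c]]))
             for c in chosen]

    def interior(lab: int) -> np.ndarray:
        vox = np.argwhere(parc.labels.data == lab)
        m = spec.endpoint_margin
        if m > 0:
            lo, hi = vox.min(axis=0), vox.max(axis=0)
            keep = np.all((vox >= lo + m) & (vox <= hi - m), axis=1)
            if keep.any():
                return vox[keep]
        return vox

    region_voxels = {int(lab): interior(int(lab)) for lab in parc.table.ids}
    min_spacing = float(np.min(parc.labels.spacing))
    step = 0.5 * min_spacing
    extent_lo = world_from_voxel(np.zeros((1, 3)), affine)[0]
    extent_hi = world_from_voxel(
        np.asarray(spec.shape, dtype=float)[None] - 1, affine)[0]

    streamlines: list[np.ndarray] = []
    counts = np.zeros((n, n), dtype=np.int64)
    for r1, r2 in pairs:
        vox1, vox2 = region_voxels[r1], region_voxels[r2]
        arc_dir = rng.standard_normal(3)
        arc_dir /= np.linalg.norm(arc_dir)
        for _ in range(spec.streamlines_per_bundle):
            s_vox = vox1[rng.integers(len(vox1))]
            e_vox = vox2[rng.integers(len(vox2))]
            s = world_from_voxel(s_vox[None].astype(float), affine)[0]
            e = world_from_voxel(e_vox[None].astype(float), affine)[0]
            if np.allclose(s, e):
                raise SpecError("degenerate bundle: coincident endpoints")
            chord = e - s
            perp = arc_dir - (arc_dir @ chord) * chord / (chord @ chord)
            norm = np.linalg.norm(perp)
            if norm > 1e-12:
                perp /= norm
            ctrl = 0.5 * (s + e) + spec.arc_fraction * np.linalg.norm(chord) * perp
            ctrl = np.clip(ctrl, extent_lo, extent_hi)
            length = np.linalg.norm(ctrl - s) + np.linalg.norm(e - ctrl)
            n_pts = max(int(np.ceil(length / step)) + 1, 2)
            pts = _bezier(s, ctrl, e, n_pts)
            if spec.jitter_sd > 0 and n_pts > 2:
                pts[1:-1] += rng.normal(0.0, spec.jitter_sd,
                                        size=(n_pts - 2, 3))
                np.clip(pts, extent_lo, extent_hi, out=pts)
            pts[0], pts[-1] = s, e
            streamlines.append(pts)
        i, j = int(np.where(parc.table.ids == r1)[0][0]), \
            int(np.where(parc.table.ids == r2)[0][0])
        counts[i, j] += spec.streamlines_per_bundle
        counts[j, i] += spec.streamlines_per_bundle

    t = Tractogram(streamlines, space_tag="native",
                   reference_affine=affine, reference_shape=spec.shape)
    truth = ConnectivityMatrix(counts, parc.table.ids)
    return t, truth, parc


def make_synthetic_warp(spec: WarpSpec) -> DisplacementField:
    """Build the displacement field described by ``spec`` on its grid."""
    affine = _spacing_affine(spec.spacing)
    idx = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in spec.shape],
                    indexing="ij"),
        axis=-1,
    )
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    vectors = np.zeros_like(world)
    if spec.kind in ("affine", "composed"):
        A = AffineTransform(spec.affine)
        flat = world.reshape(-1, 3)
        vectors += (A.apply(flat) - flat).reshape(world.shape)
    if spec.kind in ("sinusoidal", "composed"):
        rng = np.random.default_rng(spec.seed)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
        vectors += spec.amplitude * np.sin(
            spec.frequency * world + phases
        )
    field = DisplacementField(vectors, affine)
    if spec.kind == "composed":
        det = jacobian_determinant(field).data
        if det.min() <= 0:
            raise SpecError(
                "composed warp is not diffeomorphic on its grid "
                f"(min Jacobian determinant {det.min():.3g})"
            )
    return field


def jacobian_determinant(field: DisplacementField) -> VolumeGrid:
    """Voxelwise determinant of the warp Jacobian d(x + d(x))/dx.

    Central differences along each grid axis of the mapped positions,
    converted to world derivatives through the grid affine.  The identity
    field gives 1 everywhere; a positive determinant at every voxel is the
    numerical certificate that the field is locally invertible.
    """
    shape = field.shape
    if min(shape) < 2:
        raise StreamwarpError(
            "Jacobian needs at least 2 voxels along every axis"
        )
    # d(displacement)/d(voxel index), shape (X, Y, Z, 3 comp, 3 axis)
    grads = np.stack(
        [np.stack(np.gradient(field.vectors[..., c], axis=(0, 1, 2)), axis=-1)
         for c in range(3)],
        axis=-2,
    )
    # world-space Jacobian: I + dD/dindex @ dindex/dworld
    inv3 = np.linalg.inv(field.affine[:3, :3])
    jac = np.eye(3) + grads @ inv3
    det = np.linalg.det(jac)
    return VolumeGrid(det, field.affine.copy())
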