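# Methods

## Coordinate conventions

One canonical frame everywhere: world RAS millimeters, 0-based voxel
indices, voxel-to-world affines mapping voxel *centers*. All format quirks
are confined to the I/O layer: TRK's corner-offset voxel-mm storage and
voxel-order field are resolved on read/write (and cross-checked against
the header affine rather than trusted), TCK is read as the RAS mm it
stores, and displacement fields written by LPS-convention registration
tools get their first two vector components negated under the `lps_mm`
dialect. Streamline points are float64 internally regardless of the
float32 on disk, so warping error is dominated by interpolation, not
storage.

Continuous voxel coordinates are converted to voxel indices with
round-half-away-from-zero, everywhere (label transfer, endpoint
assignment, rasterization). The rule is symmetric, locale-independent and
pinned once so boundary cases are deterministic across runs and platforms.

## Warping model

A transform chain is an ordered list of 4×4 affines and dense displacement
fields applied **left to right to points**: `y = T_k(… T_1(x))`, with
`T(x) = x + d(x)` for fields and `d` interpolated trilinearly at `x`'s
continuous voxel coordinate in the field's own grid. Each field
contributes exactly one interpolation per point (instrumentable via
`interpolation_audit`); nothing else in the pipeline resamples anything.
No directional data is reoriented — the method warps coordinates only.

Point-transform order is the reverse of the image-resampling order used by
registration suites; the README carries the worked conversion. Points that
leave a field's interpolation hull raise by default; the `clamp` policy
clamps to the hull and counts the clamped points, because silent
extrapolation corrupts connectomes.

Trilinear interpolation reproduces any field whose vectors are affine in
position exactly; this is the basis of the sampling oracle tests.

## Displacement-field inversion

Two routes, both fixed-point iteration `d_inv(y) ← −d(y + d_inv(y))`:

* `invert_displacement_field` iterates on a grid (optionally refined by an
  integer `upsample` factor) until the largest update is below `tol`
  (default 1e-3 mm, max 50 iterations). At convergence the composition
  moves the inverse-grid points by < 2·tol; sampling the gridded inverse
  *between* its nodes adds a curvature-dependent interpolation error that
  shrinks with `upsample`.
* `InverseDisplacement` runs the same iteration per query point inside a
  chain, avoiding the inverse-grid interpolation error entirely. For a
  field with Lipschitz constant L < 1 (the synthetic warps guarantee
  L = a·k) the iteration is a contraction with rate L, and the converged
  round-trip error is below tol for L ≤ 1/2. This is the route used for
  round-trip validation and is preferred whenever the inverse is applied
  to points rather than stored as an image.

## Interpolation-free label transfer

Every labeled source voxel center is forward-mapped through the chain and
rounded to a target voxel; the label is carried over. Iteration order is
ascending source flat index with x varying fastest, so the "last label
wins" rule at contested targets is fully deterministic. Same-label merges
are not collisions; a source voxel counts as collided only when its target
voxel also received a *different* label. Targets outside the grid are
dropped and counted. Forward mapping leaves holes where the warp expands
tissue; they stay background by design — filling them would reintroduce
the interpolation the method exists to avoid. Streamline endpoints and
voxel labels move through the *same* map, so an endpoint lying on a voxel
center always finds its own label at the target unless a collision
overwrote it; this consistency is what the conservation tests exploit.

## Connectome construction

Endpoints are the exact first and last streamline points — no dilation or
search radius. A streamline counts once in `M_ij = M_ji` iff both
endpoints land in two different regions; background or out-of-grid
endpoints and same-region loops contribute nothing, and the diagonal is
zero (streamlines are unoriented, and whether same-region streamlines
should count is left excluded and flagged). The edge density image marks,
per streamline with an assigned region pair, every voxel its path visits,
at most once per streamline; generator point spacing of at most half a
voxel keeps traces near-contiguous.

## Comparison machinery

* Generalized Jaccard distance over flattened upper triangles (the
  diagonal is zero and symmetric duplication cancels; pinned for
  determinism). Undefined for two all-zero matrices — an error, never a
  silent 0.
* Network metrics use **binary** edges and integer degrees: the printed
  formulas count nonzero edges, so ⟨k⟩ = 2E/N, D = 2E/(N(N−1)) (hence
  ⟨k⟩ = (N−1)·D identically), and assortativity is the
  Pearson-correlation form over the E edges' endpoint-degree pairs. A
  regular graph makes the correlation 0/0: returned as an explicit
  undefined flag (`None`).
* Glass's delta uses the sample (n−1) standard deviation of the reference
  group; the choice of denominator is a documented convention here.
* Cohort analysis groups subject pairs by type and reports the mean/SD of
  pairwise distances plus, per metric, the Pearson r between members
  across the group's pairs — both r and r² are reported, since a signed
  association and its squared magnitude answer different questions.
  Groups with fewer than two pairs, or constant metrics, leave the
  correlation NaN rather than fabricating a value.

## Synthetic data: what it emulates, and what it does not

* **Block parcellation**: rectangular tiling chosen to balance tiling
  economy against block isotropy; 129 regions by default, matching the
  Lausanne scale-60 atlas size used for structural connectomes. Blocks are
  ~8–10 voxels across on the default 48³ grid at 1.25 mm — far smaller
  than real cortical regions relative to the warp, so the fraction of
  voxels adjacent to a different label is several times the real-brain
  one. Collision fractions measured here (~4% at displacement-gradient
  0.1) are therefore upper bounds in kind, not magnitude, for the ~1%
  seen on real data; the property test asserts < 5% at gradient 0.1.
* **Phantoms**: quadratic Bezier bundles between designated region pairs,
  200 streamlines per bundle and 5 bundles by default, Gaussian jitter
  (0.5 mm) on interior points. Endpoint voxels are sampled at least 2
  voxels inside their region's faces: with margin m, no differently
  labeled voxel can be carried onto an endpoint's target voxel by a warp
  whose per-axis compression stays below m/(m+1), which makes exact
  connectome recovery achievable and turns any deviation into a signal.
  Real endpoints at the gray–white boundary do not enjoy this margin —
  the phantom isolates the transform machinery from boundary ambiguity,
  it does not model it.
* **Warps**: separable sinusoids `d_c(x) = a sin(k x_c + φ_c)` with
  seeded phases. The Jacobian is diagonal with entries `1 + a k cos(·)`,
  so `a·k < 1` guarantees a positive determinant — a constructive
  diffeomorphism certificate, enforced at spec time rather than checked
  post hoc (composed affine+sinusoid kinds are additionally verified
  numerically). Real registration warps are not separable and have
  spatially varying anisotropic compression; the synthetic family spans
  the gradient magnitudes that matter (up to 0.5) without those features.
* Nothing here simulates diffusion signal, fiber crossings, or
  tractography failure modes; passing tests demonstrate correctness of
  the normalization/comparison machinery, not tract reconstruction
  fidelity.

## Problem sizes and numerical choices

Default validation sizes — 10⁴ streamlines for conservation and oracle
checks, ~10⁵ points on a 64³ field for round-trip error, 129 regions
throughout — were chosen as the smallest sizes at which every code path
(collisions, drops, clamping, multi-bundle recovery) is actually
exercised. Inversion tolerance defaults to 1e-3 mm (well below voxel
scale); the round-trip acceptance bound is twice that. The
degree–density identity is asserted at machine precision since it is
algebraic, not statistical.

## Known limitations

* TCK files carry no reference image; grid metadata must be supplied
  separately when endpoint assignment is intended.
* Forward label transfer leaves holes under expansion (by design); any
  endpoint falling in a hole is dropped from the connectome rather than
  recovered from a neighbor.
* Assortativity on near-regular graphs is numerically delicate; the
  undefined flag triggers on an exact-zero denominator (tolerance 1e-12),
  not on "almost regular".
* The cohort machinery reports descriptive statistics only; no inferential
  tests are included.
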