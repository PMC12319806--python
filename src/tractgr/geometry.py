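"""Streamline--voxel geometry and sparse forward-operator assembly.

This module provides the geometric primitives shared by every stage of the
tract-specific pipeline: exact intersection of streamline polylines with a
voxel grid, and assembly of the sparse linear operators that map per-streamline
compartment weights to voxel-wise signals (the convex microstructure-informed
tractography forward model).

Conventions
-----------
* Streamline coordinates are world millimetres (TCK convention); the inverse
  of the NIfTI affine maps them to voxel space.  The affine maps integer voxel
  indices to the world position of voxel *centres*, so in the shifted voxel
  coordinates used internally voxel ``i`` spans the half-open cube
  ``[i, i+1)``.
* Diffusion kernels follow the stick / zeppelin / ball decomposition with
  fixed diffusivities: a stick (restricted, intra-axonal) compartment with
  parallel diffusivity ``d_par``, an axially symmetric zeppelin (hindered,
  extra-axonal) compartment with ``d_par``/``d_perp``, and isotropic balls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "AcquisitionScheme",
    "KernelParams",
    "SegmentMap",
    "LinearSystem",
    "voxelize_streamline",
    "build_segment_map",
    "build_dwi_operator",
    "build_myelin_operator",
    "stick_signal",
    "zeppelin_signal",
    "ball_signal",
]


@dataclass(frozen=True)
class AcquisitionScheme:
    """Multi-shell acquisition: b-values (s/mm^2) and unit gradient directions.

    ``bvecs`` rows for b=0 measurements may be zero vectors; for b>0 they must
    be unit norm to 1e-6.  At least one b=0 measurement is required.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = 10.0

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape == (3, bvals.size) and bvecs.shape[0] != bvecs.shape[1]:
            bvecs = bvecs.T
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} bvals"
            )
        b0 = bvals <= self.b0_threshold
        if not b0.any():
            raise ValueError("acquisition scheme must contain at least one b=0")
        norms = np.linalg.norm(bvecs[~b0], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("b>0 gradient directions must be unit norm")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    @property
    def n_measurements(self) -> int:
        return self.bvals.size


@dataclass(frozen=True)
class KernelParams:
    """Fixed diffusivities of the stick-zeppelin-ball model, in mm^2/s.

    Defaults are the standard white-matter values: parallel diffusivity
    1.7e-3 for stick and zeppelin, perpendicular 0.51e-3 for the zeppelin,
    and two isotropic balls (1.7e-3 gray-matter-like, 3.0e-3 free water).
    """

    d_par: float = 1.7e-3
    d_perp: float = 0.51e-3
    d_iso: tuple[float, ...] = (1.7e-3, 3.0e-3)

    def __post_init__(self):
        if not (self.d_par >= self.d_perp > 0):
            raise ValueError("require d_par >= d_perp > 0")
        object.__setattr__(self, "d_iso", tuple(float(d) for d in self.d_iso))


def stick_signal(bvals, bvecs, direction, d_par):
    """Attenuation of a stick compartment: exp(-b d_par (g.u)^2)."""
    cos = bvecs @ np.asarray(direction, dtype=float)
    return np.exp(-np.asarray(bvals) * d_par * cos**2)


def zeppelin_signal(bvals, bvecs, direction, d_par, d_perp):
    """Attenuation of an axially symmetric tensor (zeppelin)."""
    cos = bvecs @ np.asarray(direction, dtype=float)
    return np.exp(-np.asarray(bvals) * (d_perp + (d_par - d_perp) * cos**2))


def ball_signal(bvals, d_iso):
    """Attenuation of an isotropic ball."""
    return np.exp(-np.asarray(bvals) * d_iso)


@dataclass
class SegmentMap:
    """Per-streamline voxel traversal: indices, in-voxel lengths, directions.

    For streamline ``i``, ``voxels[i]`` is an (m, 3) int array of 0-based
    voxel indices, ``lengths[i]`` the (m,) in-voxel lengths in mm, and
    ``directions[i]`` the (m, 3) unit chord directions of each in-voxel piece.
    """

    grid_shape: tuple[int, int, int]
    voxels: list = field(default_factory=list)
    lengths: list = field(default_factory=list)
    directions: list = field(default_factory=list)
    clipped: list = field(default_factory=list)

    @property
    def n_streamlines(self) -> int:
        return len(self.voxels)

    def arc_length(self, i: int) -> float:
        return float(self.lengths[i].sum())

    def traversed_voxels(self) -> np.ndarray:
        """Flat indices of all voxels traversed by any streamline."""
        if not self.voxels:
            return np.empty(0, dtype=np.int64)
        flat = [
            np.ravel_multi_index(v.T, self.grid_shape)
            for v in self.voxels
            if len(v)
        ]
        if not flat:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(flat))


def voxelize_streamline(points, affine, grid_shape):
    """Split a world-mm polyline at voxel faces of the grid.

    Returns ``(voxels, lengths, directions, clipped)`` where the first three
    are arrays as stored in :class:`SegmentMap` and ``clipped`` flags whether
    any portion fell outside the grid (that portion is dropped).

    Voxel ``i`` spans the half-open interval ``[i, i+1)`` along each axis in
    the internal corner-based voxel coordinates; the affine itself maps voxel
    indices to world centre positions, hence the half-voxel shift below.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("polyline needs >= 2 points of dimension 3")
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    # corner-based voxel coordinates: voxel centre i -> i + 0.5
    vox = pts @ inv[:3, :3].T + inv[:3, 3] + 0.5

    out_v, out_l, out_d = [], [], []
    clipped = False
    shape = np.asarray(grid_shape, dtype=int)
    for a_w, b_w, a_v, b_v in zip(pts[:-1], pts[1:], vox[:-1], vox[1:]):
        seg_len = float(np.linalg.norm(b_w - a_w))
        if seg_len == 0.0:
            continue
        delta = b_v - a_v
        # parameters where the segment crosses integer planes on any axis
        ts = [0.0, 1.0]
        for ax in range(3):
            if delta[ax] == 0.0:
                continue
            lo, hi = sorted((a_v[ax], b_v[ax]))
            first = np.ceil(lo)
            planes = np.arange(first, np.floor(hi) + 1.0)
            ts.extend(((planes - a_v[ax]) / delta[ax]).tolist())
        ts = np.unique(np.clip(np.asarray(ts), 0.0, 1.0))
        direction = (b_w - a_w) / seg_len
        for t0, t1 in zip(ts[:-1], ts[1:]):
            if t1 - t0 <= 1e-15:
                continue
            mid = a_v + delta * (0.5 * (t0 + t1))
            idx = np.floor(mid).astype(int)
            if np.any(idx < 0) or np.any(idx >= shape):
                clipped = True
                continue
            out_v.append(idx)
            out_l.append(seg_len * (t1 - t0))
            out_d.append(direction)

    if out_v:
        voxels = np.asarray(out_v, dtype=int)
        lengths = np.asarray(out_l, dtype=float)
        directions = np.asarray(out_d, dtype=float)
    else:
        voxels = np.empty((0, 3), dtype=int)
        lengths = np.empty(0, dtype=float)
        directions = np.empty((0, 3), dtype=float)
    return voxels, lengths, directions, clipped


def build_segment_map(streamlines, affine, grid_shape) -> SegmentMap:
    """Voxelize every streamline of a tractogram (world-mm polylines)."""
    segmap = SegmentMap(grid_shape=tuple(int(s) for s in grid_shape))
    for pts in streamlines:
        v, l, d, c = voxelize_streamline(pts, affine, grid_shape)
        segmap.voxels.append(v)
        segmap.lengths.append(l)
        segmap.directions.append(d)
        segmap.clipped.append(c)
    return segmap


@dataclass
class LinearSystem:
    """Sparse forward model ``A x = y`` with typed column blocks.

    ``columns`` holds one descriptor per column, in stable order: first
    ``("restricted", streamline_index)`` for every streamline, then
    ``("hindered", voxel_flat, direction)`` per voxel orientation cluster,
    then ``("iso", voxel_flat, d_iso)`` per voxel and ball kernel.
    ``voxel_rows`` maps each masked voxel (flat index) to its row block.
    """

    A: sparse.csr_matrix
    columns: list
    voxel_rows: np.ndarray  # flat voxel indices, one per row block
    n_meas_per_voxel: int
    y: np.ndarray | None = None

    @property
    def n_restricted(self) -> int:
        return sum(1 for c in self.columns if c[0] == "restricted")

    def column_block(self, kind: str) -> np.ndarray:
        return np.asarray([i for i, c in enumerate(self.columns) if c[0] == kind])

    def to_mtx(self, path) -> None:
        """Export the operator in Matrix Market format for inspection."""
        from scipy.io import mmwrite

        mmwrite(str(path), sparse.coo_matrix(self.A))


def _canonical_hemisphere(d: np.ndarray) -> np.ndarray:
    """Flip a direction so antipodal pairs map to one representative."""
    for comp in d:
        if abs(comp) > 1e-12:
            return d if comp > 0 else -d
    raise ValueError("zero-norm direction")


def _cluster_directions(dirs, lengths, angle_deg: float):
    """Greedy length-weighted clustering of antipodally-identified directions.

    Returns (labels, cluster_unit_directions). Deterministic: segments are
    consumed in input order, clusters keep their creation order.
    """
    cos_thresh = np.cos(np.deg2rad(angle_deg))
    means: list[np.ndarray] = []   # length-weighted direction sums
    units: list[np.ndarray] = []
    labels = np.empty(len(dirs), dtype=int)
    for i, (d, w) in enumerate(zip(dirs, lengths)):
        d = _canonical_hemisphere(np.asarray(d, dtype=float))
        assigned = -1
        for k, u in enumerate(units):
            if abs(float(u @ d)) >= cos_thresh:
                assigned = k
                break
        if assigned < 0:
            means.append(w * d)
            units.append(d.copy())
            assigned = len(units) - 1
        else:
            s = means[assigned]
            # keep the running mean in the same hemisphere as the sum
            s = s + (w * d if float(s @ d) >= 0 else -w * d)
            means[assigned] = s
            units[assigned] = s / np.linalg.norm(s)
        labels[i] = assigned
    return labels, [u.copy() for u in units]


def build_dwi_operator(
    segmap: SegmentMap,
    scheme: AcquisitionScheme,
    kernels: KernelParams,
    mask: np.ndarray,
    cluster_angle_deg: float = 15.0,
) -> LinearSystem:
    """Assemble the diffusion forward operator over a voxel mask.

    Column blocks:

    * restricted — one per streamline; entry for (voxel v, measurement q) is
      ``stick(q, segment direction) * in-voxel length`` (mm), so the unknown
      is a cross-sectional area (mm^2) and the product a volume signal.
    * hindered — one zeppelin column per voxel orientation cluster (segment
      directions clustered at ``cluster_angle_deg`` after antipodal
      identification); entries are the dimensionless zeppelin attenuation,
      so the unknown is a hindered volume (mm^3).
    * isotropic — one ball column per voxel and isotropic diffusivity.

    Rows are ordered voxel-major: masked voxels in ascending flat-index
    order, ``scheme.n_measurements`` rows each.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(segmap.grid_shape):
        raise ValueError("mask shape does not match segment map grid")
    if not mask.any():
        raise ValueError("empty mask")
    voxel_flat = np.flatnonzero(mask.ravel())
    row_of_voxel = {int(v): i for i, v in enumerate(voxel_flat)}
    n_meas = scheme.n_measurements
    bvals, bvecs = scheme.bvals, scheme.bvecs

    rows, cols, vals = [], [], []
    columns: list = []

    # restricted block, one column per streamline (stable: streamline order)
    per_voxel_dirs: dict[int, list] = {}
    per_voxel_lens: dict[int, list] = {}
    for si in range(segmap.n_streamlines):
        col = len(columns)
        columns.append(("restricted", si))
        v = segmap.voxels[si]
        if len(v) == 0:
            continue
        flat = np.ravel_multi_index(v.T, segmap.grid_shape)
        for f, length, d in zip(flat, segmap.lengths[si], segmap.directions[si]):
            f = int(f)
            if f not in row_of_voxel:
                continue
            nrm = np.linalg.norm(d)
            if nrm < 1e-12:
                raise ValueError("zero-norm segment direction")
            u = d / nrm
            sig = stick_signal(bvals, bvecs, u, kernels.d_par) * length
            base = row_of_voxel[f] * n_meas
            rows.extend(range(base, base + n_meas))
            cols.extend([col] * n_meas)
            vals.extend(sig.tolist())
            per_voxel_dirs.setdefault(f, []).append(u)
            per_voxel_lens.setdefault(f, []).append(length)

    # hindered block: per-voxel orientation clusters, voxel then cluster order
    for f in voxel_flat:
        f = int(f)
        if f not in per_voxel_dirs:
            continue
        labels, units = _cluster_directions(
            per_voxel_dirs[f], per_voxel_lens[f], cluster_angle_deg
        )
        for u in units:
            col = len(columns)
            columns.append(("hindered", f, tuple(u)))
            sig = zeppelin_signal(bvals, bvecs, u, kernels.d_par, kernels.d_perp)
            base = row_of_voxel[f] * n_meas
            rows.extend(range(base, base + n_meas))
            cols.extend([col] * n_meas)
            vals.extend(sig.tolist())

    # isotropic block: per voxel per ball diffusivity
    for f in voxel_flat:
        f = int(f)
        base = row_of_voxel[f] * n_meas
        for d_iso in kernels.d_iso:
            col = len(columns)
            columns.append(("iso", f, d_iso))
            sig = ball_signal(bvals, d_iso)
            rows.extend(range(base, base + n_meas))
            cols.extend([col] * n_meas)
            vals.extend(sig.tolist())

    A = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(voxel_flat.size * n_meas, len(columns))
    )
    return LinearSystem(
        A=A, columns=columns, voxel_rows=voxel_flat, n_meas_per_voxel=n_meas
    )


def build_myelin_operator(
    segmap: SegmentMap, mvf: np.ndarray, mask: np.ndarray, voxel_volume: float
) -> LinearSystem:
    """Assemble the myelin volume system: lengths vs per-voxel myelin volume.

    One row per masked voxel; ``A[v, i]`` is the in-voxel length (mm) of
    streamline ``i`` in voxel ``v`` and ``y[v] = MVF[v] * voxel_volume``
    (mm^3), so the non-negative solution is a per-streamline myelin
    cross-sectional area in mm^2.
    """
    mask = np.asarray(mask, dtype=bool)
    mvf = np.asarray(mvf, dtype=float)
    if not mask.any():
        raise ValueError("empty mask")
    if mvf.min() < 0 or mvf.max() > 1:
        raise ValueError("MVF must lie in [0, 1]")
    voxel_flat = np.flatnonzero(mask.ravel())
    row_of_voxel = {int(v): i for i, v in enumerate(voxel_flat)}

    rows, cols, vals = [], [], []
    columns: list = []
    for si in range(segmap.n_streamlines):
        col = len(columns)
        columns.append(("restricted", si))
        v = segmap.voxels[si]
        if len(v) == 0:
            continue
        flat = np.ravel_multi_index(v.T, segmap.grid_shape)
        for f, length in zip(flat, segmap.lengths[si]):
            f = int(f)
            if f in row_of_voxel:
                rows.append(row_of_voxel[f])
                cols.append(col)
                vals.append(length)

    A = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(voxel_flat.size, len(columns))
    )
    A.sum_duplicates()
    y = mvf.ravel()[voxel_flat] * float(voxel_volume)
    return LinearSystem(
        A=A, columns=columns, voxel_rows=voxel_flat, n_meas_per_voxel=1, y=y
    )
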