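"""Synthetic crossing-fiber phantoms with known axon/myelin ground truth.

The phantom generates everything the tract-specific g-ratio pipeline needs —
streamlines, multi-shell diffusion signal, MT-related maps, a parcellation,
and a calibration ROI — from a declarative :class:`PhantomSpec`, with exact
per-streamline and per-edge ground truth.

Volume bookkeeping
------------------
Each streamline of a bundle carries a fixed intra-axonal cross-sectional area
``a`` (mm^2) and myelin cross-sectional area ``m`` (mm^2); traversing a voxel
for a length ``l`` (mm) deposits ``a*l`` of intra-axonal and ``m*l`` of myelin
volume there.  An extra-axonal hindered pool proportional to the axonal one
(``a*l*(1/ICVF_fiber - 1)``, oriented along the local segment) fixes the
intra-cellular volume fraction of the fiber water at ``ICVF_fiber``.  The
remaining non-myelin water in each voxel is isotropic free water; voxels not
traversed by any bundle are a mixture of free water and a gray-matter-like
isotropic pool set by ``isovf_background``.  With this construction the voxel
fractions satisfy the aggregate g-ratio model identities exactly:
``AVF = (1-MVF)(1-ISOVF)*ICVF`` and ``g = sqrt(AVF/(AVF+MVF))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    AcquisitionScheme,
    KernelParams,
    build_segment_map,
    stick_signal,
    zeppelin_signal,
    ball_signal,
)
from .streamlines import StreamlineSet, resample_polyline

__all__ = [
    "BundleSpec",
    "PhantomSpec",
    "GroundTruth",
    "PhantomOverfillError",
    "build_phantom",
    "simulate_dwi",
    "simulate_mtw",
    "default_scheme",
    "two_bundle_spec",
    "single_bundle_spec",
    "calibration_phantom",
]

FREE_WATER_DIFFUSIVITY = 3.0e-3   # mm^2/s, CSF-like isotropic pool
GM_DIFFUSIVITY = 1.7e-3           # mm^2/s, gray-matter-like isotropic pool


class PhantomOverfillError(ValueError):
    """Deposited tissue exceeds the voxel volume somewhere."""


@dataclass
class BundleSpec:
    """A coherent fiber bundle: centerline plus per-streamline ground truth.

    ``g_true**2 == axon_csa_true / (axon_csa_true + myelin_csa_true)``.
    """

    id: int
    centerline: np.ndarray           # (n, 3) world mm
    n_streamlines: int
    axon_csa_true: float             # mm^2 per streamline
    myelin_csa_true: float           # mm^2 per streamline

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.axon_csa_true <= 0:
            raise ValueError("axon_csa_true must be > 0")
        if self.myelin_csa_true < 0:
            raise ValueError("myelin_csa_true must be >= 0")

    @property
    def g_true(self) -> float:
        return float(
            np.sqrt(
                self.axon_csa_true / (self.axon_csa_true + self.myelin_csa_true)
            )
        )

    @classmethod
    def from_g(cls, id, centerline, n_streamlines, axon_csa_true, g_true):
        """Construct from a target g-ratio instead of a myelin area."""
        if not (0 < g_true <= 1):
            raise ValueError("g_true must lie in (0, 1]")
        myelin = axon_csa_true * (1.0 - g_true**2) / g_true**2
        return cls(id, centerline, n_streamlines, axon_csa_true, myelin)


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic crossing-fiber dataset."""

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size: float = 1.0                       # mm, isotropic
    bundles: list = field(default_factory=list)
    n_spurious: int = 10
    isovf_background: float = 0.8                 # free-water fraction off-bundle
    icvf_fiber: float = 0.8                       # intra-cellular fraction of fiber water
    noise_sigma: float = 0.0                      # signal units; 0 = noiseless
    jitter_sd: float | None = None                # default 0.2 * voxel_size
    step: float = 0.5                             # mm resampling step
    label_radius: int = 1                         # parcellation half-width (voxels)
    fa_calib_threshold: float = 0.8
    mtsat_scale: float = 20.0                     # true MVF = scale * MTsat
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.isovf_background < 1):
            raise ValueError("isovf_background must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0 < self.icvf_fiber <= 1):
            raise ValueError("icvf_fiber must lie in (0, 1]")
        if self.jitter_sd is None:
            self.jitter_sd = 0.2 * self.voxel_size

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size
        return aff

    @property
    def voxel_volume(self) -> float:
        return float(self.voxel_size**3)


@dataclass
class GroundTruth:
    """Exact per-voxel, per-streamline and per-edge ground truth."""

    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    voxel_size: float
    mvf: np.ndarray
    avf: np.ndarray
    icvf: np.ndarray
    isovf: np.ndarray
    fa: np.ndarray
    g: np.ndarray
    mtsat: np.ndarray
    iso_volume: np.ndarray       # mm^3 free water per voxel
    gm_volume: np.ndarray        # mm^3 gray-matter-like isotropic per voxel
    bundle_count: np.ndarray     # number of bundles depositing in each voxel
    axon_csa: np.ndarray         # per streamline, mm^2 (0 for spurious)
    myelin_csa: np.ndarray       # per streamline, mm^2
    extra_csa: np.ndarray        # per streamline hindered-pool area, mm^2
    bundle_id: np.ndarray        # per streamline; -1 for spurious
    edges: pd.DataFrame          # node_a, node_b, bundle, av, mv, g

    @property
    def voxel_volume(self) -> float:
        return float(self.voxel_size**3)


def default_scheme(seed: int = 0) -> AcquisitionScheme:
    """Multi-shell scheme mirroring a standard in-vivo protocol:
    6 b=0 plus 10/30/64 directions at b = 300/1000/2000 s/mm^2."""
    bvals = [0.0] * 6
    bvecs = [[0.0, 0.0, 0.0]] * 6
    for b, n, offset in ((300.0, 10, 0.11), (1000.0, 30, 0.37), (2000.0, 64, 0.73)):
        dirs = _fibonacci_hemisphere(n, offset)
        bvals.extend([b] * n)
        bvecs.extend(dirs.tolist())
    return AcquisitionScheme(np.asarray(bvals), np.asarray(bvecs))


def _fibonacci_hemisphere(n: int, phase: float) -> np.ndarray:
    """Near-uniform directions on the upper hemisphere (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    z = i / n                       # cos(theta) in (0, 1): upper hemisphere
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i + 2 * np.pi * phase
    r = np.sqrt(1.0 - z**2)
    d = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def two_bundle_spec(
    g_true=(0.60, 0.80),
    n_streamlines: int = 50,
    axon_csa: float = 0.004,
    n_spurious: int = 10,
    noise_sigma: float = 0.0,
    seed: int = 0,
    grid: int = 16,
) -> PhantomSpec:
    """Two bundles with distinct g-ratios mixing along a shared corridor.

    Bundle 0 runs straight along +x; bundle 1 descends at ~53 degrees into
    bundle 0's path, shares its central corridor, and leaves again toward
    separate endpoint labels.  Voxels along most of both tracts therefore
    contain two fiber populations with different g-ratios — the pervasive
    partial-volume situation of in-vivo white matter — while each bundle
    keeps exclusive end segments that anchor its per-streamline areas.
    """
    scale = grid / 16.0
    x0, x1 = 1.0 * scale, (grid - 2.0)
    mid = (grid - 1) / 2.0
    y_off = mid + 4.0 * scale
    cx0, cx1 = 4.0 * scale, (grid - 5.0)   # corridor extent along x
    line_a = np.array([[x0, mid, mid], [x1, mid, mid]])
    line_b = np.array(
        [
            [x0, y_off, mid],
            [cx0, mid, mid],
            [cx1, mid, mid],
            [x1, y_off, mid],
        ]
    )
    bundles = [
        BundleSpec.from_g(0, line_a, n_streamlines, axon_csa, g_true[0]),
        BundleSpec.from_g(1, line_b, n_streamlines, axon_csa, g_true[1]),
    ]
    return PhantomSpec(
        grid_shape=(grid, grid, grid),
        bundles=bundles,
        n_spurious=n_spurious,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def orthogonal_crossing_spec(
    g_true=(0.60, 0.80),
    n_streamlines: int = 50,
    axon_csa: float = 0.004,
    n_spurious: int = 10,
    noise_sigma: float = 0.0,
    seed: int = 0,
    grid: int = 16,
) -> PhantomSpec:
    """Two orthogonal bundles crossing in a single central region.

    Bundle 0 runs along +x, bundle 1 along +y through the grid centre.  The
    crossing occupies ~1 voxel of each tract, so the partial-volume footprint
    is minimal — the clean-crossing counterpart of :func:`two_bundle_spec`.
    """
    c = grid - 2.0
    mid = (grid - 1) / 2.0
    line_x = np.array([[1.0, mid, mid], [c, mid, mid]])
    line_y = np.array([[mid, 1.0, mid], [mid, c, mid]])
    bundles = [
        BundleSpec.from_g(0, line_x, n_streamlines, axon_csa, g_true[0]),
        BundleSpec.from_g(1, line_y, n_streamlines, axon_csa, g_true[1]),
    ]
    return PhantomSpec(
        grid_shape=(grid, grid, grid),
        bundles=bundles,
        n_spurious=n_spurious,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def single_bundle_spec(
    g_true: float = 0.70,
    n_streamlines: int = 50,
    axon_csa: float = 0.004,
    noise_sigma: float = 0.0,
    seed: int = 0,
    grid: int = 16,
) -> PhantomSpec:
    """One straight bundle along +x; no crossing, no spurious streamlines."""
    mid = (grid - 1) / 2.0
    line_x = np.array([[1.0, mid, mid], [grid - 2.0, mid, mid]])
    bundles = [BundleSpec.from_g(0, line_x, n_streamlines, axon_csa, g_true)]
    return PhantomSpec(
        grid_shape=(grid, grid, grid),
        bundles=bundles,
        n_spurious=0,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _perp_basis(direction: np.ndarray):
    d = direction / np.linalg.norm(direction)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _bundle_streamlines(bundle: BundleSpec, spec: PhantomSpec, rng) -> list:
    """Jittered copies of the centerline: a constant Gaussian offset per
    streamline in the plane perpendicular to the overall bundle direction."""
    center = resample_polyline(bundle.centerline, spec.step)
    direction = center[-1] - center[0]
    e1, e2 = _perp_basis(direction)
    out = []
    for _ in range(bundle.n_streamlines):
        o1, o2 = rng.normal(0.0, spec.jitter_sd, size=2)
        out.append(center + o1 * e1 + o2 * e2)
    return out


def _label_blocks(spec: PhantomSpec):
    """Parcellation label cubes at each bundle's two endpoints.

    Returns (parcellation grid, per-bundle (label_a, label_b), label centres).
    """
    parc = np.zeros(spec.grid_shape, dtype=np.int32)
    inv = np.linalg.inv(spec.affine)
    pairs, centres = [], {}
    next_label = 1
    r = spec.label_radius
    shape = np.asarray(spec.grid_shape)
    for bundle in spec.bundles:
        labels = []
        for endpoint in (bundle.centerline[0], bundle.centerline[-1]):
            vox = np.floor(endpoint @ inv[:3, :3].T + inv[:3, 3] + 0.5).astype(int)
            lo = np.maximum(vox - r, 0)
            hi = np.minimum(vox + r + 1, shape)
            block = parc[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            block[block == 0] = next_label
            labels.append(next_label)
            centres[next_label] = vox
            next_label += 1
        pairs.append(tuple(labels))
    return parc, pairs, centres


def _spurious_streamlines(spec: PhantomSpec, pairs, centres, rng) -> list:
    """Implausible streamlines: bowed arcs between endpoint labels of
    *different* bundles, so their local orientation stays >= ~30 degrees away
    from every bundle orientation in any shared voxel."""
    if len(pairs) < 2:
        combos = [(pairs[0][0], pairs[0][1])] if pairs else []
    else:
        # candidate label pairs across bundles whose connecting direction
        # stays >= ~35 degrees away from every bundle's overall orientation,
        # so spurious arcs never mimic a plausible tract
        bundle_dirs = []
        for b in spec.bundles:
            d = b.centerline[-1] - b.centerline[0]
            bundle_dirs.append(d / np.linalg.norm(d))
        cos_max = np.cos(np.deg2rad(35.0))
        combos = []
        for i, pa in enumerate(pairs):
            for j, pb in enumerate(pairs):
                if i >= j:
                    continue
                for a in pa:
                    for b_lab in pb:
                        d = centres[b_lab] - centres[a]
                        nrm = np.linalg.norm(d)
                        if nrm == 0:
                            continue
                        d = d / nrm
                        if all(abs(d @ u) < cos_max for u in bundle_dirs):
                            combos.append((a, b_lab))
        if not combos:
            combos = [(pa[0], pb[1]) for pa, pb in zip(pairs[:-1], pairs[1:])]
    out = []
    vs = spec.voxel_size
    shape = np.asarray(spec.grid_shape, dtype=float)
    for _ in range(spec.n_spurious):
        a, b = combos[rng.integers(len(combos))]
        p0 = (centres[a] + rng.uniform(-0.3, 0.3, 3)) * vs
        p1 = (centres[b] + rng.uniform(-0.3, 0.3, 3)) * vs
        ctrl = 0.5 * (p0 + p1)
        ctrl[2] += rng.choice([-1.0, 1.0]) * rng.uniform(1.5, 2.5) * vs
        ctrl = np.clip(ctrl, 0.6 * vs, (shape - 1.6) * vs)
        t = np.linspace(0.0, 1.0, 64)[:, None]
        bezier = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t**2 * p1
        out.append(resample_polyline(bezier, spec.step))
    return out


def build_phantom(spec: PhantomSpec):
    """Assemble a phantom dataset.

    Returns ``(streamlines, truth, parcellation, calibration_roi)``; the
    streamline order is bundle 0, bundle 1, ..., then spurious streamlines.
    Raises :class:`PhantomOverfillError` if the deposited tissue volume
    exceeds any voxel's volume.
    """
    rng = np.random.default_rng(spec.seed)
    parc, pairs, centres = _label_blocks(spec)

    all_lines: list = []
    axon_csa, myelin_csa, extra_csa, bundle_id = [], [], [], []
    extra_ratio = 1.0 / spec.icvf_fiber - 1.0
    for bundle in spec.bundles:
        lines = _bundle_streamlines(bundle, spec, rng)
        all_lines.extend(lines)
        axon_csa.extend([bundle.axon_csa_true] * len(lines))
        myelin_csa.extend([bundle.myelin_csa_true] * len(lines))
        extra_csa.extend([bundle.axon_csa_true * extra_ratio] * len(lines))
        bundle_id.extend([bundle.id] * len(lines))
    spurious = _spurious_streamlines(spec, pairs, centres, rng)
    all_lines.extend(spurious)
    axon_csa.extend([0.0] * len(spurious))
    myelin_csa.extend([0.0] * len(spurious))
    extra_csa.extend([0.0] * len(spurious))
    bundle_id.extend([-1] * len(spurious))

    axon_csa = np.asarray(axon_csa)
    myelin_csa = np.asarray(myelin_csa)
    extra_csa = np.asarray(extra_csa)
    bundle_id = np.asarray(bundle_id, dtype=int)

    segmap = build_segment_map(all_lines, spec.affine, spec.grid_shape)
    shape = spec.grid_shape
    vvox = spec.voxel_volume
    av_vol = np.zeros(shape)
    mv_vol = np.zeros(shape)
    eh_vol = np.zeros(shape)
    tensor = np.zeros(shape + (3, 3))
    bundle_seen = np.zeros(shape + (len(spec.bundles),), dtype=bool)

    for si in range(segmap.n_streamlines):
        if axon_csa[si] == 0.0:
            continue
        a, m, e = axon_csa[si], myelin_csa[si], extra_csa[si]
        for vox, length, d in zip(
            segmap.voxels[si], segmap.lengths[si], segmap.directions[si]
        ):
            v = tuple(vox)
            av_vol[v] += a * length
            mv_vol[v] += m * length
            eh_vol[v] += e * length
            u = d / np.linalg.norm(d)
            uu = np.outer(u, u)
            d_par, d_perp = 1.7e-3, 0.51e-3
            tensor[v] += a * length * d_par * uu
            tensor[v] += e * length * (d_perp * np.eye(3) + (d_par - d_perp) * uu)
            bundle_seen[v][bundle_id[si]] = True

    mvf = mv_vol / vvox
    water = (1.0 - mvf) * vvox
    iso_volume = water - av_vol - eh_vol
    overfill = iso_volume < -1e-9 * vvox
    if overfill.any():
        worst = np.unravel_index(np.argmin(iso_volume), shape)
        frac = (mv_vol + av_vol + eh_vol)[worst] / vvox
        raise PhantomOverfillError(
            f"total tissue volume fraction {frac:.3f} > 1 at voxel {worst}; "
            "reduce per-streamline cross-sectional areas or bundle density"
        )
    iso_volume = np.clip(iso_volume, 0.0, None)

    fiber = (av_vol + eh_vol) > 0
    gm_volume = np.zeros(shape)
    gm_volume[~fiber] = water[~fiber] * (1.0 - spec.isovf_background)
    iso_volume[~fiber] = water[~fiber] * spec.isovf_background

    avf = av_vol / vvox
    icvf = np.zeros(shape)
    icvf[fiber] = av_vol[fiber] / (av_vol[fiber] + eh_vol[fiber])
    isovf = np.zeros(shape)
    nz = water > 0
    isovf[nz] = iso_volume[nz] / water[nz]

    g = np.full(shape, np.nan)
    dn = avf + mvf
    g[dn > 0] = np.sqrt(avf[dn > 0] / dn[dn > 0])

    fa = np.zeros(shape)
    w = av_vol + eh_vol
    idx = np.argwhere(w > 0)
    for v in map(tuple, idx):
        lam = np.linalg.eigvalsh(tensor[v] / w[v])
        fa[v] = _fa_from_eigenvalues(lam)

    mtsat = mvf / spec.mtsat_scale

    bundle_count = bundle_seen.sum(axis=-1)
    calib_roi = (bundle_count == 1) & (fa > spec.fa_calib_threshold) & (mvf > 0)

    rows = []
    lengths = np.array([segmap.arc_length(i) for i in range(len(all_lines))])
    for bundle, (la, lb) in zip(spec.bundles, pairs):
        sel = bundle_id == bundle.id
        av = float((axon_csa[sel] * lengths[sel]).sum())
        mv = float((myelin_csa[sel] * lengths[sel]).sum())
        rows.append(
            {
                "node_a": min(la, lb),
                "node_b": max(la, lb),
                "bundle": bundle.id,
                "av": av,
                "mv": mv,
                "g": float(np.sqrt(av / (av + mv))) if av + mv > 0 else np.nan,
            }
        )
    edges = pd.DataFrame(rows)

    truth = GroundTruth(
        grid_shape=shape,
        affine=spec.affine,
        voxel_size=spec.voxel_size,
        mvf=mvf,
        avf=avf,
        icvf=icvf,
        isovf=isovf,
        fa=fa,
        g=g,
        mtsat=mtsat,
        iso_volume=iso_volume,
        gm_volume=gm_volume,
        bundle_count=bundle_count,
        axon_csa=axon_csa,
        myelin_csa=myelin_csa,
        extra_csa=extra_csa,
        bundle_id=bundle_id,
        edges=edges,
    )
    return StreamlineSet(all_lines), truth, parc, calib_roi


def _fa_from_eigenvalues(lam) -> float:
    lam = np.asarray(lam, dtype=float)
    ss = float((lam**2).sum())
    if ss == 0:
        return 0.0
    mean = lam.mean()
    return float(np.clip(np.sqrt(1.5 * ((lam - mean) ** 2).sum() / ss), 0.0, 1.0))


def simulate_dwi(
    truth: GroundTruth,
    streamlines: StreamlineSet,
    scheme: AcquisitionScheme,
    kernels: KernelParams | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    noise_model: str = "rician",
) -> np.ndarray:
    """Forward-simulate the multi-shell diffusion signal of the phantom.

    Voxel signal (in mm^3 volume units) is the sum of each streamline's stick
    contribution (area x in-voxel length, along the local segment), its
    proportional hindered zeppelin pool, and the voxel's isotropic pools, so
    the b=0 signal equals the voxel's non-myelin water volume, i.e.
    ``(1 - MVF) * voxel_volume``.  Optional Rician (default) or Gaussian
    noise of standard deviation ``noise_sigma`` in signal units.
    """
    kernels = kernels or KernelParams()
    segmap = build_segment_map(streamlines, truth.affine, truth.grid_shape)
    n_meas = scheme.n_measurements
    signal = np.zeros(truth.grid_shape + (n_meas,))

    for si in range(segmap.n_streamlines):
        a = truth.axon_csa[si]
        if a == 0.0:
            continue
        e = truth.extra_csa[si]
        for vox, length, d in zip(
            segmap.voxels[si], segmap.lengths[si], segmap.directions[si]
        ):
            nrm = np.linalg.norm(d)
            if nrm < 1e-12:
                raise ValueError("zero-norm segment direction")
            u = d / nrm
            v = tuple(vox)
            signal[v] += a * length * stick_signal(
                scheme.bvals, scheme.bvecs, u, kernels.d_par
            )
            signal[v] += e * length * zeppelin_signal(
                scheme.bvals, scheme.bvecs, u, kernels.d_par, kernels.d_perp
            )

    signal += truth.iso_volume[..., None] * ball_signal(
        scheme.bvals, FREE_WATER_DIFFUSIVITY
    )
    signal += truth.gm_volume[..., None] * ball_signal(scheme.bvals, GM_DIFFUSIVITY)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        if noise_model == "rician":
            n1 = rng.normal(0.0, noise_sigma, signal.shape)
            n2 = rng.normal(0.0, noise_sigma, signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
        elif noise_model == "gaussian":
            signal = signal + rng.normal(0.0, noise_sigma, signal.shape)
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
    return signal


def simulate_mtw(mtsat, s0, t1, flip_angle, b1, tr) -> np.ndarray:
    """MT-weighted gradient-echo signal consistent with the MTsat definition.

    ``S_MTw = S0 * a / (1 + (MTsat + a^2/2) * T1 / TR)`` with
    ``a = flip_angle * B1`` (rad); inverting this with the MTsat estimator
    reproduces the input saturation map exactly in the noiseless case.
    T1 and TR share units (ms).
    """
    mtsat = np.asarray(mtsat, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    if np.any(s0 <= 0) or np.any(t1 <= 0):
        raise ValueError("S0 and T1 must be positive")
    a = flip_angle * b1
    if np.any(a <= 0) or np.any(a >= np.pi / 2):
        raise ValueError("effective flip angle must lie in (0, pi/2)")
    denom = 1.0 + (mtsat + a**2 / 2.0) * t1 / tr
    if np.any(denom <= 0):
        raise ValueError("non-positive signal denominator")
    return s0 * a / denom


def calibration_phantom(
    grid: int = 8,
    mtsat: float = 0.0227,
    icvf: float = 0.8,
    isovf: float = 0.0,
    fa: float = 0.9,
    roi_margin: int = 1,
):
    """Uniform single-compartment phantom for calibration-closure checks.

    Returns ``(maps, roi)`` where ``maps`` is a dict of constant MTsat, ICVF,
    ISOVF, and FA grids and ``roi`` a central high-FA region; outside the ROI
    the FA is below any calibration threshold.
    """
    shape = (grid, grid, grid)
    maps = {
        "mtsat": np.full(shape, mtsat),
        "icvf": np.full(shape, icvf),
        "isovf": np.full(shape, isovf),
        "fa": np.full(shape, 0.2),
    }
    roi = np.zeros(shape, dtype=bool)
    sl = slice(roi_margin, grid - roi_margin)
    roi[sl, sl, sl] = True
    maps["fa"][roi] = fa
    return maps, roi
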