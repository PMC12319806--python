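"""Voxel-wise quantitative maps: MTsat, MVF calibration, AVF, g-ratio, FA.

The aggregate g-ratio model combines a myelin-sensitive map with diffusion
compartment fractions:

    AVF = (1 - MVF) (1 - ISOVF) ICVF
    g   = sqrt( AVF / (AVF + MVF) )

MVF itself is obtained by linearly calibrating the magnetization transfer
saturation map, ``MVF = alpha_calib * MTsat``, where the global factor
``alpha_calib`` is fixed by asserting a reference g-ratio (0.7 by convention)
in a high-FA single-fiber calibration region (the splenium in vivo).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import AcquisitionScheme

logger = logging.getLogger(__name__)

__all__ = [
    "MTsatInputs",
    "CalibrationResult",
    "compute_mtsat",
    "compute_alpha_calib",
    "compute_avf",
    "compute_gratio",
    "compute_fa",
    "fa_from_eigenvalues",
]


@dataclass(frozen=True)
class MTsatInputs:
    """Inputs of the MTsat estimator.

    ``flip_angle`` is the excitation flip angle of the MT-weighted image in
    radians, ``b1`` the relative transmit field (dimensionless, ~1), and
    ``tr``/``t1`` share units (ms).
    """

    s_mtw: np.ndarray
    s0: np.ndarray
    t1: np.ndarray
    flip_angle: float
    b1: np.ndarray | float = 1.0
    tr: float = 27.0


def compute_mtsat(inputs: MTsatInputs) -> np.ndarray:
    """Magnetization transfer saturation per voxel.

    ``MTsat = (S0 a / S_MTw - 1) TR / T1 - a^2 / 2`` with
    ``a = flip_angle * B1``; voxels with non-positive S_MTw map to NaN.
    """
    s_mtw = np.asarray(inputs.s_mtw, dtype=float)
    s0 = np.asarray(inputs.s0, dtype=float)
    t1 = np.asarray(inputs.t1, dtype=float)
    a = inputs.flip_angle * np.asarray(inputs.b1, dtype=float)
    bad = s_mtw <= 0
    if bad.any():
        logger.info("MTsat: %d voxels with non-positive S_MTw set to NaN", bad.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (s0 * a / s_mtw - 1.0) * inputs.tr / t1 - a**2 / 2.0
    return np.where(bad, np.nan, out)


@dataclass
class CalibrationResult:
    """Global MTsat-to-MVF calibration factor and per-voxel diagnostics."""

    alpha_calib: float
    per_voxel_factors: np.ndarray
    n_voxels: int


def mvf_target(icvf, isovf, g_ref: float) -> np.ndarray:
    """Myelin volume fraction implied by the g-ratio model at a fixed g.

    Solving ``g_ref^2 = AVF/(AVF+MVF)`` with ``AVF = (1-MVF)(1-ISOVF)ICVF``
    for MVF gives, with ``c = (1-ISOVF) ICVF``:

        MVF* = c (1 - g_ref^2) / (g_ref^2 + c (1 - g_ref^2))
    """
    c = (1.0 - np.asarray(isovf, dtype=float)) * np.asarray(icvf, dtype=float)
    num = c * (1.0 - g_ref**2)
    return num / (g_ref**2 + num)


def compute_alpha_calib(
    mtsat,
    icvf,
    isovf,
    fa,
    roi_mask,
    g_ref: float = 0.7,
    fa_thresh: float = 0.8,
) -> CalibrationResult:
    """Global calibration factor from a single-fiber reference region.

    Within ``roi_mask`` restricted to voxels with FA above ``fa_thresh``,
    each voxel's factor is ``MVF*/MTsat`` where MVF* is the myelin fraction
    implied by the model at ``g_ref``; the global factor is the mean over
    selected voxels.  To calibrate a multi-subject cohort with equal subject
    weighting, call per subject and average the returned factors.

    Voxels with non-positive MTsat are excluded; an empty selection after FA
    thresholding is an error.
    """
    roi = np.asarray(roi_mask, dtype=bool) & (np.asarray(fa, dtype=float) > fa_thresh)
    if not roi.any():
        raise ValueError("no calibration voxel passes the FA threshold")
    mtsat = np.asarray(mtsat, dtype=float)
    usable = roi & (mtsat > 0) & np.isfinite(mtsat)
    if not usable.any():
        raise ValueError("no calibration voxel with positive MTsat")
    target = mvf_target(
        np.asarray(icvf, dtype=float)[usable],
        np.asarray(isovf, dtype=float)[usable],
        g_ref,
    )
    factors = target / mtsat[usable]
    return CalibrationResult(
        alpha_calib=float(factors.mean()),
        per_voxel_factors=factors,
        n_voxels=int(usable.sum()),
    )


def compute_avf(mvf, isovf, icvf) -> np.ndarray:
    """Intra-axonal volume fraction: AVF = (1 - MVF)(1 - ISOVF) ICVF."""
    return (
        (1.0 - np.asarray(mvf, dtype=float))
        * (1.0 - np.asarray(isovf, dtype=float))
        * np.asarray(icvf, dtype=float)
    )


def compute_gratio(avf, mvf) -> np.ndarray:
    """Aggregate g-ratio: sqrt(AVF / (AVF + MVF)); NaN where AVF + MVF = 0.

    Also valid at the tract level with summed volumes AV and MV in place of
    the voxel fractions.
    """
    avf = np.asarray(avf, dtype=float)
    mvf = np.asarray(mvf, dtype=float)
    denom = avf + mvf
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.sqrt(avf / denom)
    return np.where(denom > 0, g, np.nan)


def fa_from_eigenvalues(evals) -> np.ndarray:
    """Fractional anisotropy from diffusion tensor eigenvalues (last axis)."""
    lam = np.asarray(evals, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = ((lam - mean) ** 2).sum(axis=-1)
    den = (lam**2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.clip(np.where(den > 0, fa, 0.0), 0.0, 1.0)


def compute_fa(
    dwi: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray | None = None,
    max_bval: float = 1000.0,
) -> np.ndarray:
    """FA map from a log-linear tensor fit restricted to b <= ``max_bval``.

    The single-tensor model is only valid at moderate b-values, hence the
    shell restriction.  Voxels with any non-positive signal on the selected
    measurements are NaN.
    """
    use = scheme.bvals <= max_bval
    if (use & ~scheme.b0_mask).sum() < 6:
        raise ValueError("need >= 6 diffusion directions at b <= max_bval")
    b = scheme.bvals[use]
    g = scheme.bvecs[use]
    # design: ln S = ln S0 - b (g' D g), D with 6 unique components
    X = np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    shape = dwi.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    signal = dwi[..., use]
    fa = np.full(shape, np.nan)
    pinv = np.linalg.pinv(X)
    for v in map(tuple, np.argwhere(mask)):
        s = signal[v]
        if np.any(s <= 0):
            continue
        beta = pinv @ np.log(s)
        D = np.array(
            [
                [beta[1], beta[4], beta[5]],
                [beta[4], beta[2], beta[6]],
                [beta[5], beta[6], beta[3]],
            ]
        )
        fa[v] = fa_from_eigenvalues(np.linalg.eigvalsh(D))
    return fa
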