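"""Conventional tractometry: sample a volumetric map along streamlines.

The comparator to the tract-specific pipeline: each streamline's g-ratio is
the median of trilinear samples of the volumetric g-ratio map taken at
arc-length-uniform points (0.5 mm by default, matching the tractography step
size), and each connectome edge is the mean over its member streamlines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .streamlines import StreamlineSet, resample_polyline

__all__ = ["TractometryResult", "sample_along", "streamline_medians", "edge_tractometry"]


def _trilinear_nan_aware(grid: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinear interpolation that ignores NaN / out-of-grid corners.

    Corner weights of missing values are dropped and the remainder
    renormalized, so a sample is NaN only when every contributing corner is
    undefined.  ``coords`` are continuous voxel coordinates (n, 3) with voxel
    centres at integers.
    """
    grid = np.asarray(grid, dtype=float)
    shape = np.asarray(grid.shape)
    base = np.floor(coords).astype(int)
    frac = coords - base
    num = np.zeros(len(coords))
    den = np.zeros(len(coords))
    for corner in range(8):
        offset = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = base + offset
        w = np.prod(np.where(offset, frac, 1.0 - frac), axis=1)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        vals = np.full(len(coords), np.nan)
        vals[inside] = grid[tuple(idx[inside].T)]
        ok = inside & np.isfinite(vals) & (w > 0)
        num[ok] += w[ok] * vals[ok]
        den[ok] += w[ok]
    with np.errstate(invalid="ignore"):
        out = num / den
    return np.where(den > 0, out, np.nan)


def sample_along(g_map, affine, points, step: float = 0.5) -> np.ndarray:
    """Trilinear samples of a map along a streamline at uniform arc length.

    Samples that fall outside the grid or entirely outside defined (non-NaN)
    tissue are excluded from the returned vector; an empty result means the
    streamline never touches defined tissue.
    """
    pts = resample_polyline(np.asarray(points, dtype=float), step)
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    samples = _trilinear_nan_aware(g_map, vox)
    return samples[np.isfinite(samples)]


def streamline_medians(
    g_map, affine, streamlines: StreamlineSet, step: float = 0.5
) -> np.ndarray:
    """Per-streamline median of the sampled map; NaN when no valid sample."""
    out = np.full(len(streamlines), np.nan)
    for i, line in enumerate(streamlines):
        s = sample_along(g_map, affine, line, step)
        if s.size:
            out[i] = np.median(s)
    return out


@dataclass
class TractometryResult:
    """Per-streamline medians and per-edge means of the sampled map."""

    medians: np.ndarray
    edges: pd.DataFrame       # node_a, node_b, count, g
    step: float


def edge_tractometry(
    medians: np.ndarray, node_pairs: np.ndarray, step: float = 0.5
) -> TractometryResult:
    """Mean per-streamline median per connectome edge.

    ``node_pairs`` as produced by :func:`tractgr.connectome.assign_edges`;
    unassigned streamlines and self-loops are ignored, as are NaN medians.
    """
    pairs = np.asarray(node_pairs)
    medians = np.asarray(medians, dtype=float)
    valid = (pairs[:, 0] > 0) & (pairs[:, 0] != pairs[:, 1]) & np.isfinite(medians)
    df = pd.DataFrame(
        {"node_a": pairs[valid, 0], "node_b": pairs[valid, 1], "g": medians[valid]}
    )
    edges = df.groupby(["node_a", "node_b"], as_index=False).agg(
        count=("g", "size"), g=("g", "mean")
    )
    return TractometryResult(medians=medians, edges=edges, step=step)
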