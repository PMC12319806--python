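"""Streamline container and TCK I/O.

Streamlines are ordered 3D polylines in world millimetre coordinates (the TCK
convention).  :class:`StreamlineSet` is a thin list-of-arrays container with
optional per-streamline scalar weights; file I/O goes through
``nibabel.streamlines``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile

__all__ = ["StreamlineSet", "resample_polyline", "polyline_length"]


def polyline_length(points) -> float:
    """Arc length (mm) of a polyline."""
    pts = np.asarray(points, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def resample_polyline(points, step: float) -> np.ndarray:
    """Resample a polyline at arc-length-uniform spacing ``step`` (mm).

    The first and last points are always included; interior samples sit at
    multiples of ``step`` along the cumulative arc length.
    """
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return pts[:1].copy()
    targets = np.arange(0.0, total, step)
    if total - targets[-1] > 1e-9:
        targets = np.concatenate([targets, [total]])
    else:
        targets[-1] = total
    out = np.empty((targets.size, 3))
    for dim in range(3):
        out[:, dim] = np.interp(targets, s, pts[:, dim])
    return out


@dataclass
class StreamlineSet:
    """Ordered polylines in world mm, with optional per-streamline weights."""

    streamlines: list = field(default_factory=list)
    weights: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __getitem__(self, i):
        return self.streamlines[i]

    def lengths(self) -> np.ndarray:
        return np.array([polyline_length(s) for s in self.streamlines])

    def subset(self, indices) -> "StreamlineSet":
        indices = np.asarray(indices)
        w = None if self.weights is None else np.asarray(self.weights)[indices]
        return StreamlineSet([self.streamlines[int(i)] for i in indices], w)

    def save_tck(self, path) -> None:
        tractogram = Tractogram(
            [np.asarray(s, dtype=np.float32) for s in self.streamlines],
            affine_to_rasmm=np.eye(4),
        )
        TckFile(tractogram).save(str(path))

    @classmethod
    def load_tck(cls, path) -> "StreamlineSet":
        tck = nib.streamlines.load(str(path))
        return cls([np.asarray(s, dtype=float) for s in tck.streamlines])
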