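"""Volume-weighted connectomes, edge g-ratio, and cohort edge filters.

An edge is the bundle of streamlines connecting two parcellation nodes.  Its
myelin volume MV and intra-axonal volume AV are the sums of the member
streamlines' fitted volumes; the tract-specific aggregate g-ratio follows as
``sqrt(AV / (AV + MV))`` — an intensive quantity, invariant to how the volume
is split among streamlines.  The tract caliber is the sum of the member
streamlines' intra-axonal and myelin cross-sectional areas (mm^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .fit import StreamlineWeights
from .maps import compute_gratio
from .streamlines import StreamlineSet

logger = logging.getLogger(__name__)

__all__ = [
    "Connectome",
    "assign_edges",
    "build_connectome",
    "caliber_filter",
    "consensus_filter",
    "single_fiber_roi_compare",
]


def assign_edges(
    streamlines: StreamlineSet,
    parcellation: np.ndarray,
    affine: np.ndarray,
    search_radius: float = 2.0,
):
    """Map each streamline to the (node_a, node_b) labels of its endpoints.

    An endpoint takes the label of its containing voxel; if that is
    background (0) the nearest labelled voxel centre within ``search_radius``
    mm is used (ties broken by distance, then by smaller label).  Streamlines
    with any unresolved endpoint get the pair (-1, -1) and are counted.

    Returns ``(pairs, assigned_mask)`` with ``pairs`` an (n, 2) int array of
    (min, max) node labels.
    """
    parc = np.asarray(parcellation)
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    shape = np.asarray(parc.shape)
    voxel_edge = float(np.cbrt(abs(np.linalg.det(np.asarray(affine)[:3, :3]))))
    r_vox = int(np.ceil(search_radius / voxel_edge))
    offsets = np.array(list(product(range(-r_vox, r_vox + 1), repeat=3)))

    def endpoint_label(p_world):
        v = p_world @ inv[:3, :3].T + inv[:3, 3]
        idx = np.floor(v + 0.5).astype(int)
        if np.all(idx >= 0) and np.all(idx < shape):
            lab = int(parc[tuple(idx)])
            if lab > 0:
                return lab
        best = (np.inf, -1)
        for off in offsets:
            j = idx + off
            if np.any(j < 0) or np.any(j >= shape):
                continue
            lab = int(parc[tuple(j)])
            if lab <= 0:
                continue
            centre = j @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
            d = float(np.linalg.norm(centre - p_world))
            if d <= search_radius and (d, lab) < best:
                best = (d, lab)
        return best[1]

    pairs = np.empty((len(streamlines), 2), dtype=int)
    assigned = np.ones(len(streamlines), dtype=bool)
    for i, line in enumerate(streamlines):
        a = endpoint_label(np.asarray(line)[0])
        b = endpoint_label(np.asarray(line)[-1])
        if a < 0 or b < 0:
            pairs[i] = (-1, -1)
            assigned[i] = False
        else:
            pairs[i] = (min(a, b), max(a, b))
    dropped = int((~assigned).sum())
    if dropped:
        logger.info("assign_edges: %d streamlines with unassigned endpoints", dropped)
    return pairs, assigned


@dataclass
class Connectome:
    """Edge table of an undirected, diagonal-free volume-weighted connectome.

    ``edges`` columns: node_a < node_b, count, mv (mm^3), av (mm^3),
    caliber (mm^2), scaled_caliber (1/mm), g.  Edges with AV + MV = 0 keep a
    NaN g and a ``degenerate`` flag.
    """

    edges: pd.DataFrame
    node_labels: np.ndarray

    def matrix(self, metric: str = "g") -> pd.DataFrame:
        labels = np.asarray(self.node_labels)
        m = pd.DataFrame(np.nan, index=labels, columns=labels)
        for _, row in self.edges.iterrows():
            m.loc[row.node_a, row.node_b] = row[metric]
            m.loc[row.node_b, row.node_a] = row[metric]
        return m

    def density(self) -> float:
        n = len(self.node_labels)
        possible = n * (n - 1) / 2
        return len(self.edges) / possible if possible else np.nan

    def subset(self, keep_mask) -> "Connectome":
        return Connectome(
            self.edges.loc[np.asarray(keep_mask)].reset_index(drop=True),
            self.node_labels,
        )


def build_connectome(
    node_pairs: np.ndarray,
    mv_weights: StreamlineWeights,
    av_weights: StreamlineWeights,
    node_volumes: dict | None = None,
    node_labels=None,
) -> Connectome:
    """Aggregate per-streamline volumes into an edge table.

    Streamlines with pair (-1, -1) (unassigned) or equal endpoints
    (self-loops) are ignored.  ``node_volumes`` (mm^3 per label) enables the
    node-volume-scaled caliber ``caliber / (vol_a + vol_b)``.
    """
    pairs = np.asarray(node_pairs)
    valid = (pairs[:, 0] > 0) & (pairs[:, 0] != pairs[:, 1])
    df = pd.DataFrame(
        {
            "node_a": pairs[valid, 0],
            "node_b": pairs[valid, 1],
            "mv": mv_weights.volume[valid],
            "av": av_weights.volume[valid],
            "caliber": av_weights.csa[valid] + mv_weights.csa[valid],
        }
    )
    grouped = (
        df.groupby(["node_a", "node_b"], as_index=False)
        .agg(count=("mv", "size"), mv=("mv", "sum"), av=("av", "sum"),
             caliber=("caliber", "sum"))
    )
    grouped["g"] = compute_gratio(grouped["av"].to_numpy(), grouped["mv"].to_numpy())
    grouped["degenerate"] = (grouped["av"] + grouped["mv"]) <= 0
    if node_volumes is not None:
        vols = grouped.apply(
            lambda r: node_volumes.get(int(r.node_a), np.nan)
            + node_volumes.get(int(r.node_b), np.nan),
            axis=1,
        )
        grouped["scaled_caliber"] = grouped["caliber"] / vols
    else:
        grouped["scaled_caliber"] = np.nan
    if node_labels is None:
        node_labels = np.unique(pairs[valid])
    return Connectome(grouped, np.asarray(node_labels))


def caliber_filter(cohort: list, keep_fraction: float = 0.20):
    """Remove the bottom ``1 - keep_fraction`` of edges by total caliber,
    pooled across the whole cohort (all subjects and sessions).

    The threshold is the caliber of the ``floor(keep_fraction * n)``-th
    largest pooled edge; edges tied with the threshold are kept everywhere,
    so with distinct calibers exactly that many pooled edges survive.
    """
    if not cohort:
        raise ValueError("empty cohort")
    pooled = np.concatenate([c.edges["caliber"].to_numpy() for c in cohort])
    n = pooled.size
    keep = int(np.floor(keep_fraction * n))
    if keep <= 0:
        threshold = np.inf
    else:
        threshold = np.sort(pooled)[n - keep]
    return [c.subset(c.edges["caliber"].to_numpy() >= threshold) for c in cohort]


def consensus_filter(
    cohort: list, min_presence: float = 0.5, subject_ids=None
):
    """Keep only edges present (nonzero streamline count) in at least
    ``ceil(min_presence * n_subjects)`` subjects; applied to every
    connectome.  ``subject_ids`` groups multiple sessions per subject; by
    default each connectome is its own subject.
    """
    if subject_ids is None:
        subject_ids = list(range(len(cohort)))
    subjects = sorted(set(subject_ids))
    need = int(np.ceil(min_presence * len(subjects)))

    presence: dict = {}
    for conn, sid in zip(cohort, subject_ids):
        present = conn.edges.loc[conn.edges["count"] > 0]
        for a, b in zip(present["node_a"], present["node_b"]):
            presence.setdefault((int(a), int(b)), set()).add(sid)
    keep_edges = {e for e, s in presence.items() if len(s) >= need}

    out = []
    for conn in cohort:
        mask = [
            (int(a), int(b)) in keep_edges
            for a, b in zip(conn.edges["node_a"], conn.edges["node_b"])
        ]
        out.append(conn.subset(np.asarray(mask, dtype=bool)))
    return out


def single_fiber_roi_compare(
    g_map: np.ndarray,
    fa: np.ndarray,
    roi_masks: dict,
    segmap,
    streamline_medians: np.ndarray,
    mv_weights: StreamlineWeights,
    av_weights: StreamlineWeights,
    fa_thresh: float = 0.7,
) -> pd.DataFrame:
    """Compare the three g-ratio estimates inside single-fiber regions.

    For each ROI (restricted to voxels with FA above ``fa_thresh``):

    * ``voxel`` — median of the volumetric g-ratio map over the ROI;
    * ``tractometry`` — median of the per-streamline tractometry medians of
      streamlines traversing the ROI;
    * ``tract_specific`` — aggregate g of those streamlines from their summed
      fitted AV and MV.

    Empty ROIs yield NaN rows.
    """
    rows = []
    for name, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool) & (np.asarray(fa) > fa_thresh)
        if not mask.any():
            rows.append(
                {"roi": name, "voxel": np.nan, "tractometry": np.nan,
                 "tract_specific": np.nan, "n_streamlines": 0}
            )
            continue
        vals = np.asarray(g_map)[mask]
        voxel_med = float(np.nanmedian(vals))
        flat_roi = set(np.flatnonzero(mask.ravel()).tolist())
        traversing = []
        for si in range(segmap.n_streamlines):
            if len(segmap.voxels[si]) == 0:
                continue
            flat = np.ravel_multi_index(segmap.voxels[si].T, segmap.grid_shape)
            if any(int(f) in flat_roi for f in flat):
                traversing.append(si)
        if traversing:
            tm = float(np.nanmedian(streamline_medians[traversing]))
            av = float(av_weights.volume[traversing].sum())
            mv = float(mv_weights.volume[traversing].sum())
            ts = float(compute_gratio(av, mv))
        else:
            tm = ts = np.nan
        rows.append(
            {"roi": name, "voxel": voxel_med, "tractometry": tm,
             "tract_specific": ts, "n_streamlines": len(traversing)}
        )
    return pd.DataFrame(rows)
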