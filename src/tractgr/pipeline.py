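"""End-to-end tract-specific and tractometry pipelines on a phantom.

Chains the full method: simulate the multi-shell signal, filter the
tractogram against the diffusion data, fit per-streamline myelin areas to the
MVF map, refit the myelin-corrected signal for true intra-axonal areas, build
the MV/AV-weighted connectome with edge g-ratios, and run the conventional
tractometry comparator on the same filtered streamlines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import Connectome, assign_edges, build_connectome
from .fit import (
    FilterResult,
    StreamlineWeights,
    fit_filtering,
    fit_myelin,
    fit_true_axonal,
    myelin_correct_signal,
)
from .geometry import KernelParams, build_segment_map
from .phantom import GroundTruth, PhantomSpec, build_phantom, default_scheme, simulate_dwi
from .streamlines import StreamlineSet
from .tractometry import TractometryResult, edge_tractometry, streamline_medians

__all__ = ["PhantomPipelineResult", "run_phantom_pipeline", "node_volumes_from_parcellation"]


def node_volumes_from_parcellation(parcellation, voxel_volume: float) -> dict:
    labels, counts = np.unique(parcellation[parcellation > 0], return_counts=True)
    return {int(l): float(c) * voxel_volume for l, c in zip(labels, counts)}


@dataclass
class PhantomPipelineResult:
    truth: GroundTruth
    streamlines: StreamlineSet
    parcellation: np.ndarray
    calib_roi: np.ndarray
    filter_result: FilterResult
    mv_weights: StreamlineWeights       # over filtered streamlines
    av_weights: StreamlineWeights
    node_pairs: np.ndarray
    connectome: Connectome
    tractometry: TractometryResult
    comparison: pd.DataFrame            # per true bundle: g_true vs both methods


def run_phantom_pipeline(
    spec: PhantomSpec,
    scheme=None,
    kernels: KernelParams | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> PhantomPipelineResult:
    """Run the complete two-branch pipeline on a synthetic phantom.

    The fitting mask is the set of voxels traversed by any streamline.  The
    tractometry branch samples the ground-truth volumetric g-ratio map (the
    stand-in for the calibrated in-vivo map) along the same filtered
    streamlines used by the tract-specific branch.
    """
    scheme = scheme or default_scheme()
    kernels = kernels or KernelParams()
    streamlines, truth, parcellation, calib_roi = build_phantom(spec)
    dwi = simulate_dwi(
        truth, streamlines, scheme, kernels,
        noise_sigma=spec.noise_sigma, seed=spec.seed,
    )

    segmap = build_segment_map(streamlines, truth.affine, truth.grid_shape)
    mask = np.zeros(truth.grid_shape, dtype=bool)
    traversed = segmap.traversed_voxels()
    mask.ravel()[traversed] = True

    filt = fit_filtering(
        dwi, streamlines, scheme, kernels, mask, truth.affine,
        tol=tol, max_iter=max_iter,
    )
    kept = filt.filtered

    mv_w = fit_myelin(truth.mvf, kept, mask, truth.affine, tol=tol, max_iter=max_iter)
    corrected, cmask = myelin_correct_signal(dwi, truth.mvf, scheme, mask)
    av_w = fit_true_axonal(
        corrected, kept, scheme, kernels, cmask, truth.affine,
        tol=tol, max_iter=max_iter,
    )

    pairs, _ = assign_edges(kept, parcellation, truth.affine)
    vols = node_volumes_from_parcellation(parcellation, truth.voxel_volume)
    conn = build_connectome(pairs, mv_w, av_w, node_volumes=vols)

    medians = streamline_medians(truth.g, truth.affine, kept, step=spec.step)
    tracto = edge_tractometry(medians, pairs, step=spec.step)

    comparison = _compare_to_truth(truth, conn, tracto)
    return PhantomPipelineResult(
        truth=truth,
        streamlines=streamlines,
        parcellation=parcellation,
        calib_roi=calib_roi,
        filter_result=filt,
        mv_weights=mv_w,
        av_weights=av_w,
        node_pairs=pairs,
        connectome=conn,
        tractometry=tracto,
        comparison=comparison,
    )


def _compare_to_truth(truth, conn: Connectome, tracto: TractometryResult):
    rows = []
    for _, edge in truth.edges.iterrows():
        key = (edge.node_a, edge.node_b)
        ts = conn.edges.loc[
            (conn.edges.node_a == key[0]) & (conn.edges.node_b == key[1])
        ]
        tm = tracto.edges.loc[
            (tracto.edges.node_a == key[0]) & (tracto.edges.node_b == key[1])
        ]
        rows.append(
            {
                "bundle": int(edge.bundle),
                "node_a": key[0],
                "node_b": key[1],
                "g_true": edge.g,
                "av_true": edge.av,
                "mv_true": edge.mv,
                "g_tract_specific": float(ts.g.iloc[0]) if len(ts) else np.nan,
                "av_fit": float(ts.av.iloc[0]) if len(ts) else np.nan,
                "mv_fit": float(ts.mv.iloc[0]) if len(ts) else np.nan,
                "g_tractometry": float(tm.g.iloc[0]) if len(tm) else np.nan,
            }
        )
    return pd.DataFrame(rows)
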