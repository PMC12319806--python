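"""Repeatability and variability analytics for edge-level g-ratio cohorts.

Covers scan-rescan agreement (ICC(2,1) and Bland–Altman limits in percent of
the pairwise mean), inter-subject coefficient of variation, global z-scoring
of edge distributions, cross-technique Pearson correlation, and the
mixed-effects model relating edge g-ratio to tract caliber and length:

    g = b0 + b1 * caliber + b2 * length + u0_subject + u1_subject * length + eps

fit by restricted maximum likelihood with a random intercept and a random
length slope per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "MixedModelResult",
    "icc_scan_rescan",
    "bland_altman",
    "cova",
    "zscore_edges",
    "fit_mixed_model",
    "cross_technique_correlation",
    "simulate_mixed_model_data",
]


def icc_scan_rescan(scan: np.ndarray, rescan: np.ndarray) -> float:
    """Intraclass correlation ICC(2,1): two-way random effects, absolute
    agreement, single measurement — the scan-rescan convention.

    ``scan`` and ``rescan`` are paired observations over targets (edges,
    possibly pooled over subjects).  Returns NaN when the total variance is
    zero.
    """
    x = np.asarray(scan, dtype=float)
    y = np.asarray(rescan, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scan and rescan must be equal-length 1D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    data = np.stack([x, y], axis=1)   # n targets x k=2 raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        return np.nan
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return np.nan
    return float((msr - mse) / denom)


def bland_altman(scan: np.ndarray, rescan: np.ndarray):
    """Bland–Altman agreement with differences in percent of the pairwise mean.

    Returns ``(mean_diff, lower, upper)`` where the limits are
    ``mean +/- 1.96 sd`` of the percentage differences.  With a single pair
    the sd is undefined and the limits are NaN.
    """
    x = np.asarray(scan, dtype=float)
    y = np.asarray(rescan, dtype=float)
    mean_pair = 0.5 * (x + y)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff_pct = 100.0 * (x - y) / mean_pair
    diff_pct = diff_pct[np.isfinite(diff_pct)]
    if diff_pct.size == 0:
        return np.nan, np.nan, np.nan
    mean = float(diff_pct.mean())
    if diff_pct.size < 2:
        warnings.warn("single pair: limits of agreement undefined", stacklevel=2)
        return mean, np.nan, np.nan
    sd = float(diff_pct.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def cova(edge_values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Coefficient of variation (sd/mean) across subjects, per edge.

    ``edge_values`` is subjects x edges (scan/rescan already averaged per
    subject).  Edges with zero mean yield NaN.  Aggregation to network pairs
    or nodes is a plain mean over member edges of this output.
    """
    vals = np.asarray(edge_values, dtype=float)
    mean = vals.mean(axis=axis)
    sd = vals.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = sd / mean
    return np.where(mean != 0, out, np.nan)


def zscore_edges(values: np.ndarray):
    """Z-score with a single global mean/sd over all edges and subjects."""
    vals = np.asarray(values, dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0 or np.ptp(finite) == 0:
        return np.zeros_like(vals)
    return (vals - finite.mean()) / finite.std(ddof=0)


def cross_technique_correlation(
    technique_a: np.ndarray, technique_b: np.ndarray
) -> np.ndarray:
    """Pearson correlation across subjects, per edge.

    Inputs are subjects x edges arrays of matched edges; aggregation to
    networks or nodes is a mean over the per-edge correlations.
    """
    a = np.asarray(technique_a, dtype=float)
    b = np.asarray(technique_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("technique arrays must share shape")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    num = (a * b).sum(axis=0)
    den = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    return np.where(den > 0, r, np.nan)


@dataclass
class MixedModelResult:
    """REML fit of the caliber/length mixed model."""

    beta: dict                       # intercept, caliber, length
    conf_int: dict                   # 95% CI per fixed effect
    pvalues: dict
    random_effects: dict             # per subject: intercept (and length slope)
    resid_var: float
    adjusted_r2: float               # marginal (fixed-effects) adjusted R^2
    random_slope: bool               # False if fell back to intercept-only
    converged: bool
    model: object = field(repr=False, default=None)

    def adjusted_g(self, data: pd.DataFrame, keep: str) -> np.ndarray:
        """g with the random effects and the *other* fixed effect removed,
        for plotting g against ``keep`` (one of 'caliber', 'length')."""
        other = "length" if keep == "caliber" else "caliber"
        g = data["g"].to_numpy(dtype=float).copy()
        g -= self.beta[other] * data[other].to_numpy(dtype=float)
        for sid, re in self.random_effects.items():
            sel = (data["subject"] == sid).to_numpy()
            g[sel] -= re.get("intercept", 0.0)
            if self.random_slope:
                g[sel] -= re.get("length", 0.0) * data.loc[sel, "length"].to_numpy()
        return g


def fit_mixed_model(data: pd.DataFrame, reml: bool = True) -> MixedModelResult:
    """Fit ``g ~ caliber + length`` with per-subject random intercept and
    random length slope (REML).

    ``data`` needs columns ``g``, ``caliber`` (node-volume-scaled), ``length``
    and ``subject``.  A singular random-effects covariance triggers a
    fallback to a random-intercept-only model, flagged in the result.
    """
    required = {"g", "caliber", "length", "subject"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    if data["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")

    def _fit(re_formula):
        model = smf.mixedlm(
            "g ~ caliber + length", data, groups=data["subject"],
            re_formula=re_formula,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=reml, method="lbfgs", maxiter=500)

    random_slope = True
    res = _fit("~length")
    singular = (
        not np.all(np.isfinite(np.asarray(res.cov_re)))
        or np.linalg.matrix_rank(np.asarray(res.cov_re)) < res.cov_re.shape[0]
    )
    if singular:
        random_slope = False
        res = _fit("1")

    names = {"Intercept": "intercept", "caliber": "caliber", "length": "length"}
    beta = {names[k]: float(res.fe_params[k]) for k in names}
    ci = res.conf_int()
    conf = {names[k]: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in names}
    pvals = {names[k]: float(res.pvalues[k]) for k in names}

    re_out = {}
    for sid, re in res.random_effects.items():
        entry = {"intercept": float(re.iloc[0])}
        if random_slope and len(re) > 1:
            entry["length"] = float(re.iloc[1])
        re_out[sid] = entry

    fitted_fixed = (
        beta["intercept"]
        + beta["caliber"] * data["caliber"].to_numpy(dtype=float)
        + beta["length"] * data["length"].to_numpy(dtype=float)
    )
    g = data["g"].to_numpy(dtype=float)
    n, p = g.size, 2
    ss_res = float(((g - fitted_fixed) ** 2).sum())
    ss_tot = float(((g - g.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)

    return MixedModelResult(
        beta=beta,
        conf_int=conf,
        pvalues=pvals,
        random_effects=re_out,
        resid_var=float(res.scale),
        adjusted_r2=float(adj_r2),
        random_slope=random_slope,
        converged=bool(res.converged),
        model=res,
    )


def simulate_mixed_model_data(
    n_subjects: int = 20,
    n_edges: int = 200,
    beta0: float = 0.70,
    beta1: float = -7.46e-3,
    beta2: float = 4.04e-4,
    sd_intercept: float = 0.01,
    sd_slope: float = 1.0e-4,
    sd_noise: float = 0.02,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Synthetic edge table drawn from the caliber/length mixed model.

    Defaults use the tract-specific fixed effects (negative caliber effect,
    positive length effect) with calibers ~ |N(0, 1)| in node-volume-scaled
    units and lengths uniform on 10–160 mm, spanning the plausible tract
    range.  Setting the sds to 0 collapses to a deterministic linear model.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        u0 = rng.normal(0.0, sd_intercept) if sd_intercept > 0 else 0.0
        u1 = rng.normal(0.0, sd_slope) if sd_slope > 0 else 0.0
        caliber = np.abs(rng.normal(0.0, 1.0, n_edges))
        length = rng.uniform(10.0, 160.0, n_edges)
        eps = rng.normal(0.0, sd_noise, n_edges) if sd_noise > 0 else 0.0
        g = beta0 + beta1 * caliber + beta2 * length + u0 + u1 * length + eps
        rows.append(
            pd.DataFrame(
                {"subject": s, "caliber": caliber, "length": length, "g": g}
            )
        )
    return pd.concat(rows, ignore_index=True)
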