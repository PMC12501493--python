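"""MR-PRESSO: simulation-based pleiotropy residual sum and outlier test.

The global test compares the observed weighted residual sum of squares
around leave-one-out IVW fits to its distribution under the no-pleiotropy
model, estimated by parametric simulation; the outlier test assigns each
SNP a simulation p-value for its own residual (Bonferroni-flagged); the
distortion test asks whether removing the flagged outliers changes the
causal estimate more than removing random SNP subsets of the same size.

All simulation p-values use add-one smoothing, (1 + #extreme)/(n_sim + 1),
so no p can be exactly zero. Agreement with the reference algorithm is
statistical, not bitwise: RNG streams differ.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .harmonize import HarmonizedSet
from .mr import ivw
from .models import MREstimate, PressoResult

__all__ = ["presso_global", "presso_outlier", "presso_distortion", "run_presso"]


def _xyw(hs) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    df = hs.data if isinstance(hs, HarmonizedSet) else hs
    x = df["beta_exp"].to_numpy(dtype=float)
    sx = df["se_exp"].to_numpy(dtype=float)
    y = df["beta_out"].to_numpy(dtype=float)
    sy = df["se_out"].to_numpy(dtype=float)
    return x, sx, y, sy, [str(s) for s in df["snp"]]


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes theta_{-i}, vectorized.

    IVW equals WLS through the origin with weights 1/se_out², so
    theta_{-i} = (S_xy - w_i x_i y_i) / (S_xx - w_i x_i²).
    """
    sxy = np.sum(w * x * y, axis=-1, keepdims=True)
    sxx = np.sum(w * x * x, axis=-1, keepdims=True)
    return (sxy - w * x * y) / (sxx - w * x * x)


def presso_global(
    hs: HarmonizedSet | pd.DataFrame,
    n_sim: int = 1000,
    seed: Optional[int] = None,
    redraw_exposure: bool = True,
) -> PressoResult:
    """Global heterogeneity test on the weighted residual sum of squares.

    For each SNP i, the residual r_i = beta_out_i - theta_{-i}·beta_exp_i is
    taken about the leave-one-out IVW slope; rss_obs = sum w_i r_i² with
    w = 1/se_out². ``n_sim`` datasets are simulated under the null
    (beta_out* ~ Normal(theta_{-i}·beta_exp_i, se_out_i); exposure betas are
    re-drawn ~ Normal(beta_exp_i, se_exp_i) too unless ``redraw_exposure``
    is off), the statistic recomputed identically on each, and
    p_global = (1 + #{RSS* >= rss_obs}) / (n_sim + 1).
    """
    if seed is None:
        raise ValueError("presso_global requires an explicit seed")
    x, sx, y, sy, snps = _xyw(hs)
    k = len(x)
    if k < 4:
        raise ValueError(f"MR-PRESSO requires k >= 4 SNPs, got {k}")
    # canonicalize so the simulation p-value is exactly invariant to SNP
    # reordering and to joint allele flips: orient beta_exp >= 0 and sort by
    # SNP id; per-SNP outputs are mapped back to the input order at the end
    flip = np.where(x < 0, -1.0, 1.0)
    x, y = x * flip, y * flip
    order = np.argsort(np.asarray(snps, dtype=object), kind="stable")
    inverse = np.argsort(order, kind="stable")
    x, sx, y, sy = x[order], sx[order], y[order], sy[order]
    w = 1.0 / sy**2
    theta_loo = _loo_slopes(x[None, :], y[None, :], w[None, :])[0]
    resid = y - theta_loo * x
    rss_obs = float(np.sum(w * resid**2))

    rng = np.random.default_rng(seed)
    mu = theta_loo * x
    y_sim = rng.normal(loc=mu, scale=sy, size=(n_sim, k))
    if redraw_exposure:
        x_sim = rng.normal(loc=x, scale=sx, size=(n_sim, k))
    else:
        x_sim = np.broadcast_to(x, (n_sim, k))
    w_sim = np.broadcast_to(w, (n_sim, k))
    theta_loo_sim = _loo_slopes(x_sim, y_sim, w_sim)
    resid_sim = y_sim - theta_loo_sim * x_sim
    rss_sim = np.sum(w_sim * resid_sim**2, axis=1)

    p_global = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    return PressoResult(
        rss_obs=rss_obs,
        p_global=p_global,
        n_sim=n_sim,
        seed=seed,
        snp_ids=tuple(snps),
        _sim_abs_resid=np.abs(resid_sim)[:, inverse],
        _obs_abs_resid=np.abs(resid)[inverse],
    )


def presso_outlier(
    hs: HarmonizedSet | pd.DataFrame,
    global_result: PressoResult,
    alpha: float = 0.05,
) -> PressoResult:
    """Per-SNP outlier test on the stored simulated residual distributions.

    p_i = (1 + #{|r*_i| >= |r_i|}) / (n_sim + 1); SNP i is flagged when
    p_i < alpha/k (Bonferroni across the k tested SNPs). Also fills in the
    raw and outlier-corrected IVW estimates.
    """
    if global_result._sim_abs_resid is None:
        raise ValueError("run presso_global first (simulated residuals not stored)")
    sim_abs = np.asarray(global_result._sim_abs_resid)
    obs_abs = np.asarray(global_result._obs_abs_resid)
    n_sim = global_result.n_sim
    k = len(obs_abs)
    pvals = (1 + np.sum(sim_abs >= obs_abs[None, :], axis=0)) / (n_sim + 1)
    flagged = tuple(int(i) for i in np.flatnonzero(pvals < alpha / k))

    df = hs.data if isinstance(hs, HarmonizedSet) else hs
    theta_raw, _ = ivw(df, model="fixed")
    theta_corrected: Optional[MREstimate] = None
    if flagged and k - len(flagged) >= 2:
        keep = df.drop(df.index[list(flagged)]).reset_index(drop=True)
        theta_corrected, _ = ivw(keep, model="fixed")

    return PressoResult(
        rss_obs=global_result.rss_obs,
        p_global=global_result.p_global,
        n_sim=n_sim,
        seed=global_result.seed,
        outlier_pvals=[float(p) for p in pvals],
        outlier_indices=flagged,
        snp_ids=global_result.snp_ids,
        theta_raw=theta_raw,
        theta_corrected=theta_corrected,
        _sim_abs_resid=global_result._sim_abs_resid,
        _obs_abs_resid=global_result._obs_abs_resid,
    )


def presso_distortion(
    hs: HarmonizedSet | pd.DataFrame,
    result: PressoResult,
    n_sim: Optional[int] = None,
    seed: Optional[int] = None,
) -> PressoResult:
    """Distortion test: is the outlier-driven shift in theta larger than
    expected from removing random non-outlier subsets of the same size?

    D = 100·(theta_raw - theta_corrected)/|theta_corrected|; the null draws
    random subsets from the non-outlier SNPs, removes them, and recomputes
    D. Returns the result with ``p_distortion`` set, or with ``None``
    (not applicable) when no outliers were flagged or too few SNPs remain.
    """
    df = hs.data if isinstance(hs, HarmonizedSet) else hs
    k = len(df)
    n_out = len(result.outlier_indices)
    if n_out == 0 or result.theta_corrected is None or k - n_out < 2:
        result.p_distortion = None
        result.distortion_coefficient = None
        return result
    if result.theta_corrected.theta == 0:
        raise ZeroDivisionError("distortion coefficient undefined: corrected theta is 0")
    n_sim = n_sim or result.n_sim
    seed = result.seed + 1 if seed is None else seed
    rng = np.random.default_rng(seed)

    theta_raw = result.theta_raw.theta
    d_obs = 100.0 * (theta_raw - result.theta_corrected.theta) / abs(result.theta_corrected.theta)

    non_outliers = np.setdiff1d(np.arange(k), np.asarray(result.outlier_indices, dtype=int))
    x, _, y, sy, _ = _xyw(df)
    w = 1.0 / sy**2
    sxy, sxx = np.sum(w * x * y), np.sum(w * x * x)
    d_null = np.empty(n_sim)
    for b in range(n_sim):
        drop = rng.choice(non_outliers, size=n_out, replace=False)
        theta_b = (sxy - np.sum(w[drop] * x[drop] * y[drop])) / (sxx - np.sum(w[drop] * x[drop] ** 2))
        d_null[b] = 100.0 * (theta_raw - theta_b) / abs(theta_b) if theta_b != 0 else np.inf
    result.distortion_coefficient = float(d_obs)
    result.p_distortion = float(np.mean(np.abs(d_null) >= abs(d_obs)))
    return result


def run_presso(
    hs: HarmonizedSet | pd.DataFrame,
    n_sim: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    redraw_exposure: bool = True,
    distortion: bool = True,
) -> PressoResult:
    """Global, outlier, and (when applicable) distortion tests in sequence."""
    result = presso_global(hs, n_sim=n_sim, seed=seed, redraw_exposure=redraw_exposure)
    result = presso_outlier(hs, result, alpha=alpha)
    if distortion:
        result = presso_distortion(hs, result)
    return result
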