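"""Two-sample MR estimators, heterogeneity statistics, and OR reporting.

Notation: for SNP *i*, ``beta_exp`` (x_i) is the per-allele SBP effect with
standard error ``se_exp``; ``beta_out`` (y_i) the per-allele outcome
log-odds with standard error ``se_out``. The Wald ratio y_i/x_i estimates
the causal log-odds per 1 mmHg SBP increase; IVW pools ratios with
inverse-variance weights, which is algebraically a weighted least-squares
regression of y on x through the origin with weights 1/se_out².

Multiplicative random effects inflate the fixed-effect SE by
sqrt(Q/(k-1)) floored at 1 — underdispersion never shrinks the SE. ``auto``
model selection applies random effects exactly when Cochran's Q is
significant at p < 0.05, the convention used when published analyses switch
models "in the presence of heterogeneity".
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .harmonize import HarmonizedSet
from .models import EggerIntercept, HeterogeneityStats, MREstimate, Z_95

__all__ = [
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "leave_one_out",
    "to_or_per_reduction",
]


def _arrays(hs: HarmonizedSet | pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    df = hs.data if isinstance(hs, HarmonizedSet) else hs
    x = df["beta_exp"].to_numpy(dtype=float)
    sx = df["se_exp"].to_numpy(dtype=float)
    y = df["beta_out"].to_numpy(dtype=float)
    sy = df["se_out"].to_numpy(dtype=float)
    snps = [str(s) for s in df["snp"]]
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("standard errors must be > 0")
    return x, sx, y, sy, snps


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    second_order: bool = False,
) -> tuple[float, float]:
    """Single-SNP causal estimate beta_out/beta_exp with its delta-method SE.

    First-order (default): se = se_out/|beta_exp|, the standard choice that
    ignores exposure-side noise — adequate for strong instruments (F >= 10).
    ``second_order`` adds the beta_out²·se_exp²/beta_exp⁴ term.
    """
    if beta_exp == 0:
        raise ZeroDivisionError("wald ratio undefined for beta_exp = 0")
    ratio = beta_out / beta_exp
    if second_order:
        se = math.sqrt(se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4)
    else:
        se = se_out / abs(beta_exp)
    return ratio, se


def _ratios(hs) -> tuple[np.ndarray, np.ndarray, list[str]]:
    x, sx, y, sy, snps = _arrays(hs)
    if np.any(x == 0):
        raise ZeroDivisionError("beta_exp = 0 for at least one SNP; wald ratios undefined")
    return y / x, sy / np.abs(x), snps


def _two_sided_normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def ivw(
    hs: HarmonizedSet | pd.DataFrame,
    model: str = "auto",
    het_alpha: float = 0.05,
) -> tuple[MREstimate, HeterogeneityStats]:
    """Inverse-variance-weighted causal estimate with Cochran's Q and I².

    ``model``: ``fixed``, ``multiplicative_random``, or ``auto`` (random
    effects iff Q's p-value < ``het_alpha``).
    """
    if model not in ("fixed", "multiplicative_random", "auto"):
        raise ValueError(f"unknown IVW model {model!r}")
    ratios, ses, _ = _ratios(hs)
    k = len(ratios)
    if k < 2:
        raise ValueError(f"IVW requires k >= 2 SNPs, got {k}")
    w = 1.0 / ses**2
    theta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (ratios - theta) ** 2))
    df = k - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    het = HeterogeneityStats(q=q, df=df, p_q=p_q, i2=i2)

    if model == "auto":
        chosen = "multiplicative_random" if p_q < het_alpha else "fixed"
    else:
        chosen = model
    if chosen == "multiplicative_random":
        se = se_fixed * max(1.0, math.sqrt(q / df))
        method = "ivw_mre"
        note = f"multiplicative random effects (dispersion {max(1.0, math.sqrt(q / df)):.3f})"
    else:
        se = se_fixed
        method = "ivw_fe"
        note = "fixed effect"
    if model == "auto":
        note += f"; auto-selected at Q p={p_q:.3g}"
    pval = _two_sided_normal_p(theta / se) if se > 0 else 0.0
    est = MREstimate(method=method, theta=theta, se=se, pval=pval, k=k, model_note=note)
    return est, het


def egger(hs: HarmonizedSet | pd.DataFrame) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure betas with a
    free intercept; a nonzero intercept indicates directional pleiotropy.

    SNPs are oriented so beta_exp >= 0 (both betas negated where needed) —
    the fit is otherwise not invariant to allele coding. Weights 1/se_out².
    SEs use the multiplicative random-effects convention with the residual
    dispersion factor floored at 1; p-values from t(k-2).
    """
    x, sx, y, sy, snps = _arrays(hs)
    k = len(x)
    if k < 3:
        raise ValueError(f"MR-Egger requires k >= 3 SNPs, got {k}")
    flip = np.sign(x)
    flip[flip == 0] = 1.0
    x, y = x * flip, y * flip
    if np.allclose(x, x[0]):
        raise ValueError("all beta_exp identical after orientation: singular Egger design")
    w = 1.0 / sy**2
    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=w).fit()
    # normalized_cov_params = (X' W X)^-1: fixed-effect covariance
    se_fixed = np.sqrt(np.diag(fit.normalized_cov_params))
    dispersion = max(1.0, math.sqrt(fit.scale)) if k > 2 else 1.0
    se_int, se_slope = se_fixed * dispersion
    a0, theta = fit.params
    dof = k - 2
    p_slope = float(2.0 * stats.t.sf(abs(theta / se_slope), dof)) if se_slope > 0 else 0.0
    p_int = float(2.0 * stats.t.sf(abs(a0 / se_int), dof)) if se_int > 0 else 0.0
    return MREstimate(
        method="egger",
        theta=float(theta),
        se=float(se_slope),
        pval=p_slope,
        k=k,
        egger_intercept=EggerIntercept(estimate=float(a0), se=float(se_int), pval=p_int),
        model_note=f"residual dispersion {dispersion:.3f}, t({dof}) inference",
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(
    hs: HarmonizedSet | pd.DataFrame,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MREstimate:
    """Weighted-median estimator: consistent when >= 50% of instrument
    weight comes from valid instruments.

    Point estimate: linear interpolation of the ordered Wald ratios at
    standardized cumulative weight 0.5 (weights 1/se²; scale-invariant, so
    doubling all weights changes nothing). SE by parametric bootstrap:
    ratios re-drawn ~ Normal(ratio_i, se_i) with weights held fixed.
    """
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed for the bootstrap")
    ratios, ses, _ = _ratios(hs)
    k = len(ratios)
    if k < 3:
        raise ValueError(f"weighted median requires k >= 3 SNPs, got {k}")
    w = 1.0 / ses**2
    theta = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=ratios, scale=ses, size=(n_boot, k))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _weighted_median(draws[b], w)
    se = float(np.std(boots, ddof=1))
    pval = _two_sided_normal_p(theta / se) if se > 0 else 0.0
    return MREstimate(
        method="weighted_median",
        theta=theta,
        se=se,
        pval=pval,
        k=k,
        model_note=f"parametric bootstrap SE, {n_boot} draws",
    )


def leave_one_out(
    hs: HarmonizedSet | pd.DataFrame,
    model: str = "auto",
    alpha: float = 0.05,
) -> list[tuple[str, MREstimate, bool]]:
    """k IVW re-estimates, each omitting one SNP.

    Returns ``(excluded_snp, estimate, influential)`` triples; a SNP is
    flagged influential when its exclusion changes the sign of theta or the
    nominal significance (p < alpha) relative to the full-set estimate.
    """
    df = hs.data if isinstance(hs, HarmonizedSet) else hs
    k = len(df)
    if k < 3:
        raise ValueError(f"leave-one-out requires k >= 3 SNPs, got {k}")
    full, _ = ivw(df, model=model)
    out = []
    for i in range(k):
        sub = df.drop(df.index[i]).reset_index(drop=True)
        est, _ = ivw(sub, model=model)
        influential = (np.sign(est.theta) != np.sign(full.theta) and full.theta != 0) or (
            (est.pval < alpha) != (full.pval < alpha)
        )
        out.append((str(df["snp"].iloc[i]), est, bool(influential)))
    return out


def to_or_per_reduction(theta: float, se: float) -> tuple[float, float, float]:
    """Transform a log-odds estimate already on the per-1-mmHg-reduction
    scale to (OR, CI low, CI high) with a 1.96-quantile 95% interval.

    The pipeline estimates on the per-increase scale and negates exactly
    once before calling this.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    or_ = math.exp(theta)
    lo = math.exp(theta - Z_95 * se)
    hi = math.exp(theta + Z_95 * se)
    return (or_, min(lo, hi), max(lo, hi))
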