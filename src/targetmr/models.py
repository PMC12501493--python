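"""Shared result containers for drug-target MR analyses.

Conventions used throughout the package:

* Exposure effects are per-allele SBP effects (mmHg); outcome effects are
  log-odds for binary outcomes. Causal estimates (``theta``) are kept on the
  per-1-mmHg-SBP-*increase* scale internally; reporting negates exactly once,
  via :attr:`MREstimate.or_reduction` / :attr:`MREstimate.ci_reduction`, to the
  per-1-mmHg-*reduction* scale used in drug-target MR reports.
* Genomic coordinates are 1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

__all__ = [
    "CohortMeta",
    "HeterogeneityStats",
    "EggerIntercept",
    "MREstimate",
    "PressoResult",
    "DrugClassResult",
    "MIN_SNPS",
    "Z_95",
]

#: normal quantile used for 95% CIs (verbatim 1.96, the convention that
#: reproduces published drug-target MR confidence bounds)
Z_95 = 1.96

#: minimum number of SNPs each estimator requires
MIN_SNPS = {
    "wald": 1,
    "ivw_fe": 2,
    "ivw_mre": 2,
    "egger": 3,
    "weighted_median": 3,
}


@dataclass(frozen=True)
class CohortMeta:
    """Outcome cohort metadata (case/control counts and effect scale)."""

    name: str
    n_cases: int
    n_controls: int
    trait_scale: str = "log_odds"  # "log_odds" | "linear"

    def __post_init__(self) -> None:
        if self.n_cases + self.n_controls <= 0:
            raise ValueError(f"cohort {self.name!r}: n_cases + n_controls must be > 0")
        if self.trait_scale not in ("log_odds", "linear"):
            raise ValueError(f"unknown trait_scale {self.trait_scale!r}")

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        """Case prevalence mu = n_cases / (n_cases + n_controls)."""
        return self.n_cases / self.n


@dataclass
class HeterogeneityStats:
    """Cochran's Q heterogeneity test across per-SNP Wald ratios."""

    q: float
    df: int
    p_q: float
    i2: float  # max(0, (Q - df) / Q), in [0, 1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HeterogeneityStats":
        return cls(**d)


@dataclass
class EggerIntercept:
    """MR-Egger intercept: average directional pleiotropy per SNP."""

    estimate: float
    se: float
    pval: float

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EggerIntercept":
        return cls(**d)


@dataclass
class MREstimate:
    """A single method's causal estimate.

    ``theta`` is the log-odds of the outcome per 1 mmHg SBP increase. The
    reporting scale (odds ratio per 1 mmHg reduction) is exposed through
    :attr:`or_reduction` and :attr:`ci_reduction`.
    """

    method: str  # wald | ivw_fe | ivw_mre | egger | weighted_median
    theta: float
    se: float
    pval: float
    k: int
    egger_intercept: Optional[EggerIntercept] = None
    model_note: str = ""

    def __post_init__(self) -> None:
        if self.method not in MIN_SNPS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.k < MIN_SNPS[self.method]:
            raise ValueError(
                f"{self.method} requires >= {MIN_SNPS[self.method]} SNPs, got k={self.k}"
            )
        if not self.se >= 0:
            raise ValueError("se must be >= 0")

    @property
    def or_reduction(self) -> float:
        """Odds ratio per 1 mmHg SBP reduction: exp(-theta)."""
        return math.exp(-self.theta)

    @property
    def ci_reduction(self) -> tuple[float, float]:
        """95% CI for :attr:`or_reduction`, bounds ordered ascending."""
        lo = math.exp(-self.theta - Z_95 * self.se)
        hi = math.exp(-self.theta + Z_95 * self.se)
        return (min(lo, hi), max(lo, hi))

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "theta": self.theta,
            "se": self.se,
            "pval": self.pval,
            "k": self.k,
            "egger_intercept": self.egger_intercept.to_dict() if self.egger_intercept else None,
            "model_note": self.model_note,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MREstimate":
        d = dict(d)
        ei = d.pop("egger_intercept", None)
        return cls(egger_intercept=EggerIntercept.from_dict(ei) if ei else None, **d)


@dataclass
class PressoResult:
    """MR-PRESSO global, per-SNP outlier, and distortion test results.

    ``p_distortion`` is ``None`` when the distortion test is not applicable
    (no outliers, or too few SNPs left after removal) — never a silent zero.
    """

    rss_obs: float
    p_global: float
    n_sim: int
    seed: int
    outlier_pvals: Sequence[float] = field(default_factory=list)
    outlier_indices: tuple[int, ...] = ()
    snp_ids: tuple[str, ...] = ()
    theta_raw: Optional[MREstimate] = None
    theta_corrected: Optional[MREstimate] = None
    p_distortion: Optional[float] = None
    distortion_coefficient: Optional[float] = None
    # per-SNP simulated |residual| matrix kept so the outlier test can be run
    # after the global test without re-simulating (not serialized)
    _sim_abs_resid: Optional[object] = field(default=None, repr=False, compare=False)
    _obs_abs_resid: Optional[object] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        lo = 1.0 / (self.n_sim + 1)
        if not (lo - 1e-12 <= self.p_global <= 1.0):
            raise ValueError("p_global outside add-one-smoothed range")

    @property
    def outlier_snps(self) -> tuple[str, ...]:
        return tuple(self.snp_ids[i] for i in self.outlier_indices)

    def to_dict(self) -> dict:
        return {
            "rss_obs": self.rss_obs,
            "p_global": self.p_global,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "outlier_pvals": list(self.outlier_pvals),
            "outlier_indices": list(self.outlier_indices),
            "snp_ids": list(self.snp_ids),
            "theta_raw": self.theta_raw.to_dict() if self.theta_raw else None,
            "theta_corrected": self.theta_corrected.to_dict() if self.theta_corrected else None,
            "p_distortion": self.p_distortion,
            "distortion_coefficient": self.distortion_coefficient,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PressoResult":
        d = dict(d)
        for key in ("theta_raw", "theta_corrected"):
            v = d.pop(key)
            d[key] = MREstimate.from_dict(v) if v else None
        d["outlier_pvals"] = list(d["outlier_pvals"])
        d["outlier_indices"] = tuple(d["outlier_indices"])
        d["snp_ids"] = tuple(d["snp_ids"])
        return cls(**d)


@dataclass
class DrugClassResult:
    """Consolidated result for one drug class in one outcome cohort."""

    drug_class: str
    cohort: str
    estimates: dict  # method name -> MREstimate
    heterogeneity: Optional[HeterogeneityStats] = None
    presso: Optional[PressoResult] = None
    leave_one_out: Optional[list] = None  # list of (snp_id, MREstimate)
    tier: str = "null"  # significant | suggestive | null | not_estimable
    positive_control: str = "not_run"  # passed | failed | not_run
    k: int = 0
    notes: str = ""

    @property
    def primary(self) -> Optional[MREstimate]:
        """The headline IVW estimate (auto fixed/random), if estimable."""
        return self.estimates.get("ivw")

    def to_dict(self) -> dict:
        return {
            "drug_class": self.drug_class,
            "cohort": self.cohort,
            "estimates": {m: e.to_dict() for m, e in self.estimates.items()},
            "heterogeneity": self.heterogeneity.to_dict() if self.heterogeneity else None,
            "presso": self.presso.to_dict() if self.presso else None,
            "leave_one_out": (
                [[snp, est.to_dict()] for snp, est in self.leave_one_out]
                if self.leave_one_out is not None
                else None
            ),
            "tier": self.tier,
            "positive_control": self.positive_control,
            "k": self.k,
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DrugClassResult":
        loo = d.get("leave_one_out")
        return cls(
            drug_class=d["drug_class"],
            cohort=d["cohort"],
            estimates={m: MREstimate.from_dict(e) for m, e in d["estimates"].items()},
            heterogeneity=(
                HeterogeneityStats.from_dict(d["heterogeneity"]) if d.get("heterogeneity") else None
            ),
            presso=PressoResult.from_dict(d["presso"]) if d.get("presso") else None,
            leave_one_out=(
                [(snp, MREstimate.from_dict(e)) for snp, e in loo] if loo is not None else None
            ),
            tier=d.get("tier", "null"),
            positive_control=d.get("positive_control", "not_run"),
            k=d.get("k", 0),
            notes=d.get("notes", ""),
        )
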