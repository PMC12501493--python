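"""Synthetic GWAS summary statistics with known ground truth.

Simulation is at the summary level — per-SNP effects and standard errors
are drawn directly, matching the two-sample MR data model (no individual
genotypes). For the exposure (SBP, mmHg), true per-allele effects gamma_i
are drawn near target-gene regions and observed with sampling noise
``se_i = sqrt(1 / (2 maf_i (1 - maf_i) n_exposure))`` (unit-variance trait).
For a binary outcome, the true log-odds effect of SNP i is

    Gamma_i = theta * gamma_i + alpha_i + outlier_shift * 1[i in outliers]

with alpha_i ~ Normal(pleiotropy_mean, pleiotropy_sd²) horizontal
pleiotropy, observed with case-control noise
``se = 1 / sqrt(2 maf (1-maf) n mu (1-mu))``. Exposure and outcome noise
are independent (non-overlapping cohorts). LD is block-constant: blocks of
consecutive within-region SNPs share one pairwise r²; decay is not modelled.

All randomness flows from the single mandatory config seed through
:class:`numpy.random.SeedSequence`; each outcome cohort derives its own
stream from a stable hash of the cohort name, so adding a cohort never
perturbs another's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .models import CohortMeta
from .sumstats_io import CANONICAL_COLUMNS, LDTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "OutcomeDraw",
    "EqtlSim",
    "StudyData",
    "default_target_regions",
    "simulate_exposure",
    "simulate_outcome",
    "simulate_eqtl",
    "simulate_study",
    "cohort_seed",
]

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def default_target_regions() -> pd.DataFrame:
    """Synthetic drug-class -> target-gene region table.

    Nine antihypertensive drug classes with their canonical protein-target
    genes (the symbols are the field-standard targets; chromosome placement
    and coordinates are synthetic, laid out so that no two classes' windows
    overlap). One row per (class, gene), 1-based inclusive coordinates.
    """
    classes = [
        ("Adrenergic neuron blockers", ["SLC6A2"]),
        ("Alpha-adrenoceptor blockers", ["ADRA1A", "ADRA1B"]),
        ("ACE inhibitors", ["ACE"]),
        ("Angiotensin II receptor blockers", ["AGTR1"]),
        ("Beta-adrenoceptor blockers", ["ADRB1", "ADRB2"]),
        ("Calcium channel blockers", ["CACNA1C", "CACNA1D", "CACNB2"]),
        ("Loop diuretics", ["SLC12A1", "SLC12A2"]),
        ("Aldosterone antagonists", ["NR3C2"]),
        ("Thiazide diuretics", ["SLC12A3"]),
    ]
    rows = []
    gene_span = 60_000
    spacing = 1_000_000  # >> 2 * 100 kb window: class windows never overlap
    for ci, (drug_class, genes) in enumerate(classes):
        chrom = str(ci + 1)
        for gi, gene in enumerate(genes):
            start = 1_000_000 + gi * spacing
            rows.append(
                {
                    "drug_class": drug_class,
                    "gene": gene,
                    "chrom": chrom,
                    "start": start,
                    "end": start + gene_span,
                }
            )
    return pd.DataFrame(rows, columns=["drug_class", "gene", "chrom", "start", "end"])


class SimulationConfig(BaseModel):
    """Parameters of the synthetic two-sample MR study.

    Sample-size defaults mirror a large blood-pressure exposure GWAS
    (n = 757,601) and registry-scale case-control outcome cohorts; the true
    causal effect ``theta`` is the outcome log-odds per 1 mmHg SBP increase.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_snps_per_region: int = Field(default=30, ge=1)
    n_null_snps_per_region: int = Field(default=4, ge=0)
    regions: Optional[pd.DataFrame] = None
    theta: float = 1.3  # outcome log-odds per 1 SD (~19 mmHg) SBP increase
    gamma_mean: float = 0.015  # mean true per-allele SBP effect, SD units
    gamma_sd: float = 0.006
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    outlier_indices: tuple[int, ...] = ()
    outlier_shift: float = 0.0
    n_exposure: int = Field(default=757_601, gt=0)
    n_outcome: int = Field(default=199_565, gt=0)
    maf_range: tuple[float, float] = (0.05, 0.40)
    palindromic_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    palindromic_eaf_range: tuple[float, float] = (0.45, 0.55)
    swap_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    strand_flip_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    proxy_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    ld_block_size: int = Field(default=3, ge=1)
    ld_r2_within: float = Field(default=0.3, ge=0.0, lt=1.0)
    window_bp: int = Field(default=100_000, gt=0)
    seed: int

    @model_validator(mode="after")
    def _check_ranges(self) -> "SimulationConfig":
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5] with lo <= hi")
        if self.swap_fraction + self.strand_flip_fraction > 1.0:
            raise ValueError("swap_fraction + strand_flip_fraction must be <= 1")
        return self

    def resolved_regions(self) -> pd.DataFrame:
        return self.regions if self.regions is not None else default_target_regions()


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated exposure GWAS."""

    theta: float
    snp_ids: list[str]
    gamma: np.ndarray  # true per-allele SBP effects
    maf: np.ndarray
    in_window: np.ndarray  # bool: within ±window of a target region
    drug_class: list[str]  # class whose window the SNP falls in ("" outside)
    source_gene: list[str]
    palindromic_ids: set[str]
    outlier_indices: tuple[int, ...]
    proxy_map: dict[str, str] = field(default_factory=dict)  # orig snp -> proxy id

    def index_of(self, snp: str) -> int:
        return self.snp_ids.index(snp)


@dataclass
class OutcomeDraw:
    """One outcome cohort's records plus its per-cohort ground truth."""

    records: pd.DataFrame
    cohort: CohortMeta
    pleiotropy: np.ndarray  # alpha_i, aligned with truth.snp_ids
    gamma_total: np.ndarray  # Gamma_i = theta*gamma + alpha + outlier shift
    expected_actions: dict[str, str]  # snp -> harmonization action expected


def _draw_alleles(rng: np.random.Generator, n: int, palindromic: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e = np.empty(n, dtype="<U1")
    o = np.empty(n, dtype="<U1")
    for i in range(n):
        pool = _PALINDROMIC_PAIRS if palindromic[i] else _NONPALINDROMIC_PAIRS
        e[i], o[i] = pool[rng.integers(len(pool))]
    return e, o


def simulate_exposure(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth, LDTable]:
    """Simulate the exposure (SBP) GWAS, its ground truth, and an LD table.

    Within each target-gene region, ``n_snps_per_region`` SNPs are placed
    inside the ±window and carry true effects gamma_i ~
    Normal(gamma_mean, gamma_sd²); ``n_null_snps_per_region`` decoys are
    placed on the same chromosome outside every window with gamma = 0.
    Blocks of ``ld_block_size`` consecutive within-region SNPs share
    pairwise r² = ``ld_r2_within`` in the emitted LD table. A configurable
    fraction of SNPs is palindromic (A/T or C/G) with eaf drawn near 0.5.
    """
    regions = config.resolved_regions()
    if len(regions) == 0:
        raise ValueError("region set empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    rows = []
    gamma_list: list[float] = []
    in_window: list[bool] = []
    classes: list[str] = []
    genes: list[str] = []
    snp_counter = 0
    ld = LDTable()
    block_members: list[list[str]] = []

    for _, reg in regions.iterrows():
        placed: list[str] = []
        for j in range(config.n_snps_per_region):
            snp_counter += 1
            snp = f"rs{100000 + snp_counter}"
            pos = int(rng.integers(reg["start"] - config.window_bp, reg["end"] + config.window_bp + 1))
            rows.append({"snp": snp, "chrom": str(reg["chrom"]), "pos": pos})
            gamma_list.append(float(rng.normal(config.gamma_mean, config.gamma_sd)))
            in_window.append(True)
            classes.append(reg["drug_class"])
            genes.append(reg["gene"])
            placed.append(snp)
        for j in range(config.n_null_snps_per_region):
            snp_counter += 1
            snp = f"rs{100000 + snp_counter}"
            # well outside any ±window on this chromosome
            pos = int(reg["end"] + 4 * config.window_bp + j * 1_000 + rng.integers(500))
            rows.append({"snp": snp, "chrom": str(reg["chrom"]), "pos": pos})
            gamma_list.append(0.0)
            in_window.append(False)
            classes.append("")
            genes.append("")
        for b in range(0, len(placed), config.ld_block_size):
            block = placed[b : b + config.ld_block_size]
            if len(block) > 1:
                block_members.append(block)

    df = pd.DataFrame(rows)
    n = len(df)
    gamma = np.asarray(gamma_list)

    palindromic = rng.random(n) < config.palindromic_fraction
    e_allele, o_allele = _draw_alleles(rng, n, palindromic)
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=n)
    eaf = np.where(rng.random(n) < 0.5, maf, 1.0 - maf)
    pal_lo, pal_hi = config.palindromic_eaf_range
    eaf[palindromic] = rng.uniform(pal_lo, pal_hi, size=int(palindromic.sum()))
    maf = np.minimum(eaf, 1.0 - eaf)

    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    beta = rng.normal(gamma, se)
    pval = 2.0 * stats.norm.sf(np.abs(beta / se))
    pval = np.clip(pval, np.nextafter(0.0, 1.0), 1.0)

    df["effect_allele"] = e_allele
    df["other_allele"] = o_allele
    df["eaf"] = eaf
    df["beta"] = beta
    df["se"] = se
    df["pval"] = pval
    df["n"] = config.n_exposure
    df = df[list(CANONICAL_COLUMNS)]

    for block in block_members:
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                a, b = block[i], block[j]
                ia, ib = df.index[df["snp"] == a][0], df.index[df["snp"] == b][0]
                amap = {
                    df["effect_allele"].iloc[ia]: df["effect_allele"].iloc[ib],
                    df["other_allele"].iloc[ia]: df["other_allele"].iloc[ib],
                }
                if len(amap) < 2:  # degenerate letter overlap; skip map
                    amap = None
                ld.add(a, b, config.ld_r2_within, amap)

    # proxy partners: for a fraction of within-window SNPs, register a
    # high-LD companion that only the outcome studies will report
    proxy_map: dict[str, str] = {}
    if config.proxy_fraction > 0:
        candidates = np.flatnonzero(np.asarray(in_window))
        chosen = candidates[rng.random(len(candidates)) < config.proxy_fraction]
        for i in chosen:
            orig = df["snp"].iloc[i]
            proxy = f"{orig}p"
            amap = {df["effect_allele"].iloc[i]: df["effect_allele"].iloc[i],
                    df["other_allele"].iloc[i]: df["other_allele"].iloc[i]}
            ld.add(orig, proxy, 0.95, amap)
            proxy_map[orig] = proxy

    truth = SyntheticTruth(
        theta=config.theta,
        snp_ids=list(df["snp"]),
        gamma=gamma,
        maf=maf,
        in_window=np.asarray(in_window),
        drug_class=classes,
        source_gene=genes,
        palindromic_ids=set(df["snp"].iloc[np.flatnonzero(palindromic)]),
        outlier_indices=tuple(config.outlier_indices),
        proxy_map=proxy_map,
    )
    if truth.outlier_indices and max(truth.outlier_indices) >= n:
        raise ValueError("outlier_indices outside generated SNP range")
    return df, truth, ld


def cohort_seed(master_seed: int, name: str) -> int:
    """Stable per-cohort (or per-class) seed below 2^31."""
    return (master_seed * 1_000_003 + zlib.crc32(name.encode())) % (2**31)


def simulate_outcome(
    exposure: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimulationConfig,
    cohort: CohortMeta,
    theta_per_snp: Optional[np.ndarray] = None,
    maf_ambiguity: float = 0.42,
) -> OutcomeDraw:
    """Simulate one outcome cohort's summary statistics from the truth.

    The reporting convention is perturbed to exercise harmonization: a
    ``swap_fraction`` of SNPs are reported with effect/other alleles
    swapped (beta and eaf re-expressed accordingly) and a
    ``strand_flip_fraction`` of non-palindromic SNPs on the complementary
    strand. Expected harmonization actions are recorded per SNP. SNPs with
    a registered proxy partner are emitted under the proxy's id instead of
    their own (the original is absent from this cohort). Cohorts on the
    linear scale get beta and se multiplied by mu(1-mu).
    """
    if cohort.n_cases == 0:
        raise ValueError(f"cohort {cohort.name!r} has zero cases")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1, cohort_seed(0, cohort.name)])
    )
    n = len(exposure)
    theta_vec = np.full(n, truth.theta) if theta_per_snp is None else np.asarray(theta_per_snp, dtype=float)
    alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n) if (
        config.pleiotropy_mean != 0 or config.pleiotropy_sd > 0
    ) else np.zeros(n)
    gamma_total = theta_vec * truth.gamma + alpha
    if truth.outlier_indices:
        gamma_total = gamma_total.copy()
        gamma_total[list(truth.outlier_indices)] += config.outlier_shift

    mu = cohort.case_fraction
    maf = truth.maf
    # case-control log-odds SE; the cohort's own size takes precedence over
    # the config-level default when both are available
    n_out = cohort.n if cohort.n > 0 else config.n_outcome
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_out * mu * (1.0 - mu))
    beta = rng.normal(gamma_total, se)
    pval = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), np.nextafter(0.0, 1.0), 1.0)

    eaf_exp = exposure["eaf"].to_numpy(dtype=float)
    eaf = np.clip(eaf_exp + rng.normal(0.0, 0.005, size=n), 0.01, 0.99)

    u = rng.random(n)
    swap = u < config.swap_fraction
    strand = (u >= config.swap_fraction) & (u < config.swap_fraction + config.strand_flip_fraction)

    e_rep = exposure["effect_allele"].to_numpy().copy()
    o_rep = exposure["other_allele"].to_numpy().copy()
    beta_rep = beta.copy()
    eaf_rep = eaf.copy()
    expected: dict[str, str] = {}
    snp_ids = list(exposure["snp"])
    pal = np.array([s in truth.palindromic_ids for s in snp_ids])

    for i in range(n):
        snp = snp_ids[i]
        if pal[i]:
            # palindromic: strand is unknowable; plant only same-letter or
            # swapped-letter reports so the expected action is deterministic
            ambiguous = (
                min(eaf_exp[i], 1 - eaf_exp[i]) > maf_ambiguity
                or min(eaf_rep[i], 1 - eaf_rep[i]) > maf_ambiguity
            )
            if swap[i]:
                e_rep[i], o_rep[i] = o_rep[i], e_rep[i]
                beta_rep[i] = -beta_rep[i]
                eaf_rep[i] = 1.0 - eaf_rep[i]
                expected[snp] = "dropped_palindromic" if ambiguous else "flipped"
            else:
                expected[snp] = "dropped_palindromic" if ambiguous else "aligned"
            continue
        if swap[i]:
            e_rep[i], o_rep[i] = o_rep[i], e_rep[i]
            beta_rep[i] = -beta_rep[i]
            eaf_rep[i] = 1.0 - eaf_rep[i]
            expected[snp] = "flipped"
        elif strand[i]:
            e_rep[i], o_rep[i] = _COMPLEMENT[e_rep[i]], _COMPLEMENT[o_rep[i]]
            expected[snp] = "strand_corrected"
        else:
            expected[snp] = "aligned"

    records = pd.DataFrame(
        {
            "snp": snp_ids,
            "chrom": exposure["chrom"].to_numpy(),
            "pos": exposure["pos"].to_numpy(),
            "effect_allele": e_rep,
            "other_allele": o_rep,
            "eaf": eaf_rep,
            "beta": beta_rep,
            "se": se,
            "pval": pval,
            "n": cohort.n,
        }
    )

    if truth.proxy_map:
        records = records.copy()
        renamed = records["snp"].map(lambda s: truth.proxy_map.get(s, s))
        records["snp"] = renamed

    if cohort.trait_scale == "linear":
        factor = mu * (1.0 - mu)
        records["beta"] = records["beta"] * factor
        records["se"] = records["se"] * factor

    return OutcomeDraw(
        records=records[list(CANONICAL_COLUMNS)],
        cohort=cohort,
        pleiotropy=alpha,
        gamma_total=gamma_total,
        expected_actions=expected,
    )


@dataclass
class EqtlSim:
    """Synthetic cis-eQTL layer: expression instruments per target gene."""

    expression: pd.DataFrame  # canonical sumstats + "gene" column
    sbp: pd.DataFrame  # the same SNPs' effects on SBP
    gene_coefs: dict[str, float]  # expression -> SBP coefficient per gene
    eqtl_effects: np.ndarray


def simulate_eqtl(
    config: SimulationConfig,
    n_eqtl_per_gene: int = 5,
    n_eqtl_samples: int = 1_000,
    gene_sbp_coef: float | dict[str, float] = 0.5,
    eqtl_effect_range: tuple[float, float] = (0.2, 0.6),
) -> EqtlSim:
    """Simulate cis-eQTL effects on expression and their mediated SBP effects.

    Each target gene receives ``n_eqtl_per_gene`` independent cis-eQTLs with
    per-allele expression effects drawn from ``eqtl_effect_range``; the SBP
    effect of each eQTL is its expression effect times the gene-level
    expression->SBP coefficient, so reduced expression lowers SBP whenever
    the coefficient is positive.
    """
    regions = config.resolved_regions()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rows_expr, rows_sbp = [], []
    effects = []
    coefs: dict[str, float] = {}
    counter = 0
    for _, reg in regions.iterrows():
        gene = reg["gene"]
        coef = gene_sbp_coef.get(gene, 0.0) if isinstance(gene_sbp_coef, dict) else float(gene_sbp_coef)
        coefs[gene] = coef
        for j in range(n_eqtl_per_gene):
            counter += 1
            snp = f"rse{500000 + counter}"
            pos = int(rng.integers(reg["start"], reg["end"] + 1))
            maf = float(rng.uniform(*config.maf_range))
            b_expr = float(rng.uniform(*eqtl_effect_range)) * (1 if rng.random() < 0.8 else -1)
            se_expr = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_eqtl_samples)
            beta_expr = float(rng.normal(b_expr, se_expr))
            se_sbp = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
            beta_sbp = float(rng.normal(coef * b_expr, se_sbp))
            pair = _NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))]
            base = {
                "snp": snp,
                "chrom": str(reg["chrom"]),
                "pos": pos,
                "effect_allele": pair[0],
                "other_allele": pair[1],
                "eaf": maf,
            }
            rows_expr.append(
                {**base, "beta": beta_expr, "se": se_expr,
                 "pval": float(np.clip(2 * stats.norm.sf(abs(beta_expr / se_expr)), 1e-300, 1.0)),
                 "n": n_eqtl_samples, "gene": gene, "drug_class": reg["drug_class"]}
            )
            rows_sbp.append(
                {**base, "beta": beta_sbp, "se": se_sbp,
                 "pval": float(np.clip(2 * stats.norm.sf(abs(beta_sbp / se_sbp)), 1e-300, 1.0)),
                 "n": config.n_exposure}
            )
            effects.append(b_expr)
    cols = list(CANONICAL_COLUMNS)
    return EqtlSim(
        expression=pd.DataFrame(rows_expr)[cols + ["gene", "drug_class"]],
        sbp=pd.DataFrame(rows_sbp)[cols],
        gene_coefs=coefs,
        eqtl_effects=np.asarray(effects),
    )


@dataclass
class StudyData:
    """A complete synthetic nine-class, two-cohort study fixture."""

    exposure: pd.DataFrame
    truth: SyntheticTruth
    ld: LDTable
    regions: pd.DataFrame
    outcomes: dict[str, OutcomeDraw]  # primary outcome cohorts
    control: OutcomeDraw  # positive-control outcome (CAD-like)
    theta_by_class: dict[str, float]
    theta_control: float


def simulate_study(
    config: SimulationConfig,
    theta_by_class: Optional[dict[str, float]] = None,
    theta_control: float = 0.5,
    cohorts: Optional[Sequence[CohortMeta]] = None,
    control_cohort: Optional[CohortMeta] = None,
) -> StudyData:
    """Generate the full study fixture: exposure GWAS, LD, two independent
    caries-like outcome cohorts, and a CAD-like positive-control outcome.

    ``theta_by_class`` optionally assigns each drug class its own true
    causal effect (log-odds per mmHg SBP increase) for the primary outcome;
    unlisted classes fall back to ``config.theta``. The control outcome uses
    ``theta_control`` for every class (SBP raises CAD risk, so the
    SBP-lowering orientation is protective by construction). Default cohort
    metadata mirrors a biobank cohort analysed on the linear scale
    (2,110 cases / 359,084 controls) and a registry cohort on the log-odds
    scale (4,170 cases / 195,395 controls); the control cohort mirrors a
    CAD meta-analysis (122,733 cases / 424,528 controls).
    """
    exposure, truth, ld = simulate_exposure(config)
    theta_by_class = dict(theta_by_class or {})
    theta_vec = np.array(
        [theta_by_class.get(c, config.theta) if c else 0.0 for c in truth.drug_class]
    )
    control_vec = np.where([bool(c) for c in truth.drug_class], theta_control, 0.0)

    if cohorts is None:
        cohorts = [
            CohortMeta(name="biobank", n_cases=2_110, n_controls=359_084, trait_scale="linear"),
            CohortMeta(name="registry", n_cases=4_170, n_controls=195_395, trait_scale="log_odds"),
        ]
    if control_cohort is None:
        control_cohort = CohortMeta(name="cad_control", n_cases=122_733, n_controls=424_528)

    outcomes = {
        meta.name: simulate_outcome(exposure, truth, config, meta, theta_per_snp=theta_vec)
        for meta in cohorts
    }
    control = simulate_outcome(exposure, truth, config, control_cohort, theta_per_snp=control_vec)
    resolved = {c: theta_by_class.get(c, config.theta) for c in set(truth.drug_class) if c}
    return StudyData(
        exposure=exposure,
        truth=truth,
        ld=ld,
        regions=config.resolved_regions(),
        outcomes=outcomes,
        control=control,
        theta_by_class=resolved,
        theta_control=theta_control,
    )
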