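"""Instrument selection for drug-target MR.

For each drug class the pipeline restricts exposure SNPs to ±100 kb windows
around the class's target genes, keeps genome-wide-significant hits
(p < 5e-8, strict), greedily prunes to mutual pairwise LD r² < 0.1, drops
weak instruments (F < 10), and substitutes high-LD proxies (r² > 0.8) for
instruments absent from the outcome study. Every SNP considered receives
exactly one terminal fate in the selection log, so selections are fully
auditable and invariant to input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .sumstats_io import LDTable

__all__ = [
    "InstrumentSet",
    "window_filter",
    "significance_filter",
    "f_statistic",
    "f_filter",
    "clump",
    "resolve_proxies",
    "select_instruments",
]


@dataclass
class InstrumentSet:
    """Selected instruments for one drug class plus the selection audit.

    ``records`` carries canonical summary-stat columns plus ``f_stat``,
    ``source_gene``, ``is_proxy``, ``proxied_snp``, ``proxy_r2``.
    ``selection_log`` has one row per input SNP: (snp, fate, detail).
    """

    drug_class: str
    records: pd.DataFrame
    selection_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "fate", "detail"])
    )

    @property
    def k(self) -> int:
        return len(self.records)


def _log(entries: list, snps, fate: str, detail: str = "") -> None:
    for s in snps:
        entries.append({"snp": str(s), "fate": fate, "detail": detail})


def window_filter(
    records: pd.DataFrame,
    regions: pd.DataFrame,
    window_bp: int = 100_000,
    log: Optional[list] = None,
) -> pd.DataFrame:
    """Keep SNPs within ±window_bp of any target-gene region (1-based
    inclusive bounds on both sides); tag each with its source gene.

    A SNP covered by several regions is kept once, assigned to the region
    whose midpoint is nearest. Positions and regions must share a genome
    build (caller's responsibility).
    """
    if len(regions) == 0:
        raise ValueError("empty region list")
    keep_rows = []
    dropped = []
    regions = regions.reset_index(drop=True)
    mid = (regions["start"].to_numpy() + regions["end"].to_numpy()) / 2.0
    for _, row in records.iterrows():
        on_chrom = regions["chrom"].astype(str).to_numpy() == str(row["chrom"])
        lo = regions["start"].to_numpy() - window_bp
        hi = regions["end"].to_numpy() + window_bp
        inside = on_chrom & (row["pos"] >= lo) & (row["pos"] <= hi)
        if inside.any():
            idx = np.flatnonzero(inside)
            best = idx[np.argmin(np.abs(mid[idx] - row["pos"]))]
            rec = row.copy()
            rec["source_gene"] = regions["gene"].iloc[best]
            keep_rows.append(rec)
        else:
            dropped.append(row["snp"])
    if log is not None:
        _log(log, dropped, "outside_window", f"±{window_bp} bp of target genes")
    if keep_rows:
        return pd.DataFrame(keep_rows).reset_index(drop=True)
    cols = list(records.columns) + ["source_gene"]
    return pd.DataFrame(columns=cols)


def significance_filter(
    records: pd.DataFrame,
    p_threshold: float = 5e-8,
    log: Optional[list] = None,
) -> pd.DataFrame:
    """Keep genome-wide significant SNPs: pval < p_threshold, strictly."""
    keep = records["pval"].to_numpy() < p_threshold
    if log is not None:
        _log(log, records.loc[~keep, "snp"], "not_significant", f"p >= {p_threshold:g}")
    return records.loc[keep].reset_index(drop=True)


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F as the squared Wald z, (beta/se)².

    Needs no variance-explained or sample-size assumptions; for a single
    SNP it is the F of the exposure regression.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


def f_statistic_r2(beta: float, se: float, n: int) -> float:
    """Variance-explained form F = (n-2)·R²/(1-R²) with R² from the z-score
    (R² = z²/(z² + n - 2)); opt-in alternative to :func:`f_statistic`."""
    z2 = (beta / se) ** 2
    r2 = z2 / (z2 + n - 2)
    return (n - 2) * r2 / (1 - r2)


def f_filter(
    records: pd.DataFrame,
    f_min: float = 10.0,
    log: Optional[list] = None,
    use_r2_form: bool = False,
) -> pd.DataFrame:
    """Attach ``f_stat`` and drop weak instruments (F < f_min)."""
    records = records.copy()
    if use_r2_form:
        records["f_stat"] = [
            f_statistic_r2(b, s, n)
            for b, s, n in zip(records["beta"], records["se"], records["n"])
        ]
    else:
        records["f_stat"] = [(b / s) ** 2 for b, s in zip(records["beta"], records["se"])]
    keep = records["f_stat"].to_numpy() >= f_min
    if log is not None:
        _log(log, records.loc[~keep, "snp"], "weak_instrument", f"F < {f_min:g}")
    return records.loc[keep].reset_index(drop=True)


def clump(
    records: pd.DataFrame,
    ld: LDTable,
    clump_r2: float = 0.1,
    log: Optional[list] = None,
) -> pd.DataFrame:
    """Greedy LD clumping to mutual pairwise independence.

    Sort by p-value ascending (ties broken by chromosome then position);
    repeatedly keep the best remaining SNP and remove every remaining SNP
    with r² >= clump_r2 against ANY kept SNP. The survivors therefore all
    satisfy pairwise r² < clump_r2 — stricter than index-variant-only
    clumping. A missing LD pair is treated as r² = 0 (logged by the table).
    """
    order = records.sort_values(
        by=["pval", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)
    kept_ids: list[str] = []
    kept_idx: list[int] = []
    removed: dict[str, str] = {}
    for i, row in order.iterrows():
        snp = str(row["snp"])
        hit = next((k for k in kept_ids if ld.r2(snp, k) >= clump_r2), None)
        if hit is None:
            kept_ids.append(snp)
            kept_idx.append(i)
        else:
            removed[snp] = hit
    if log is not None:
        for snp, against in removed.items():
            _log(log, [snp], "clumped_out", f"r2 >= {clump_r2:g} with kept SNP {against}")
    return order.iloc[kept_idx].reset_index(drop=True)


def resolve_proxies(
    records: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LDTable,
    proxy_r2_min: float = 0.8,
    log: Optional[list] = None,
) -> pd.DataFrame:
    """Substitute proxies for instruments absent from the outcome study.

    For each instrument missing from ``outcome``: take the highest-r²
    partner with r² > proxy_r2_min that IS present in the outcome table,
    rewrite the instrument's alleles through the LD table's correlated-allele
    map (the exposure association is carried over to the proxy), and record
    ``is_proxy``/``proxied_snp``/``proxy_r2``. A proxy whose allele map is
    missing is never used (phase is not guessed); with no usable proxy the
    instrument is dropped.
    """
    outcome_snps = set(outcome["snp"].astype(str))
    rows = []
    records = records.copy()
    for col, default in (("is_proxy", False), ("proxied_snp", None), ("proxy_r2", np.nan)):
        if col not in records.columns:
            records[col] = default
    for _, row in records.iterrows():
        snp = str(row["snp"])
        if snp in outcome_snps:
            rows.append(row)
            continue
        partners = sorted(
            ((b, r2) for b, r2 in ld.partners(snp).items() if r2 > proxy_r2_min and b in outcome_snps),
            key=lambda t: (-t[1], t[0]),
        )
        chosen = None
        rejected: list[str] = []
        for proxy_id, r2 in partners:
            amap = ld.allele_map(snp, proxy_id)
            if amap is None:
                rejected.append(f"{proxy_id}: allele map missing, phase not guessed")
                continue
            if row["effect_allele"] not in amap or row["other_allele"] not in amap:
                rejected.append(f"{proxy_id}: allele map does not cover instrument alleles")
                continue
            chosen = (proxy_id, r2, amap)
            break
        if chosen is None:
            if log is not None:
                detail = f"absent from outcome, no usable proxy with r2 > {proxy_r2_min:g}"
                if rejected:
                    detail += " (rejected: " + "; ".join(rejected) + ")"
                _log(log, [snp], "no_proxy", detail)
            continue
        proxy_id, r2, amap = chosen
        new = row.copy()
        new["snp"] = proxy_id
        new["effect_allele"] = amap[row["effect_allele"]]
        new["other_allele"] = amap[row["other_allele"]]
        new["is_proxy"] = True
        new["proxied_snp"] = snp
        new["proxy_r2"] = r2
        if log is not None:
            _log(log, [snp], "proxied", f"replaced by {proxy_id} (r2={r2:g})")
        rows.append(new)
    if rows:
        return pd.DataFrame(rows).reset_index(drop=True)
    return pd.DataFrame(columns=records.columns)


def select_instruments(
    exposure: pd.DataFrame,
    regions: pd.DataFrame,
    drug_class: str,
    ld: LDTable,
    outcome: Optional[pd.DataFrame] = None,
    window_bp: int = 100_000,
    p_threshold: float = 5e-8,
    clump_r2: float = 0.1,
    f_min: float = 10.0,
    proxy_r2_min: float = 0.8,
    use_r2_form_f: bool = False,
) -> InstrumentSet:
    """Full selection pipeline for one drug class.

    Order: gene-window restriction -> genome-wide significance -> greedy LD
    clumping -> F-statistic filter -> proxy resolution (when an outcome
    table is supplied). The selection log records one terminal fate per
    input SNP; output is invariant to input row order.
    """
    class_regions = regions.loc[regions["drug_class"] == drug_class]
    if len(class_regions) == 0:
        raise ValueError(f"no target regions for drug class {drug_class!r}")
    log: list = []
    df = exposure.sort_values(by=["chrom", "pos", "snp"], kind="mergesort").reset_index(drop=True)
    df = window_filter(df, class_regions, window_bp=window_bp, log=log)
    if len(df):
        df = significance_filter(df, p_threshold=p_threshold, log=log)
    if len(df):
        df = clump(df, ld, clump_r2=clump_r2, log=log)
    if len(df):
        df = f_filter(df, f_min=f_min, log=log, use_r2_form=use_r2_form_f)
    if outcome is not None and len(df):
        df = resolve_proxies(df, outcome, ld, proxy_r2_min=proxy_r2_min, log=log)
    else:
        for col, default in (("is_proxy", False), ("proxied_snp", None), ("proxy_r2", np.nan)):
            if col not in df.columns:
                df[col] = default
    selected = df.reset_index(drop=True)
    # survivors that are not proxies get the terminal fate "selected";
    # proxied instruments were already logged under the original SNP id
    direct = selected.loc[~selected["is_proxy"].astype(bool), "snp"].astype(str)
    _log(log, direct, "selected")
    log_df = pd.DataFrame(log, columns=["snp", "fate", "detail"])
    return InstrumentSet(drug_class=drug_class, records=selected.reset_index(drop=True), selection_log=log_df)
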