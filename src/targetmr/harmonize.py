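"""Allele harmonization of exposure and outcome summary statistics.

Two GWAS may report the same SNP with the effect/other alleles swapped, on
opposite strands, or both. Harmonization rewrites every outcome record onto
the exposure's effect-allele convention:

1. same allele pair, same orientation  -> ``aligned``
2. same pair, swapped                  -> negate beta_out, flip eaf_out
                                          (``flipped``)
3. complementary-strand pair
   (non-palindromic)                   -> complement, then rule 1/2
                                          (``strand_corrected``)
4. palindromic pair (A/T or C/G)       -> strand is unknowable from alleles;
   if min(eaf, 1-eaf) > the ambiguity threshold in *either* study the SNP is
   dropped (``dropped_palindromic``); otherwise alignment is inferred from
   allele frequencies (effect alleles agree iff both frequencies fall on the
   same side of 0.5)
5. irreconcilable allele pairs         -> ``dropped_incompatible``

The drop decision depends only on the allele pair and frequencies, never on
effect sizes. The default ambiguity threshold of 0.42 is the conventional
cut for declaring a palindromic SNP's frequency too close to 0.5 to resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "COMPLEMENT",
    "ACTIONS",
    "HarmonizedSet",
    "is_palindromic",
    "harmonize_pair",
    "harmonize_set",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTIONS = (
    "aligned",
    "flipped",
    "strand_corrected",
    "dropped_palindromic",
    "dropped_incompatible",
)

_DROPPED = ("dropped_palindromic", "dropped_incompatible")

HARMONIZED_COLUMNS = (
    "snp",
    "beta_exp",
    "se_exp",
    "eaf_exp",
    "beta_out",
    "se_out",
    "eaf_out",
    "action",
    "reason",
)


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G pairs (identical on both strands)."""
    return COMPLEMENT.get(a1) == a2


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned onto one effect allele per SNP.

    ``records`` keeps the full audit (every SNP considered, including drops,
    with its action); :attr:`data` is the surviving subset used by the
    estimators and :attr:`k` its size.
    """

    drug_class: str
    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=HARMONIZED_COLUMNS))

    @property
    def data(self) -> pd.DataFrame:
        return self.records.loc[~self.records["action"].isin(_DROPPED)].reset_index(drop=True)

    @property
    def k(self) -> int:
        return int((~self.records["action"].isin(_DROPPED)).sum())


def harmonize_pair(exp: pd.Series | dict, out: pd.Series | dict, maf_ambiguity: float = 0.42) -> dict:
    """Harmonize one SNP's outcome record onto the exposure's effect allele.

    ``exp`` and ``out`` are canonical summary-stat records for the same
    ``snp``. Returns a dict with the harmonized fields plus ``action`` and a
    human-readable ``reason`` for drops.
    """
    if exp["snp"] != out["snp"]:
        raise ValueError(f"snp mismatch: {exp['snp']} vs {out['snp']}")
    e1, e2 = exp["effect_allele"], exp["other_allele"]
    o1, o2 = out["effect_allele"], out["other_allele"]

    beta_out = float(out["beta"])
    eaf_out = float(out["eaf"]) if pd.notna(out["eaf"]) else np.nan
    eaf_exp = float(exp["eaf"]) if pd.notna(exp["eaf"]) else np.nan

    def _result(action: str, reason: str = "") -> dict:
        return {
            "snp": exp["snp"],
            "beta_exp": float(exp["beta"]),
            "se_exp": float(exp["se"]),
            "eaf_exp": eaf_exp,
            "beta_out": beta_out,
            "se_out": float(out["se"]),
            "eaf_out": eaf_out,
            "action": action,
            "reason": reason,
        }

    if is_palindromic(e1, e2):
        if {o1, o2} != {e1, e2}:
            return _result("dropped_incompatible", f"outcome alleles {o1}/{o2} do not match palindromic pair {e1}/{e2}")
        if np.isnan(eaf_exp) or np.isnan(eaf_out):
            return _result("dropped_palindromic", "missing frequency on a palindromic SNP")
        if min(eaf_exp, 1 - eaf_exp) > maf_ambiguity or min(eaf_out, 1 - eaf_out) > maf_ambiguity:
            return _result(
                "dropped_palindromic",
                f"ambiguous frequency (min MAF > {maf_ambiguity}) in at least one study",
            )
        # letter-align first; reported letters may or may not reflect strand
        action = "aligned"
        if o1 != e1:
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
            action = "flipped"
        # frequency check: opposite sides of 0.5 => the two studies report
        # opposite strands; negate again
        if (eaf_exp < 0.5) != (eaf_out < 0.5):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
            action = "strand_corrected"
        return _result(action)

    if {o1, o2} == {e1, e2}:
        if o1 == e1:
            return _result("aligned")
        beta_out = -beta_out
        if not np.isnan(eaf_out):
            eaf_out = 1.0 - eaf_out
        return _result("flipped")

    c1, c2 = COMPLEMENT.get(o1), COMPLEMENT.get(o2)
    if {c1, c2} == {e1, e2}:
        if c1 == e1:
            return _result("strand_corrected", "complementary-strand report")
        beta_out = -beta_out
        if not np.isnan(eaf_out):
            eaf_out = 1.0 - eaf_out
        return _result("strand_corrected", "complementary-strand report, swapped")

    return _result("dropped_incompatible", f"alleles {e1}/{e2} vs {o1}/{o2} irreconcilable")


def harmonize_set(
    instruments,
    outcome: pd.DataFrame,
    maf_ambiguity: float = 0.42,
    drug_class: Optional[str] = None,
) -> HarmonizedSet:
    """Harmonize an instrument set against an outcome table.

    ``instruments`` is an :class:`~targetmr.instruments.InstrumentSet` or a
    canonical summary-stat frame (proxies must already be resolved, so every
    instrument is expected in the outcome table; missing ones are dropped as
    incompatible with an explicit reason). An empty result is allowed.
    """
    if hasattr(instruments, "records"):
        exp_df = instruments.records
        drug_class = drug_class or instruments.drug_class
    else:
        exp_df = instruments
        drug_class = drug_class or ""

    out_by_snp = {str(r["snp"]): r for _, r in outcome.iterrows()}
    rows = []
    for _, exp_row in exp_df.iterrows():
        snp = str(exp_row["snp"])
        out_row = out_by_snp.get(snp)
        if out_row is None:
            rows.append(
                {
                    "snp": snp,
                    "beta_exp": float(exp_row["beta"]),
                    "se_exp": float(exp_row["se"]),
                    "eaf_exp": float(exp_row["eaf"]) if pd.notna(exp_row["eaf"]) else np.nan,
                    "beta_out": np.nan,
                    "se_out": np.nan,
                    "eaf_out": np.nan,
                    "action": "dropped_incompatible",
                    "reason": "absent from outcome table (proxy resolution upstream failed to cover it)",
                }
            )
            continue
        rows.append(harmonize_pair(exp_row, out_row, maf_ambiguity=maf_ambiguity))
    records = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    return HarmonizedSet(drug_class=drug_class, records=records)
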