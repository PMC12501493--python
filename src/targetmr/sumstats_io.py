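"""Reading, validating, transforming, and writing GWAS summary statistics.

File dialects (all TSV, gzip transparently supported):

* summary statistics — canonical header ``snp, chrom, pos, effect_allele,
  other_allele, eaf, beta, se, pval, n``; extra columns (e.g. ``gene`` for
  eQTL tables) pass through untouched; alternate headers are resolved via a
  ``column_map``.
* gene target regions — ``drug_class, gene, chrom, start, end`` (1-based,
  inclusive coordinates).
* LD — ``snp_a, snp_b, r2, allele_map`` where ``allele_map`` pairs each
  allele of ``snp_a`` with its correlated allele of ``snp_b`` ("A=G,T=C").

Validation is strict on structural invariants (alleles, se > 0, p in (0,1])
and row-level: bad rows are rejected with row-indexed diagnostics, never
silently dropped. The p-vs-z consistency check is a warning only, because
rounding in published meta-analysis tables routinely breaks exact agreement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import CohortMeta, MREstimate, PressoResult

__all__ = [
    "CANONICAL_COLUMNS",
    "VALID_ALLELES",
    "RowError",
    "ValidationReport",
    "SumstatsFormatError",
    "DegenerateCohortError",
    "read_sumstats",
    "validate_sumstats",
    "write_sumstats",
    "read_regions",
    "write_regions",
    "LDTable",
    "read_ld",
    "write_ld",
    "linear_to_logor",
    "write_results",
    "read_estimates",
]

CANONICAL_COLUMNS = (
    "snp",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

VALID_ALLELES = frozenset("ACGT")

_NUMERIC = ("pos", "eaf", "beta", "se", "pval", "n")


class SumstatsFormatError(ValueError):
    """A table is structurally unusable (missing mandatory columns, ...)."""


class DegenerateCohortError(ValueError):
    """Cohort with case fraction 0 or 1: scale conversion undefined."""


@dataclass(frozen=True)
class RowError:
    row: int  # 0-based row index in the input table
    field: str
    message: str


@dataclass
class ValidationReport:
    n_input: int = 0
    n_accepted: int = 0
    row_errors: list[RowError] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return self.n_input - self.n_accepted


def _apply_column_map(df: pd.DataFrame, column_map: Optional[Mapping[str, str]]) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={src: dst for src, dst in column_map.items()})
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns and c != "eaf"]
    if missing:
        raise SumstatsFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    if "eaf" not in df.columns:
        df = df.assign(eaf=np.nan)
    return df


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, ValidationReport]:
    """Apply row-level invariants; return (accepted rows, report).

    Hard invariants reject a row: single-nucleotide A/C/G/T alleles (indels
    are rejected with a named reason), effect != other allele, se > 0,
    p in (0,1], n > 0, pos >= 1, eaf in [0,1] when present. Missing eaf is
    tolerated. count(input) = count(accepted) + count(rejected) always.
    """
    report = ValidationReport(n_input=len(df))
    df = df.copy()
    df["snp"] = df["snp"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    bad = np.zeros(len(df), dtype=bool)

    def _flag(mask: np.ndarray, fld: str, msg: str) -> None:
        for i in np.nonzero(np.asarray(mask) & ~bad)[0]:
            report.row_errors.append(RowError(row=int(i), field=fld, message=msg))
        bad[np.asarray(mask)] = True

    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        unparsable = coerced.isna() & df[col].notna() & (df[col].astype(str) != "nan")
        if col != "eaf":
            unparsable |= df[col].isna()
        if col == "eaf":
            unparsable = coerced.isna() & df[col].notna() & ~df[col].astype(str).isin(["nan", "NA", ""])
        if unparsable.any():
            _flag(unparsable.to_numpy(), col, "unparsable numeric value")
        df[col] = coerced

    for col in ("effect_allele", "other_allele"):
        invalid = ~df[col].isin(list(VALID_ALLELES))
        if invalid.any():
            _flag(invalid.to_numpy(), col, "allele is not a single nucleotide A/C/G/T (indels rejected)")
    _flag((df["effect_allele"] == df["other_allele"]).to_numpy(), "other_allele", "effect allele equals other allele")
    _flag((~(df["se"] > 0)).to_numpy(), "se", "se must be > 0")
    _flag((~((df["pval"] > 0) & (df["pval"] <= 1))).to_numpy(), "pval", "pval must be in (0, 1]")
    _flag((~(df["n"] > 0)).to_numpy(), "n", "n must be > 0")
    _flag((~(df["pos"] >= 1)).to_numpy(), "pos", "pos must be a 1-based coordinate")
    eaf_bad = df["eaf"].notna() & ~((df["eaf"] >= 0) & (df["eaf"] <= 1))
    _flag(eaf_bad.to_numpy(), "eaf", "eaf must lie in [0, 1]")

    accepted = df.loc[~bad].copy()
    accepted["pos"] = accepted["pos"].astype(np.int64)
    accepted["n"] = accepted["n"].astype(np.int64)
    report.n_accepted = len(accepted)

    # soft check: two-sided normal p implied by |beta/se| within 10% relative
    if len(accepted):
        z = np.abs(accepted["beta"].to_numpy() / accepted["se"].to_numpy())
        p_implied = 2.0 * stats.norm.sf(z)
        p_obs = accepted["pval"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(p_obs - p_implied) / np.where(p_implied > 0, p_implied, np.nan)
        inconsistent = np.nonzero((rel > 0.10) & np.isfinite(rel))[0]
        for i in inconsistent:
            report.warnings.append(
                f"row {accepted.index[i]} (snp {accepted['snp'].iloc[i]}): pval "
                f"{p_obs[i]:.3g} inconsistent with |beta/se| (implies {p_implied[i]:.3g})"
            )
    return accepted.reset_index(drop=True), report


def read_sumstats(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a summary-statistics TSV into the canonical frame.

    ``column_map`` maps *input* header names to canonical names, e.g.
    ``{"BETA": "beta", "rsid": "snp"}``. Returns the validated frame and a
    :class:`ValidationReport` with row-indexed diagnostics for rejected rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str}, compression="infer")
    raw = _apply_column_map(raw, column_map)
    return validate_sumstats(raw)


def write_sumstats(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a canonical summary-statistics frame as TSV."""
    path = Path(path)
    cols = [c for c in CANONICAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# gene target regions


def read_regions(path: str | Path) -> pd.DataFrame:
    """Read a drug-class -> target-gene region table (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["drug_class", "gene", "chrom", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"region table missing column(s): {', '.join(missing)}")
    if (df["start"] > df["end"]).any():
        bad = df.index[df["start"] > df["end"]].tolist()
        raise SumstatsFormatError(f"region rows with start > end: {bad}")
    if (df["drug_class"].astype(str).str.len() == 0).any():
        raise SumstatsFormatError("empty drug_class in region table")
    return df[required].copy()


def write_regions(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# LD table


def _parse_allele_map(text: str) -> dict[str, str]:
    # "A=G,T=C" -> {"A": "G", "T": "C"}
    out: dict[str, str] = {}
    for pair in str(text).split(","):
        a, _, b = pair.strip().partition("=")
        if not a or not b:
            raise SumstatsFormatError(f"malformed allele_map entry {text!r}")
        out[a.upper()] = b.upper()
    return out


def _format_allele_map(amap: Mapping[str, str]) -> str:
    return ",".join(f"{a}={b}" for a, b in sorted(amap.items()))


class LDTable:
    """Pairwise r² lookup with correlated-allele maps.

    Stands in for an LD reference panel: symmetric on (a, b) swap, r² of a
    SNP with itself is 1, and a missing pair is treated as r² = 0 (the query
    is logged in :attr:`missing_pairs` because real panels are sparse).
    """

    def __init__(self) -> None:
        self._r2: dict[tuple[str, str], float] = {}
        self._amap: dict[tuple[str, str], Optional[dict[str, str]]] = {}
        self._partners: dict[str, set[str]] = {}
        self.missing_pairs: list[tuple[str, str]] = []

    def add(self, snp_a: str, snp_b: str, r2: float, allele_map: Optional[Mapping[str, str]] = None) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 out of [0,1] for pair ({snp_a}, {snp_b}): {r2}")
        fwd = dict(allele_map) if allele_map else None
        rev = {v: k for k, v in fwd.items()} if fwd else None
        self._r2[(snp_a, snp_b)] = r2
        self._r2[(snp_b, snp_a)] = r2
        self._amap[(snp_a, snp_b)] = fwd
        self._amap[(snp_b, snp_a)] = rev
        self._partners.setdefault(snp_a, set()).add(snp_b)
        self._partners.setdefault(snp_b, set()).add(snp_a)

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        try:
            return self._r2[(snp_a, snp_b)]
        except KeyError:
            self.missing_pairs.append((snp_a, snp_b))
            return 0.0

    def has_pair(self, snp_a: str, snp_b: str) -> bool:
        return snp_a == snp_b or (snp_a, snp_b) in self._r2

    def allele_map(self, snp_a: str, snp_b: str) -> Optional[dict[str, str]]:
        if snp_a == snp_b:
            return None
        return self._amap.get((snp_a, snp_b))

    def partners(self, snp: str) -> dict[str, float]:
        """All SNPs with a recorded pair against ``snp``, mapped to r²."""
        return {b: self._r2[(snp, b)] for b in self._partners.get(snp, ())}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        seen = set()
        for (a, b), r2 in self._r2.items():
            if (b, a) in seen:
                continue
            seen.add((a, b))
            amap = self._amap[(a, b)]
            rows.append({"snp_a": a, "snp_b": b, "r2": r2, "allele_map": _format_allele_map(amap) if amap else ""})
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2", "allele_map"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LDTable":
        table = cls()
        for row in df.itertuples(index=False):
            amap_text = getattr(row, "allele_map", "")
            amap = _parse_allele_map(amap_text) if isinstance(amap_text, str) and amap_text else None
            table.add(str(row.snp_a), str(row.snp_b), float(row.r2), amap)
        return table


def read_ld(path: str | Path) -> LDTable:
    df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    required = ["snp_a", "snp_b", "r2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"LD table missing column(s): {', '.join(missing)}")
    return LDTable.from_frame(df)


def write_ld(table: LDTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# scale transforms


def linear_to_logor(df: pd.DataFrame, meta: CohortMeta) -> pd.DataFrame:
    """Convert linear-scale (BOLT-LMM-style) betas/SEs to log odds ratios.

    For a binary trait analysed on the linear scale, the standard conversion
    divides beta and se by mu*(1-mu) with mu the case fraction. P-values are
    unchanged (the z-score is scale-invariant).
    """
    if meta.trait_scale != "linear":
        raise ValueError(f"cohort {meta.name!r} is not on the linear scale")
    mu = meta.case_fraction
    if mu <= 0.0 or mu >= 1.0:
        raise DegenerateCohortError(
            f"cohort {meta.name!r}: case fraction {mu} leaves the log-odds scale undefined"
        )
    factor = 1.0 / (mu * (1.0 - mu))
    out = df.copy()
    out["beta"] = out["beta"] * factor
    out["se"] = out["se"] * factor
    return out


# ---------------------------------------------------------------------------
# results


def write_results(
    estimates: Sequence[MREstimate] | Sequence[tuple[str, MREstimate]],
    path_prefix: str | Path,
    presso: Optional[Iterable[PressoResult]] = None,
    provenance: Optional[dict] = None,
) -> tuple[Path, Path]:
    """Write MR estimates as a report table plus a structured JSON file.

    The TSV mirrors a primary-results table (label, method, k, beta, SE, p,
    OR, CI bounds, OR columns formatted to 4 decimals); the JSON keeps full
    float precision plus provenance (seeds, thresholds, SNP lists) so that
    :func:`read_estimates` round-trips estimates bit-identically. An empty
    estimate list yields a header-only table and a warning in the JSON.
    """
    path_prefix = Path(path_prefix)
    labelled: list[tuple[str, MREstimate]] = []
    for item in estimates:
        if isinstance(item, MREstimate):
            labelled.append(("", item))
        else:
            labelled.append((item[0], item[1]))

    rows = []
    for label, est in labelled:
        lo, hi = est.ci_reduction
        rows.append(
            {
                "label": label,
                "method": est.method,
                "k": est.k,
                "beta": -est.theta,  # per-reduction scale, as reported
                "se": est.se,
                "pval": est.pval,
                "or": f"{est.or_reduction:.4f}",
                "ci_low": f"{lo:.4f}",
                "ci_high": f"{hi:.4f}",
            }
        )
    table = pd.DataFrame(
        rows, columns=["label", "method", "k", "beta", "se", "pval", "or", "ci_low", "ci_high"]
    )
    tsv_path = path_prefix.with_suffix(".tsv")
    json_path = path_prefix.with_suffix(".json")
    table.to_csv(tsv_path, sep="\t", index=False)

    payload: dict = {
        "estimates": [{"label": lbl, **est.to_dict()} for lbl, est in labelled],
        "presso": [p.to_dict() for p in presso] if presso else [],
        "provenance": provenance or {},
    }
    if not labelled:
        payload["warnings"] = ["no estimates supplied; header-only table written"]
    json_path.write_text(json.dumps(payload, indent=2))
    return tsv_path, json_path


def read_estimates(json_path: str | Path) -> list[tuple[str, MREstimate]]:
    """Read back the structured results file written by :func:`write_results`."""
    payload = json.loads(Path(json_path).read_text())
    out = []
    for entry in payload["estimates"]:
        entry = dict(entry)
        label = entry.pop("label")
        out.append((label, MREstimate.from_dict(entry)))
    return out
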