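"""Instrument selection: windows, significance, clumping, F, proxies."""

import numpy as np
import pandas as pd
import pytest

from targetmr.instruments import (
    clump,
    f_filter,
    f_statistic,
    resolve_proxies,
    select_instruments,
    significance_filter,
    window_filter,
)
from targetmr.sumstats_io import LDTable


def snp_frame(rows):
    defaults = {
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.05,
        "se": 0.005,
        "pval": 1e-10,
        "n": 100000,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


REGION = pd.DataFrame(
    [{"drug_class": "c", "gene": "G1", "chrom": "1", "start": 1000, "end": 2000}]
)


class TestWindowFilter:
    def test_boundaries_inclusive(self):
        df = snp_frame([{"snp": "in", "pos": 900}, {"snp": "out", "pos": 899}])
        kept = window_filter(df, REGION, window_bp=100)
        assert list(kept["snp"]) == ["in"]

    def test_other_chromosome_dropped(self):
        df = snp_frame([{"snp": "rsX", "pos": 1500, "chrom": "2"}])
        assert len(window_filter(df, REGION, window_bp=100)) == 0

    def test_overlapping_regions_nearest_midpoint(self):
        regions = pd.DataFrame(
            [
                {"drug_class": "c", "gene": "NEAR", "chrom": "1", "start": 1000, "end": 2000},
                {"drug_class": "c", "gene": "FAR", "chrom": "1", "start": 1400, "end": 5000},
            ]
        )
        df = snp_frame([{"snp": "rs1", "pos": 1500}])
        kept = window_filter(df, regions, window_bp=100)
        assert len(kept) == 1  # kept once despite two covering regions
        assert kept["source_gene"].iloc[0] == "NEAR"  # midpoints 1500 vs 3200

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValueError, match="empty region"):
            window_filter(snp_frame([{"snp": "rs1"}]), REGION.iloc[:0])


class TestSignificanceFilter:
    def test_threshold_is_strict(self):
        df = snp_frame([{"snp": "at", "pval": 5e-8}, {"snp": "below", "pval": 4.9e-8}])
        assert list(significance_filter(df)["snp"]) == ["below"]

    def test_counts_and_audit(self):
        rng = np.random.default_rng(0)
        pvals = [1e-9, 1e-8, 4e-8] + list(rng.uniform(1e-7, 1, size=7))
        df = snp_frame([{"snp": f"rs{i}", "pval": p} for i, p in enumerate(pvals)])
        log = []
        kept = significance_filter(df, log=log)
        assert len(kept) == 3 and len(log) == 7
        assert all(e["fate"] == "not_significant" for e in log)


class TestFStatistic:
    def test_arithmetic(self):
        assert f_statistic(0.05, 0.01) == pytest.approx(25.0)
        assert f_statistic(0.0, 0.01) == 0.0

    def test_filter_drops_weak_and_zero(self):
        df = snp_frame(
            [
                {"snp": "strong", "beta": 0.05, "se": 0.01},  # F=25
                {"snp": "weak", "beta": 0.01, "se": 0.005},  # F=4
                {"snp": "null", "beta": 0.0, "se": 0.01},  # F=0
            ]
        )
        kept = f_filter(df)
        assert list(kept["snp"]) == ["strong"]
        assert kept["f_stat"].iloc[0] == pytest.approx(25.0)

    def test_se_zero_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)


def brute_force_greedy(df, ld, clump_r2):
    """Independent re-implementation of the greedy clumping rule."""
    remaining = df.sort_values(["pval", "chrom", "pos"], kind="mergesort")["snp"].tolist()
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [s for s in remaining if ld.r2(s, best) < clump_r2]
    return kept


class TestClump:
    def test_forced_three_snp_example(self):
        df = snp_frame(
            [
                {"snp": "s1", "pval": 1e-10, "pos": 100},
                {"snp": "s2", "pval": 1e-9, "pos": 200},
                {"snp": "s3", "pval": 1e-8, "pos": 300},
            ]
        )
        ld = LDTable()
        ld.add("s1", "s2", 0.5)
        ld.add("s1", "s3", 0.05)
        ld.add("s2", "s3", 0.01)
        assert set(clump(df, ld)["snp"]) == {"s1", "s3"}

    def test_all_independent_all_kept(self):
        df = snp_frame([{"snp": f"rs{i}", "pos": i * 100, "pval": 1e-9} for i in range(5)])
        assert len(clump(df, LDTable())) == 5

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        n = 50
        df = snp_frame(
            [{"snp": f"rs{i}", "pos": 1000 + i, "pval": float(rng.uniform(1e-12, 1e-8))} for i in range(n)]
        )
        ld = LDTable()
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.15:
                    ld.add(f"rs{i}", f"rs{j}", float(rng.uniform(0, 1)))
        assert clump(df, ld)["snp"].tolist() == brute_force_greedy(df, ld, 0.1)

    def test_mutual_independence_of_output(self):
        rng = np.random.default_rng(12)
        n = 30
        df = snp_frame(
            [{"snp": f"rs{i}", "pos": 1000 + i, "pval": float(rng.uniform(1e-12, 1e-8))} for i in range(n)]
        )
        ld = LDTable()
        for i in range(n):
            for j in range(i + 1, n):
                ld.add(f"rs{i}", f"rs{j}", float(rng.beta(0.5, 3)))
        kept = clump(df, ld)["snp"].tolist()
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert ld.r2(a, b) < 0.1


class TestResolveProxies:
    OUTCOME = snp_frame([{"snp": "rsO"}, {"snp": "rsP"}])

    def test_present_instrument_untouched(self):
        instr = snp_frame([{"snp": "rsO"}])
        out = resolve_proxies(instr, self.OUTCOME, LDTable())
        assert not out["is_proxy"].iloc[0] and out["snp"].iloc[0] == "rsO"

    def test_absent_instrument_substituted_with_allele_translation(self):
        instr = snp_frame([{"snp": "rsA", "effect_allele": "A", "other_allele": "G"}])
        ld = LDTable()
        ld.add("rsA", "rsP", 0.95, {"A": "T", "G": "C"})
        out = resolve_proxies(instr, self.OUTCOME, ld)
        row = out.iloc[0]
        assert row["snp"] == "rsP" and row["is_proxy"]
        assert row["proxied_snp"] == "rsA" and row["proxy_r2"] == 0.95
        assert row["effect_allele"] == "T" and row["other_allele"] == "C"
        assert row["beta"] == 0.05  # exposure association carried over

    def test_low_ld_proxy_not_used(self):
        instr = snp_frame([{"snp": "rsA"}])
        ld = LDTable()
        ld.add("rsA", "rsP", 0.7, {"A": "A", "G": "G"})
        log = []
        out = resolve_proxies(instr, self.OUTCOME, ld, log=log)
        assert len(out) == 0 and log[0]["fate"] == "no_proxy"

    def test_highest_r2_proxy_preferred(self):
        instr = snp_frame([{"snp": "rsA"}])
        ld = LDTable()
        ld.add("rsA", "rsP", 0.85, {"A": "A", "G": "G"})
        ld.add("rsA", "rsO", 0.99, {"A": "A", "G": "G"})
        assert resolve_proxies(instr, self.OUTCOME, ld)["snp"].iloc[0] == "rsO"

    def test_missing_allele_map_never_guessed(self):
        instr = snp_frame([{"snp": "rsA"}])
        ld = LDTable()
        ld.add("rsA", "rsP", 0.95)  # no allele map
        log = []
        out = resolve_proxies(instr, self.OUTCOME, ld, log=log)
        assert len(out) == 0
        assert "phase not guessed" in log[0]["detail"]


class TestSelectInstruments:
    @staticmethod
    def _inputs():
        rng = np.random.default_rng(21)
        rows = []
        for i in range(40):
            rows.append(
                {
                    "snp": f"rs{i}",
                    "pos": int(rng.integers(500, 2500)),
                    "pval": float(10 ** rng.uniform(-12, -2)),
                    "beta": float(rng.normal(0.05, 0.02)),
                    "se": 0.006,
                }
            )
        df = snp_frame(rows)
        ld = LDTable()
        for i in range(0, 40, 4):
            for j in range(i + 1, min(i + 4, 40)):
                ld.add(f"rs{i}", f"rs{j}", 0.4)
        return df, ld

    def test_row_order_invariance(self):
        df, ld = self._inputs()
        a = select_instruments(df, REGION, "c", ld)
        b = select_instruments(df.sample(frac=1, random_state=7), REGION, "c", ld)
        assert a.records["snp"].tolist() == b.records["snp"].tolist()

    def test_selection_log_covers_every_snp_once(self):
        df, ld = self._inputs()
        result = select_instruments(df, REGION, "c", ld)
        log = result.selection_log
        assert sorted(log["snp"]) == sorted(df["snp"])
        assert log["snp"].is_unique

    def test_survivors_satisfy_all_thresholds(self):
        df, ld = self._inputs()
        result = select_instruments(df, REGION, "c", ld)
        rec = result.records
        assert (rec["pval"] < 5e-8).all()
        assert (rec["f_stat"] >= 10).all()
        snps = rec["snp"].tolist()
        for i, a in enumerate(snps):
            for b in snps[i + 1 :]:
                assert ld.r2(a, b) < 0.1

    def test_unknown_class_rejected(self):
        df, ld = self._inputs()
        with pytest.raises(ValueError, match="no target regions"):
            select_instruments(df, REGION, "nonexistent", ld)
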