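import numpy as np
import pandas as pd
import pytest

from targetmr.harmonize import HarmonizedSet
from targetmr.synthetic import SimulationConfig


def make_harmonized(beta_exp, se_exp, beta_out, se_out, drug_class="test") -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays (all aligned)."""
    k = len(beta_exp)
    records = pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(k)],
            "beta_exp": np.asarray(beta_exp, dtype=float),
            "se_exp": np.asarray(se_exp, dtype=float),
            "eaf_exp": 0.3,
            "beta_out": np.asarray(beta_out, dtype=float),
            "se_out": np.asarray(se_out, dtype=float),
            "eaf_out": 0.3,
            "action": "aligned",
            "reason": "",
        }
    )
    return HarmonizedSet(drug_class=drug_class, records=records)


def calibration_config(seed: int, **overrides) -> SimulationConfig:
    """One-region, clean-reporting config for estimator calibration runs:
    strong instruments, no LD, no palindromic/swap/strand perturbation."""
    regions = pd.DataFrame(
        [{"drug_class": "test", "gene": "GENE1", "chrom": "1", "start": 1_000_000, "end": 1_060_000}]
    )
    defaults = dict(
        n_snps_per_region=50,
        n_null_snps_per_region=0,
        regions=regions,
        gamma_mean=0.02,
        gamma_sd=0.004,
        palindromic_fraction=0.0,
        swap_fraction=0.0,
        strand_flip_fraction=0.0,
        ld_block_size=1,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def sumstats_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": ["rs1", "rs2", "rs3"],
            "chrom": ["1", "1", "2"],
            "pos": [1000, 2000, 3000],
            "effect_allele": ["A", "C", "G"],
            "other_allele": ["G", "T", "A"],
            "eaf": [0.2, 0.35, 0.4],
            "beta": [0.05, -0.02, 0.01],
            "se": [0.01, 0.008, 0.012],
            "pval": [5.7e-7, 0.0124, 0.4047],
            "n": [100000, 100000, 100000],
        }
    )
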