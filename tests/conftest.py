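import numpy as np
import pandas as pd
import pytest

from mrphewas import HarmonisedSet, SimConfig, SummaryStatTable
from mrphewas.sumstats import CANONICAL_COLUMNS


def make_table(rows, trait_id="trait", trait_type="continuous"):
    """Build a SummaryStatTable from dict rows, filling canonical columns."""
    df = pd.DataFrame(rows)
    for col, default in (("effect_allele", "A"), ("other_allele", "G"),
                         ("eaf", 0.3), ("n", 10000.0)):
        if col not in df.columns:
            df[col] = default
    if "variant_id" not in df.columns:
        df["variant_id"] = [f"rs{i + 1}" for i in range(len(df))]
    if "pvalue" not in df.columns:
        from scipy import stats
        df["pvalue"] = 2 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
    return SummaryStatTable(trait_id=trait_id, trait_type=trait_type,
                            df=df[CANONICAL_COLUMNS])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def strong_hset(rng):
    """30 strong instruments with a true causal log-OR of 0.2, no pleiotropy."""
    n = 30
    eaf = rng.uniform(0.1, 0.5, n)
    bx_true = rng.normal(0, 0.05, n)
    se_x = 1 / np.sqrt(2 * eaf * (1 - eaf) * 3e5)
    se_y = 1 / np.sqrt(2 * eaf * (1 - eaf) * 4e4)
    bx = bx_true + se_x * rng.standard_normal(n)
    by = 0.2 * bx_true + se_y * rng.standard_normal(n)
    return HarmonisedSet.from_arrays(bx, se_x, by, se_y, eaf_exp=eaf, eaf_out=eaf,
                                     n_exp=3e5, n_cases=5e4, n_controls=11e4,
                                     lifetime_risk=0.04)


@pytest.fixture
def null_config():
    return SimConfig(seed=7, beta_causal=0.0)
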