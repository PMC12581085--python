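import numpy as np
import pandas as pd
import pytest

from mrmediate import HarmonisedSet, SummaryStats


def make_sumstats(name="trait", **cols):
    """Build a SummaryStats from keyword columns with sensible defaults."""
    n = len(cols["beta"])
    base = {
        "variant_id": [f"rs{i + 1}" for i in range(n)],
        "chrom": ["1"] * n,
        "pos": [(i + 1) * 20_000_000 for i in range(n)],
        "effect_allele": ["A"] * n,
        "other_allele": ["C"] * n,
        "eaf": [0.3] * n,
        "se": [0.01] * n,
        "pvalue": [1e-10] * n,
        "n": [100_000] * n,
    }
    base.update(cols)
    return SummaryStats(name, pd.DataFrame(base))


def make_harmonised(beta_exp, se_exp, beta_out, se_out, ids=None):
    beta_exp = np.asarray(beta_exp, float)
    n = len(beta_exp)
    table = pd.DataFrame({
        "variant_id": ids if ids is not None else [f"rs{i + 1}" for i in range(n)],
        "beta_exp": beta_exp,
        "se_exp": np.asarray(se_exp, float),
        "beta_out": np.asarray(beta_out, float),
        "se_out": np.asarray(se_out, float),
        "eaf": 0.3,
        "flag": "unchanged",
    })
    return HarmonisedSet("exposure", "outcome", table)


@pytest.fixture
def noisy_harmonised():
    """A 12-SNP set with real heterogeneity around a slope of 0.4."""
    rng = np.random.default_rng(7)
    bx = rng.uniform(0.02, 0.08, 12)
    sx = np.full(12, 0.004)
    sy = rng.uniform(0.008, 0.02, 12)
    by = 0.4 * bx + rng.normal(0, 2.0 * sy)
    return make_harmonised(bx, sx, by, sy)


@pytest.fixture
def homogeneous_harmonised():
    """Every SNP carries exactly the same Wald ratio (0.5)."""
    bx = np.array([0.02, 0.04, 0.05, 0.08])
    return make_harmonised(bx, 0.004 * np.ones(4), 0.5 * bx,
                           [0.01, 0.012, 0.009, 0.011])
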