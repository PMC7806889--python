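"""Crossed-intercepts LMM: oracle agreement, recovery, edge cases.

The profiled-ML implementation is checked against statsmodels MixedLM
(ML, variance components for the two crossed factors) as an independent
oracle, and against OLS in the zero-variance limit.
"""

import numpy as np
import pandas as pd
import pytest

import labiofreq as lf
from labiofreq.lmm import CrossedInterceptLMM


def _gaussian_lmm_data(seed, n=1000, L=50, R=10, beta=-0.2,
                       s_lin=0.5, s_reg=0.3, s_e=0.8):
    """Data drawn from the LMM's own generative process."""
    rng = np.random.default_rng(seed)
    lin = rng.integers(0, L, n)
    reg = rng.integers(0, R, n)
    hg = (rng.random(L) < 0.3)[lin].astype(float)
    y = (1.0 + beta * hg + rng.normal(0, s_lin, L)[lin]
         + rng.normal(0, s_reg, R)[reg] + rng.normal(0, s_e, n))
    return pd.DataFrame({"y": y, "hg": hg,
                         "lineage": [f"L{i}" for i in lin],
                         "region": [f"R{i}" for i in reg]})


def test_matches_statsmodels_mixedlm(small_table):
    import statsmodels.formula.api as smf

    mine = CrossedInterceptLMM.from_table(small_table, "lr_t").fit()
    df = small_table.frame
    oracle = smf.mixedlm(
        "lr_t ~ hg", df, groups=np.ones(len(df)), re_formula="0",
        vc_formula={"lineage": "0 + C(lineage)", "region": "0 + C(region)"},
    ).fit(reml=False)
    assert mine.params[0] == pytest.approx(oracle.params["Intercept"], abs=2e-4)
    assert mine.params[1] == pytest.approx(oracle.params["hg"], abs=2e-4)
    # our optimum should be at least as good as the oracle's
    assert mine.loglike >= oracle.llf - 1e-4
    assert mine.sigma_resid ** 2 == pytest.approx(oracle.scale, rel=5e-3)


def test_parameter_recovery_within_two_se():
    df = _gaussian_lmm_data(seed=14)
    df["lr_t"] = df["y"]
    res = lf.fit_lmm(df, "lr_t")
    assert abs(res.fixed_effect - (-0.2)) < 2 * res.fixed_effect_se
    assert 0.2 < res.random_sd_lineage < 0.9
    assert res.residual_sd == pytest.approx(0.8, abs=0.12)


def test_zero_variance_degrades_to_ols():
    rng = np.random.default_rng(2)
    n = 400
    hg = rng.integers(0, 2, n).astype(float)
    y = 0.5 - 0.3 * hg + rng.normal(0, 1, n)
    df = pd.DataFrame({"lr_t": y, "hg": hg,
                       "lineage": [f"L{i % 20}" for i in range(n)],
                       "region": [f"R{i % 5}" for i in range(n)]})
    model = CrossedInterceptLMM.from_table(df, "lr_t")
    X = np.column_stack([np.ones(n), hg])
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    # at the variance-ratio floor the profiled fit IS ordinary least squares
    _, beta_floor, sigma2, _, g = model._profile([-14.0, -14.0])
    assert np.allclose(beta_floor, beta_ols, atol=1e-8)
    assert g[0] == 0.0 and g[1] == 0.0
    # and the full optimizer lands close to it on group-structure-free data
    res = model.fit()
    assert np.allclose(res.params, beta_ols, atol=0.02)
    assert res.sigma_groups[0] < 0.15 and res.sigma_groups[1] < 0.15


def test_lrt_invariant_to_group_relabeling():
    df = _gaussian_lmm_data(seed=5, n=400, L=20, R=6)
    df["lr_t"] = df["y"]
    base = lf.fit_lmm(df, "lr_t")
    shuffled = df.copy()
    mapping = {f"L{i}": f"fam_{(i * 7) % 20:02d}" for i in range(20)}
    shuffled["lineage"] = shuffled["lineage"].map(mapping)
    relabeled = lf.fit_lmm(shuffled, "lr_t")
    assert relabeled.lrt_chi2 == pytest.approx(base.lrt_chi2, abs=1e-6)
    assert relabeled.fixed_effect == pytest.approx(base.fixed_effect, abs=1e-8)


def test_lrt_chi2_clipped_at_zero():
    df = _gaussian_lmm_data(seed=9, n=300, L=15, R=5, beta=0.0)
    df["lr_t"] = df["y"]
    res = lf.fit_lmm(df, "lr_t")
    assert res.lrt_chi2 >= 0.0
    assert 0.0 <= res.p_value <= 1.0


def test_requires_two_levels():
    df = pd.DataFrame({"lr_t": [1.0, 2.0], "hg": [0, 1],
                       "lineage": ["a", "a"], "region": ["r", "s"]})
    with pytest.raises(ValueError, match="levels"):
        CrossedInterceptLMM.from_table(df, "lr_t")


def test_headline_fit_on_synthetic_table(small_table):
    res = lf.fit_lmm(small_table, "lr_t")
    assert res.n == small_table.n
    assert res.n_lineages == small_table.n_lineages
    assert res.fixed_effect < 0  # generator uses a negative subsistence shift
    summary = CrossedInterceptLMM.from_table(small_table, "lr_t").fit().summary()
    assert "Random SDs" in summary and "hg" in summary
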