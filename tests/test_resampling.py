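"""Stratified lineage-then-region resampling contrasts."""

import numpy as np
import pandas as pd
import pytest

import labiofreq as lf
from labiofreq.resampling import ContrastConfig, StratifiedContrast, draw_controlled_sample


def _frame(rows):
    return pd.DataFrame(rows, columns=["doculect_id", "lineage", "region", "hg", "lr", "wilr"])


def test_single_row_group_is_forced_pick(rng):
    g = _frame([("d1", "L1", "R1", 1, 0.1, 0.0)])
    for _ in range(5):
        assert draw_controlled_sample(g, rng)["doculect_id"].tolist() == ["d1"]


def test_two_lineages_one_region_collapse_to_fair_coin():
    g = _frame([("a", "L1", "R1", 1, 0.0, 0.0), ("b", "L2", "R1", 1, 1.0, 0.0)])
    rng = np.random.default_rng(11)
    picks = [draw_controlled_sample(g, rng)["doculect_id"].iloc[0] for _ in range(10_000)]
    assert all(len(draw_controlled_sample(g, rng)) == 1 for _ in range(5))
    freq = picks.count("a") / len(picks)
    # exact enumeration gives 1/2; binomial 3-sigma band at n = 10,000
    assert abs(freq - 0.5) < 3 * 0.5 / np.sqrt(10_000)


def test_sample_size_bounded_by_lineages_and_regions(rng):
    for seed in range(20):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 60))
        g = _frame([
            (f"d{i}", f"L{r.integers(0, 10)}", f"R{r.integers(0, 6)}", 1,
             float(r.random()), 0.0)
            for i in range(n)
        ])
        s = draw_controlled_sample(g, rng)
        assert len(s) <= min(g.lineage.nunique(), g.region.nunique())
        assert s.lineage.is_unique and s.region.is_unique


def test_stage_two_universe_is_stage_one_regions():
    # L1 (region R1) and L2 (region R2): stage 1 keeps both, stage 2 keeps both
    # because each region survives; a third lineage sharing R1 can displace L1.
    g = _frame([("a", "L1", "R1", 1, 0.0, 0.0),
                ("b", "L2", "R2", 1, 0.0, 0.0),
                ("c", "L3", "R1", 1, 0.0, 0.0)])
    rng = np.random.default_rng(0)
    sizes = {len(draw_controlled_sample(g, rng)) for _ in range(200)}
    assert sizes == {2}  # R1 contributes exactly one of {a, c}, R2 contributes b


def test_identical_values_give_exact_null(small_table):
    frame = small_table.frame.copy()
    frame["lr"] = 0.25
    table = lf.AnalysisTable(frame=frame, taxonomy="large")
    dist = StratifiedContrast(table, "lr").run(iterations=200, seed=3)
    assert np.all(dist.disparities == 0.0)


def test_unstructured_gap_recovered():
    """With no lineage/region variance the mean disparity estimates the
    between-group gap in expected LR."""
    from scipy.special import logit

    cfg = lf.GeneratorConfig(n_lineages=60, regions=10, doculects_per_lineage="fixed:4",
                             sigma_lineage=0.0, sigma_region=0.0, seed=13,
                             mu=float(logit(0.022)),
                             beta_hg=float(logit(0.008) - logit(0.022)))
    table = lf.generate_profile_table(cfg)
    dist = StratifiedContrast(table, "lr").run(iterations=5000, seed=7)
    # expected gap 0.022 - 0.008 = 0.014; dataset-level binomial noise ~ 0.0015
    assert dist.mean == pytest.approx(0.014, abs=0.005)


def test_fixed_seed_reproduces_vector(small_table):
    a = StratifiedContrast(small_table, "lr").run(iterations=500, seed=9)
    b = StratifiedContrast(small_table, "lr").run(iterations=500, seed=9)
    c = StratifiedContrast(small_table, "lr").run(iterations=500, seed=10)
    assert np.array_equal(a.disparities, b.disparities)
    assert not np.array_equal(a.disparities, c.disparities)


def test_summary_recomputable_from_disparities():
    dist = lf.ContrastDistribution(np.array([1.0, 2.0, 3.0]),
                                   ContrastConfig(iterations=3))
    assert dist.mean == 2.0 and dist.median == 2.0
    assert dist.fraction_positive == 1.0
    zeros = lf.ContrastDistribution(np.zeros(10), ContrastConfig(iterations=10))
    assert zeros.fraction_positive == 0.0
    s = dist.summary()
    assert s["mean"] == 2.0 and s["iterations"] == 3


def test_empty_group_rejected(small_table):
    frame = small_table.frame.copy()
    frame["hg"] = 0
    with pytest.raises(ValueError, match="non-empty"):
        StratifiedContrast(lf.AnalysisTable(frame=frame, taxonomy="large"), "lr")


def test_functional_wrapper_matches_model_object(small_table):
    cfg = ContrastConfig(statistic="wilr", taxonomy="large", iterations=100, seed=5)
    a = lf.contrast_distribution(small_table, cfg)
    b = StratifiedContrast(small_table, "wilr").run(iterations=100, seed=5)
    assert np.array_equal(a.disparities, b.disparities)
    assert lf.summarize_contrast(a)["statistic"] == "wilr"
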