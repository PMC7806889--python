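"""Synthetic generator: bookkeeping, calibration, determinism."""

import filecmp
import json

import numpy as np
import pytest

import labiofreq as lf
from labiofreq.simulate import _expected_lr, _mean_expit


def test_words_per_list_bookkeeping(small_dataset):
    assert all(len(d.forms) == 40 for d in small_dataset.doculects)
    assert {f.concept_id for f in small_dataset.doculects[0].forms} >= {"fish", "dog", "water"}


def test_metadata_covers_every_doculect(small_dataset):
    ids = {d.glottocode for d in small_dataset.doculects}
    assert set(small_dataset.metadata["glottocode"]) == ids


def test_flat_generator_recovers_baseline_rate():
    """With no group structure the mean LR matches the inverse-logit baseline."""
    cfg = lf.GeneratorConfig(n_lineages=100, regions=5, doculects_per_lineage="fixed:5",
                             sigma_lineage=0.0, sigma_region=0.0, beta_hg=0.0,
                             hg_fraction_of_lineages=0.0, seed=17)
    ds = lf.generate_dataset(cfg)
    profiles, _ = lf.profile_doculects(ds.doculects)
    lrs = np.array([p.lr for p in profiles])
    p0 = 0.02
    # per-doculect LR is Binomial(C, p0)/C with C ~ 120 consonants
    se_mean = np.sqrt(p0 * (1 - p0) / 120 / len(lrs))
    assert abs(lrs.mean() - p0) < 4 * se_mean


def test_truth_matches_empirical_lr_as_lists_grow():
    base = dict(n_lineages=5, regions=3, doculects_per_lineage="fixed:2",
                beta_hg=-1.0, seed=23)
    small = lf.generate_dataset(lf.GeneratorConfig(**base, words_per_list=40))
    big = lf.generate_dataset(lf.GeneratorConfig(**base, words_per_list=4000))
    for ds, tol in ((small, 0.05), (big, 0.005)):
        profiles, _ = lf.profile_doculects(ds.doculects)
        for p in profiles:
            assert abs(p.lr - ds.truth["doculect_p"][p.doculect_id]) < tol


def test_paper_mimic_preset_shape_and_targets():
    cfg = lf.paper_mimic_preset(seed=1)
    assert cfg.n_lineages == 233
    assert cfg.regions == 24
    assert cfg.total_doculects == 2729
    assert cfg.beta_hg < 0
    assert _expected_lr(cfg, hg=0) == pytest.approx(0.0218, rel=1e-6)
    assert _expected_lr(cfg, hg=1) == pytest.approx(0.0079, rel=1e-6)


def test_preset_with_zero_effect_equalizes_groups():
    cfg = lf.paper_mimic_preset(seed=1)
    cfg.beta_hg = 0.0
    assert _expected_lr(cfg, hg=0) == _expected_lr(cfg, hg=1)


def test_gauss_hermite_mean_matches_monte_carlo(rng):
    mu, sigma = -3.5, 1.1
    mc = float(np.mean(1 / (1 + np.exp(-(mu + sigma * rng.normal(size=400_000))))))
    assert _mean_expit(mu, sigma) == pytest.approx(mc, abs=3e-4)


def test_fixed_seed_gives_byte_identical_files(tmp_path):
    cfg = lf.GeneratorConfig(n_lineages=8, regions=4, seed=99)
    p1 = lf.generate_dataset(cfg).write(tmp_path / "a")
    p2 = lf.generate_dataset(cfg).write(tmp_path / "b")
    for key in p1:
        assert filecmp.cmp(p1[key], p2[key], shallow=False), key


def test_truth_json_round_trips(tmp_path):
    cfg = lf.GeneratorConfig(n_lineages=6, regions=3, seed=4)
    ds = lf.generate_dataset(cfg)
    paths = ds.write(tmp_path)
    truth = json.loads(paths["truth"].read_text())
    assert truth["config"]["seed"] == 4
    assert len(truth["doculect_p"]) == len(ds.doculects)


def test_counts_path_statistically_matches_wordlist_path():
    """The fast counts-level generator and the full word-list pipeline imply
    the same LR distribution (same moments within Monte-Carlo error)."""
    base = dict(n_lineages=150, regions=10, doculects_per_lineage="fixed:4",
                beta_hg=-1.0, sigma_lineage=0.5, sigma_region=0.3)
    ds = lf.generate_dataset(lf.GeneratorConfig(**base, seed=31))
    profiles, _ = lf.profile_doculects(ds.doculects)
    table_str = lf.join_metadata(lf.profiles_frame(profiles), ds.metadata)
    table_cnt = lf.generate_profile_table(lf.GeneratorConfig(**base, seed=32))
    for col in ("lr", "wilr"):
        a = table_str.frame[col].to_numpy()
        b = table_cnt.frame[col].to_numpy()
        se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert abs(a.mean() - b.mean()) < 4 * se + 1e-4


def test_extreme_config_rejected():
    with pytest.raises(ValueError):
        lf.GeneratorConfig(n_lineages=0)
    with pytest.raises(ValueError):
        lf.GeneratorConfig(sigma_lineage=-1.0)
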