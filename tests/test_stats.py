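"""LR/WILR profiles, ratio transforms, group summaries, chi-square."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import labiofreq as lf
from labiofreq.stats import ZeroConsonantError
from labiofreq.wordlists import Doculect, WordForm


def _doc(words, did="d1"):
    forms = [WordForm(concept_id=f"c{i}", variant_index=0, raw=w, tokens=tuple(w))
             for i, w in enumerate(words)]
    return Doculect(doculect_id=did, forms=forms)


class TestProfile:
    def test_hand_counted_example(self):
        p = lf.profile_doculect(_doc(["fa", "ba"]))
        assert (p.n_consonants, p.n_labiodental, p.n_wi_labiodental) == (2, 1, 1)
        assert p.lr == 0.5 and p.wilr == 0.5

    def test_non_initial_labiodental(self):
        # LR divides by consonant tokens only; the word-medial [f] does not
        # count toward WILR
        p = lf.profile_doculect(_doc(["afa", "ba", "ka"]))
        assert p.lr == pytest.approx(1 / 3)
        assert p.wilr == 0.0

    def test_zero_consonants_excluded(self):
        with pytest.raises(ZeroConsonantError):
            lf.profile_doculect(_doc(["aoe"]))
        profiles, excluded = lf.profile_doculects([_doc(["aoe"], "dz"), _doc(["fa"], "d2")])
        assert excluded == ["dz"]
        assert [p.doculect_id for p in profiles] == ["d2"]

    def test_no_labiodentals_means_zero_ratios(self):
        p = lf.profile_doculect(_doc(["ka", "to", "ni"]))
        assert p.lr == p.wilr == 0.0
        assert not p.has_labiodental

    def test_wilr_never_exceeds_lr_on_synthetic_data(self, small_dataset):
        profiles, _ = lf.profile_doculects(small_dataset.doculects)
        for p in profiles:
            assert p.wilr <= p.lr
        # equality iff every labiodental is word-initial
        eq = [p for p in profiles if p.wilr == p.lr and p.n_labiodental > 0]
        for p in eq:
            assert p.n_wi_labiodental == p.n_labiodental


class TestTransform:
    def test_symmetry_point(self):
        assert lf.transform_ratio(0.5, 100) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("x", [0.0, 0.1, 0.37, 0.9])
    def test_odd_symmetry(self, x):
        n = 321
        assert lf.transform_ratio(x, n) + lf.transform_ratio(1 - x, n) == pytest.approx(0.0, abs=1e-12)

    def test_boundary_closed_form(self):
        y = 0.5 / 2729
        assert lf.transform_ratio(0.0, 2729) == pytest.approx(math.log(y / (1 - y)), rel=1e-14)

    def test_raw_logit_domain_error(self):
        with pytest.raises(ValueError, match="logit_smoothed"):
            lf.transform_ratio(0.0, method="raw_logit")
        assert lf.transform_ratio(0.2, method="raw_logit") == pytest.approx(math.log(0.25))

    def test_vectorized(self):
        out = lf.transform_ratio(np.array([0.0, 0.5]), 10)
        assert out.shape == (2,)
        assert out[1] == pytest.approx(0.0, abs=1e-12)


class TestSummaries:
    def test_trivial_mean(self):
        frame = lf.profiles_frame([
            lf.profile_doculect(_doc(["ka", "to"], "a")),   # lr 0.0
            lf.profile_doculect(_doc(["fa", "ko", "no", "to", "mi",
                                      "ka", "pu", "si", "ru", "lo"], "b")),  # lr 0.1
        ])
        summ = lf.summarize_by_group(frame, {"a": "g", "b": "g"})
        row = summ[summ.group == "g"].iloc[0]
        assert row.lr_mean == pytest.approx(0.05)
        assert row.n == 2

    def test_missing_label_raises(self):
        frame = lf.profiles_frame([lf.profile_doculect(_doc(["fa"], "a"))])
        with pytest.raises(ValueError, match="without a group label"):
            lf.summarize_by_group(frame, {})

    def test_group_means_track_generator_expectations(self):
        cfg = lf.GeneratorConfig(n_lineages=120, regions=12,
                                 doculects_per_lineage="fixed:4",
                                 beta_hg=-1.0, sigma_lineage=0.4, sigma_region=0.2,
                                 seed=8)
        table = lf.generate_profile_table(cfg)
        summ = lf.summarize_by_group(table.frame, table.group_labels())
        from labiofreq.simulate import _expected_lr
        target_non = _expected_lr(cfg, hg=0)
        target_hg = _expected_lr(cfg, hg=1)
        got_non = float(summ.loc[summ.group == "nonHG", "lr_mean"].iloc[0])
        got_hg = float(summ.loc[summ.group == "HG", "lr_mean"].iloc[0])
        # cluster-level Monte-Carlo error dominates; generous 3-sigma-ish bands
        assert got_non == pytest.approx(target_non, rel=0.35)
        assert got_hg == pytest.approx(target_hg, rel=0.5)


class TestChiSquare:
    def test_speaker_counts(self):
        res = lf.pearson_chi_square([[88, 4557], [365, 5264]])
        assert res.statistic == pytest.approx(127.2, abs=0.05)
        assert res.df == 1
        assert res.p_value < 1e-5

    def test_lineage_presence_counts(self):
        res = lf.pearson_chi_square([[0, 7], [18, 12]])
        assert res.statistic == pytest.approx(8.18, abs=0.02)

    def test_identical_proportions_give_zero(self):
        assert lf.pearson_chi_square([[5, 5], [5, 5]]).statistic == 0.0

    def test_row_and_column_swap_invariance(self, rng):
        t = rng.integers(1, 50, size=(2, 2))
        base = lf.pearson_chi_square(t).statistic
        assert lf.pearson_chi_square(t[::-1]).statistic == pytest.approx(base)
        assert lf.pearson_chi_square(t[:, ::-1]).statistic == pytest.approx(base)

    def test_matches_expected_counts_oracle_and_scipy(self, rng):
        for _ in range(200):
            t = rng.integers(1, 100, size=(2, 2)).astype(float)
            got = lf.pearson_chi_square(t)
            rows, cols, n = t.sum(1), t.sum(0), t.sum()
            expected = np.outer(rows, cols) / n
            brute = ((t - expected) ** 2 / expected).sum()
            assert got.statistic == pytest.approx(brute, rel=1e-12)
            sp_stat, sp_p, _, _ = chi2_contingency(t, correction=False)
            assert got.statistic == pytest.approx(sp_stat, rel=1e-12)
            assert got.p_value == pytest.approx(sp_p, rel=1e-9)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            lf.pearson_chi_square([[0, 0], [3, 4]])
        with pytest.raises(ValueError, match="marginal"):
            lf.pearson_chi_square([[3, 0], [4, 0]])
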