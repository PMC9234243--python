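"""Differential screen: t statistics, BH correction, overlaps, PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidflux.differential import (
    bh_adjust,
    increased_in_cold,
    overlap_counts,
    pca_scores,
    ttest_screen,
)
from lipidflux import synthetic

from conftest import make_table
from oracles import bh_oracle


class TestTTestScreen:
    def test_identical_groups_null(self):
        table = make_table(np.array([[1.0, 2, 3, 1, 2, 3]]), ["FA 20:3"])
        rec = ttest_screen(table).iloc[0]
        assert rec["log2_fold_change"] == 0.0
        assert rec["p_value"] == pytest.approx(1.0)
        assert rec["direction"] == "unchanged"

    def test_shifted_groups_closed_form(self):
        # pooled-variance t for [4,5,6] vs [1,2,3]: t=3.674, df=4, p=0.0213
        table = make_table(np.array([[4.0, 5, 6, 1, 2, 3]]), ["FA 20:3"])
        rec = ttest_screen(table).iloc[0]
        assert rec["log2_fold_change"] == pytest.approx(np.log2(5 / 2), abs=1e-9)
        assert rec["t_statistic"] == pytest.approx(3.674, abs=1e-3)
        assert rec["p_value"] == pytest.approx(0.0213, abs=1e-4)

    def test_scale_invariance(self, rng):
        vals = rng.lognormal(3, 0.5, size=(8, 12))
        keys = [f"FA {c}:1" for c in range(10, 18)]
        a = ttest_screen(make_table(vals, keys))
        b = ttest_screen(make_table(vals * 7.3, keys))
        np.testing.assert_allclose(a["t_statistic"], b["t_statistic"], rtol=1e-10)
        np.testing.assert_allclose(a["log2_fold_change"], b["log2_fold_change"], atol=1e-10)

    def test_planted_shifts_rank_first(self):
        """Strongly shifted lipids take the smallest q-values."""
        design = synthetic.small_design(
            tissues=("plasma", "liver"),
            panel_sizes={"plasma": 10, "liver": 200},
            frac_temperature_responsive=0.05,
            temperature_shift_log2=2.0,
            noise_sd=0.25,
            links_per_target=0,
            seed=29,
        )
        study = synthetic.generate_study(design)
        records = ttest_screen(study.normalized("liver"))
        planted = set(study.truth.temperature_shifts["liver"])
        assert planted  # the regime must actually plant something
        top = set(records.nsmallest(len(planted), "q_value")["lipid"])
        assert top == planted

    def test_null_pvalues_uniform(self):
        """With nothing planted, screen p-values look Uniform(0,1)."""
        design = synthetic.small_design(
            tissues=("plasma", "liver"),
            panel_sizes={"plasma": 10, "liver": 400},
            frac_temperature_responsive=0.0,
            links_per_target=0,
            missing_rate=0.0,
            seed=13,
        )
        study = synthetic.generate_study(design)
        records = ttest_screen(study.normalized("liver"), outlier_k=np.inf)
        stat, p = stats.kstest(records["p_value"], "uniform")
        assert p > 0.01

    def test_direction_follows_q_threshold(self, small_study):
        records = ttest_screen(small_study.normalized("liver"), q_threshold=0.30)
        unchanged = records["direction"] == "unchanged"
        assert (records.loc[unchanged, "q_value"] >= 0.30).all()
        assert (records.loc[~unchanged, "q_value"] < 0.30).all()
        assert (records["q_value"] >= records["p_value"] - 1e-15).all()


class TestBHAdjust:
    def test_hand_case(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_stepup_oracle(self, rng):
        for _ in range(500):
            p = rng.random(size=int(rng.integers(1, 13)))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_fdr_control_on_nulls(self, rng):
        """Thresholding q < alpha keeps simulated FDR near or below alpha."""
        alpha, fdps = 0.3, []
        for _ in range(300):
            p_null = rng.random(40)
            p_alt = rng.beta(0.05, 1, size=10)
            p = np.concatenate([p_null, p_alt])
            q = bh_adjust(p)
            rejected = q < alpha
            if rejected.any():
                fdps.append(rejected[:40].sum() / rejected.sum())
            else:
                fdps.append(0.0)
        assert np.mean(fdps) <= alpha + 0.03


class TestOverlapCounts:
    def test_three_set_regions(self):
        regions = overlap_counts({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}, "C": {"c"}})
        assert regions[("A", "B", "C")] == 1  # just c
        assert regions[("A", "B")] == 1  # b
        assert regions[("A",)] == 1  # a
        assert regions[("B",)] == 1  # d
        assert regions[("C",)] == 0

    def test_disjoint_sets(self):
        regions = overlap_counts({"A": {"a"}, "B": {"b"}, "C": set()})
        assert all(v == 0 for k, v in regions.items() if len(k) > 1)

    def test_matches_bruteforce_enumeration(self, rng):
        universe = [f"x{i}" for i in range(12)]
        for _ in range(50):
            sets = {
                name: {u for u in universe if rng.random() < 0.4}
                for name in ("A", "B", "C")
            }
            regions = overlap_counts(sets)
            for k in range(1, 4):
                for members in itertools.combinations(("A", "B", "C"), k):
                    expected = sum(
                        1
                        for u in universe
                        if all(u in sets[m] for m in members)
                        and not any(u in sets[m] for m in sets if m not in members)
                    )
                    assert regions[members] == expected

    def test_increased_set_rule(self, small_study):
        records = ttest_screen(small_study.normalized("liver"))
        inc = increased_in_cold(records)
        sig_up = records[(records["q_value"] < 0.30) & (records["log2_fold_change"] > 0)]
        assert inc == set(sig_up["lipid"])


class TestPCAScores:
    def test_collinear_data_one_component(self):
        data = pd.DataFrame(
            [[1.0, 2, 3, 4], [2.0, 4, 6, 8]], index=["FA 16:0", "FA 18:0"],
            columns=list("abcd"),
        )
        _, var_frac = pca_scores(data)
        assert var_frac[0] == pytest.approx(1.0)

    def test_variance_fractions_partition(self, rng):
        data = pd.DataFrame(rng.normal(size=(20, 8)))
        scores, var_frac = pca_scores(data)
        assert var_frac.sum() == pytest.approx(1.0)
        assert (np.diff(var_frac) <= 1e-12).all()

    def test_full_rank_scores_preserve_geometry(self, rng):
        # at full rank the orthonormal rotation preserves all pairwise
        # distances of the centered samples (i.e. scores are lossless)
        data = pd.DataFrame(rng.normal(size=(6, 5)))
        x = data.to_numpy().T
        scores = pca_scores(data)[0].to_numpy()
        centered = x - x.mean(axis=0)
        d_orig = np.linalg.norm(centered[:, None] - centered[None, :], axis=2)
        d_pca = np.linalg.norm(scores[:, None] - scores[None, :], axis=2)
        np.testing.assert_allclose(d_orig, d_pca, atol=1e-8)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pca_scores(pd.DataFrame([[1.0], [2.0]]))
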