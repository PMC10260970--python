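"""Binomial z tests, effect sizes, BH adjustment, learner classification,
learning-curve comparison and regional contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fosnet import (
    benjamini_hochberg,
    binom_one_sample_z,
    binom_two_sample_z,
    chi_square_proportions,
    classify_learners,
    compare_learning_curves,
    generate_behavior,
    partial_eta_squared,
    region_contrast,
)
from fosnet.behavior import BehaviorTable
from fosnet.synthetic import SyntheticSpec, generate_activation


class TestBinomialOneSample:
    @pytest.mark.parametrize(
        "s, n, p0, z_expected",
        [
            (5, 8, 1 / 3, 1.75),   # learning criterion vs 3-option chance
            (8, 9, 0.5, 2.33),     # circle-trained congruent probe
            (7, 8, 0.5, 2.12),     # fish-trained congruent probe
            (3, 8, 0.5, -0.71),    # incongruent probe (at chance)
        ],
    )
    def test_worked_values(self, s, n, p0, z_expected):
        res = binom_one_sample_z(s, n, p0)
        assert res.statistic == pytest.approx(z_expected, abs=5e-3)

    def test_null_identity(self):
        res = binom_one_sample_z(4, 8, 0.5)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_extreme_proportion_gets_haldane_anscombe(self):
        res = binom_one_sample_z(8, 8, 0.5)
        assert np.isfinite(res.effect_size["OR"])
        assert res.effect_size["OR"] == pytest.approx((8.5 / 0.5) / 1.0)

    @pytest.mark.parametrize("args", [(1, 0, 0.5), (5, 4, 0.5), (1, 4, 0.0), (1, 4, 1.0)])
    def test_invalid_inputs(self, args):
        with pytest.raises(ValueError):
            binom_one_sample_z(*args)

    def test_matches_enumeration_oracle(self):
        """Agree with the directly-coded normal-approximation formula on all
        (s, n <= 30) inputs to 1e-12."""
        p0 = 0.4
        for n in range(1, 31):
            for s in range(n + 1):
                res = binom_one_sample_z(s, n, p0)
                phat = s / n
                z = (phat - p0) / np.sqrt(p0 * (1 - p0) / n)
                assert res.statistic == pytest.approx(z, abs=1e-12)
                assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)


class TestBinomialTwoSample:
    @pytest.mark.parametrize(
        "s1, n1, s2, n2, z_expected, dp_expected",
        [
            (8, 9, 3, 8, 2.56, 0.514),  # congruent vs incongruent, circle-trained
            (7, 8, 3, 8, 2.41, 0.500),  # congruent vs incongruent, fish-trained
        ],
    )
    def test_worked_values(self, s1, n1, s2, n2, z_expected, dp_expected):
        res = binom_two_sample_z(s1, n1, s2, n2)
        assert res.statistic == pytest.approx(z_expected, abs=5e-3)
        assert res.effect_size["delta_p_hat"] == pytest.approx(dp_expected, abs=5e-4)

    def test_equal_proportions_null(self):
        assert binom_two_sample_z(4, 8, 4, 8).statistic == 0.0

    def test_degenerate_variance(self):
        with pytest.raises(ValueError, match="degenerate"):
            binom_two_sample_z(8, 8, 0, 8)

    def test_unpooled_se_oracle(self):
        for s1, n1, s2, n2 in [(5, 12, 3, 9), (1, 5, 4, 7), (10, 30, 20, 30)]:
            res = binom_two_sample_z(s1, n1, s2, n2)
            p1, p2 = s1 / n1, s2 / n2
            se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
            assert res.statistic == pytest.approx((p1 - p2) / se, abs=1e-12)


class TestPartialEtaSquared:
    def test_worked_values(self):
        # preference test: t(15) = 2.55
        assert partial_eta_squared(2.55**2, 1, 15) == pytest.approx(0.302, abs=5e-4)
        # probe-test treatment contrast: F(1, 48) = 12.89
        assert partial_eta_squared(12.89, 1, 48) == pytest.approx(0.212, abs=5e-4)
        assert partial_eta_squared(0.0, 1, 10) == 0.0

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_monotone_in_F(self, f1, f2):
        lo, hi = sorted((f1, f2))
        assert partial_eta_squared(lo, 2, 20) <= partial_eta_squared(hi, 2, 20)
        assert 0.0 <= partial_eta_squared(hi, 2, 20) < 1.0

    def test_negative_F_rejected(self):
        with pytest.raises(ValueError):
            partial_eta_squared(-1.0, 1, 10)


class TestChiSquare:
    def test_brute_force_formula(self):
        # non-learner counts reconstructed from the reported proportions
        res = chi_square_proportions(4, 26, 6, 16)
        a, b, c, d = 4, 26, 6, 16
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(expected, abs=1e-12)
        assert res.statistic == pytest.approx(1.59, abs=5e-3)
        assert res.effect_size["proportion_ratio"] == pytest.approx(0.49, abs=5e-3)

    def test_identical_rows_independent(self):
        assert chi_square_proportions(5, 10, 5, 10).statistic == 0.0

    def test_zero_margin(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_proportions(0, 0, 3, 4)


class TestBenjaminiHochberg:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_equal(self):
        assert benjamini_hochberg([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(benjamini_hochberg([0.1, 0.1, 0.1]), [0.1] * 3)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50)
    def test_dominates_input_and_capped(self, ps):
        adj = benjamini_hochberg(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()

    def test_hand_oracle_general(self, rng):
        """Match a directly-coded step-up adjustment on random inputs."""
        p = rng.random(15)
        order = np.argsort(p)
        m = p.size
        adj_sorted = p[order] * m / (np.arange(m) + 1)
        adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(benjamini_hochberg(p), expected, atol=1e-12)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestClassifyLearners:
    def test_clear_separation(self):
        b = generate_behavior(
            n_subjects=8, learner_fraction=1.0, nonretention_fraction=0.0, seed=3
        )
        # plant one subject at chance in an otherwise strong group
        trials = b.trials.copy()
        chance = trials["subject_id"] == "SL001"
        rng = np.random.default_rng(0)
        trials.loc[chance, "correct"] = (rng.random(chance.sum()) < 0.25).astype(int)
        labels = classify_learners(
            BehaviorTable(trials=trials, probe=b.probe), "SL", "SC"
        )
        assert labels["SL001"] == "non_learner"

    def test_identical_subjects_never_mixed(self):
        import pandas as pd

        b = generate_behavior(n_subjects=6, learner_fraction=1.0,
                              nonretention_fraction=0.0, seed=1)
        # make all paired subjects byte-identical copies of the first
        template = b.trials[b.trials["subject_id"] == "SL001"]
        rows = [b.trials[b.trials["treatment"] == "SC"]]
        for sid in [f"SL{k:03d}" for k in range(1, 7)]:
            rep = template.copy()
            rep["subject_id"] = sid
            rows.append(rep)
        trials = pd.concat(rows, ignore_index=True)
        probe = b.probe.copy()
        probe.loc[probe["treatment"] == "SL", "target"] = 50.0
        labels = classify_learners(BehaviorTable(trials=trials, probe=probe), "SL", "SC")
        assert labels.loc[[f"SL{k:03d}" for k in range(1, 7)]].nunique() == 1

    def test_recovery_of_planted_labels(self):
        """Mean agreement with planted labels >= 90% over 20 seeds."""
        agreement = []
        for seed in range(20):
            b = generate_behavior(n_subjects=16, seed=seed)
            labels = classify_learners(b, "SL", "SC")
            agreement.append((labels == b.labels[labels.index]).mean())
        assert np.mean(agreement) >= 0.9

    def test_missing_probe_errors(self):
        b = generate_behavior(n_subjects=6, learner_fraction=1.0, seed=0)
        probe = b.probe[b.probe["subject_id"] != "SL001"]
        with pytest.raises(ValueError, match="missing probe"):
            classify_learners(BehaviorTable(trials=b.trials, probe=probe), "SL", "SC")


class TestLearningCurves:
    def test_identical_groups_null(self):
        b = generate_behavior(n_subjects=8, seed=5)
        g = b.subset("SL")
        slope, elev = compare_learning_curves(g, g, n_permutations=200, seed=0)
        assert slope.p_value > 0.9
        assert elev.p_value > 0.9

    def test_planted_difference_detected(self):
        learn = generate_behavior(n_subjects=16, learner_fraction=1.0,
                                  plateau=0.9, seed=11).subset("SL")
        flat = generate_behavior(n_subjects=16, learner_fraction=0.0, seed=12).subset("SL")
        slope, _ = compare_learning_curves(learn, flat, n_permutations=999, seed=1)
        assert slope.p_value < 0.01

    def test_type_one_error_controlled(self):
        """Null rejection rate <= 0.07 at nominal 0.05 over 200 replicates."""
        rejections = 0
        for rep in range(200):
            a = generate_behavior(n_subjects=8, seed=1000 + 2 * rep).subset("SL")
            b = generate_behavior(n_subjects=8, seed=1001 + 2 * rep).subset("SL")
            slope, _ = compare_learning_curves(a, b, n_permutations=99, seed=rep)
            rejections += slope.p_value < 0.05
        assert rejections / 200 <= 0.07

    def test_single_session_errors(self):
        b = generate_behavior(n_subjects=6, sessions=1, seed=0)
        with pytest.raises(ValueError, match="2 sessions|slope"):
            compare_learning_curves(b.subset("SL"), b.subset("SC"))


class TestRegionContrast:
    @staticmethod
    def _two_group_spec(seed, shift_nodes=(), delta=0.0):
        return SyntheticSpec(
            n_nodes=20,
            specimens_per_treatment=8,
            treatments=("SL", "SC"),
            differential_regions=[("SL", i, delta) for i in shift_nodes],
            baseline_mean=100.0,
            noise_sd=20.0,
            seed=seed,
        )

    def test_planted_shift_recovered(self):
        """Shifted nodes carry the smallest adjusted p in >= 90% of 20 seeds."""
        hits = 0
        for seed in range(20):
            spec = self._two_group_spec(seed, shift_nodes=(0, 1, 2, 3), delta=60.0)
            table, truth = generate_activation(spec)
            df = region_contrast(table, ("SL", "SC"))
            top4 = set(df.sort_values("p_adj").index[:4])
            planted = {nid for _, nid, _ in truth.differential}
            hits += top4 == planted
        assert hits >= 18

    def test_null_rarely_significant(self):
        runs_with_hits = 0
        for seed in range(20):
            table, _ = generate_activation(self._two_group_spec(100 + seed))
            df = region_contrast(table, ("SL", "SC"))
            runs_with_hits += (df["p_adj"] < 0.05).any()
        assert runs_with_hits <= 3

    def test_direction_and_m1_identity(self):
        spec = self._two_group_spec(7, shift_nodes=(0,), delta=80.0)
        table, _ = generate_activation(spec)
        df = region_contrast(table, ("SL", "SC"))
        assert df.iloc[0]["direction"] == 1.0
        single = df.iloc[[0]]
        # BH with m = 1 leaves the p-value unchanged
        np.testing.assert_allclose(
            benjamini_hochberg(single["p"].to_numpy()), single["p"].to_numpy()
        )
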