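"""Permutation statistics: updates, paired t, effect sizes, interaction F, BH."""

import numpy as np
import pandas as pd
import pytest

from asrc.stats import (
    EffectSizeInputs,
    attribution_update_test,
    bh_adjust,
    correlation_permutation,
    hedges_d,
    interaction_permutation_test,
    outcome_update_test,
    paired_permutation_test,
    quartile_proportions,
    rm_anova_interaction_F,
    skill_updates,
)
from asrc.task import ParticipantDataset


def make_dataset(pid, outcomes, attributions, factor, reports=None):
    n = len(outcomes)
    if reports is None:
        reports = np.linspace(0.3, 0.7, n)
    return ParticipantDataset(
        participant_id=pid,
        probe=np.arange(n),
        session=np.array([1] * (n // 2) + [2] * (n - n // 2)),
        outcome=np.asarray(outcomes),
        attribution=np.asarray(attributions, dtype=object),
        skill_report=np.asarray(reports, dtype=float),
        path_length=np.asarray(factor, dtype=float),
        prop_nonup=np.full(n, 0.3),
        prop_correct_keys=np.full(n, 0.7),
        prop_pauses=np.full(n, 0.1),
        time_limit=np.full(n, 30.0),
        difficulty=np.zeros(n),
    )


class TestSkillUpdates:
    def test_hand_zscoring(self):
        u = skill_updates([0.2, 0.4, 0.6])
        np.testing.assert_allclose(u, [1.0, 1.0])  # z-scores (-1, 0, 1), sd ddof=1

    def test_reversal_negates_updates(self):
        r = np.array([0.1, 0.5, 0.2, 0.9])
        np.testing.assert_allclose(skill_updates(r), -skill_updates(r[::-1])[::-1])

    def test_constant_series_warns_and_returns_zeros(self):
        with pytest.warns(RuntimeWarning):
            u = skill_updates([0.5, 0.5, 0.5])
        np.testing.assert_array_equal(u, 0.0)


class TestPairedPermutation:
    def test_identical_conditions_give_zero_t(self):
        rng = np.random.default_rng(0)
        samples = []
        for _ in range(8):
            v = rng.normal(size=12)
            v = np.concatenate([v, v])  # condition means identical
            l = np.array([1] * 12 + [0] * 12)
            samples.append((v, l))
        res = paired_permutation_test(samples, n_perm=200, seed=1)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.9

    def test_huge_effect_hits_p_floor(self):
        rng = np.random.default_rng(0)
        samples = []
        for _ in range(10):
            v = np.concatenate([10 + 0.01 * rng.normal(size=10), 0.01 * rng.normal(size=10)])
            l = np.array([1] * 10 + [0] * 10)
            samples.append((v, l))
        res = paired_permutation_test(samples, n_perm=500, seed=2)
        assert res.p_value == pytest.approx(1 / 501)
        assert res.exceedances == 0
        assert res.effect_size is not None and res.effect_size > 5

    def test_participants_missing_a_condition_excluded(self):
        samples = [
            (np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, 0, 0])),
            (np.array([1.0, 2.0]), np.array([1, 1])),  # only condition 1
            (np.array([0.5, 2.5, 1.0, 3.0]), np.array([1, 1, 0, 0])),
        ]
        res = paired_permutation_test(samples, n_perm=100, seed=0)
        assert res.n_units == 2

    def test_p_floor_property(self):
        rng = np.random.default_rng(3)
        samples = [(rng.normal(size=10), np.array([1] * 5 + [0] * 5)) for _ in range(5)]
        for n_perm in (10, 99):
            res = paired_permutation_test(samples, n_perm=n_perm, seed=4)
            assert res.p_value >= 1 / (n_perm + 1)


class TestHedgesD:
    def test_equal_means_give_zero(self):
        assert hedges_d(mu1=1.0, mu2=1.0, sd1=0.5, sd2=0.7, n1=10, n2=12) == 0.0

    def test_printed_formula_example(self):
        d = hedges_d(mu1=1.0, mu2=0.0, sd1=1.0, sd2=1.0, n1=20, n2=20)
        assert d == pytest.approx((1 - 3 / 151) * 1.0, abs=1e-12)

    def test_swapping_groups_negates(self):
        e = EffectSizeInputs(mu1=2.0, mu2=1.2, sd1=0.8, sd2=1.1, n1=15, n2=18)
        swapped = EffectSizeInputs(mu1=1.2, mu2=2.0, sd1=1.1, sd2=0.8, n1=18, n2=15)
        assert hedges_d(e) == pytest.approx(-hedges_d(swapped))

    def test_matches_literal_transcription_on_random_inputs(self, rng):
        for _ in range(20):
            mu1, mu2 = rng.normal(size=2)
            sd1, sd2 = rng.uniform(0.1, 2, size=2)
            n1, n2 = rng.integers(2, 40, size=2)
            pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
            literal = (1 - 3 / (4 * (n1 + n2) - 9)) * (mu1 - mu2) / pooled
            assert hedges_d(mu1=mu1, mu2=mu2, sd1=sd1, sd2=sd2,
                            n1=int(n1), n2=int(n2)) == pytest.approx(literal)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            hedges_d(mu1=1.0, mu2=0.0, sd1=0.0, sd2=0.0, n1=5, n2=5)


class TestQuartileProportions:
    def test_all_probes_to_option_give_unit_proportions(self, rng):
        ds = make_dataset("p0", rng.integers(0, 2, 16), ["ability"] * 16,
                          rng.normal(size=16))
        table = quartile_proportions([ds], "ability", "path_length")
        assert (table.dropna()["proportion"] == 1.0).all()

    def test_proportions_sum_to_one_over_options(self, rng):
        ds = make_dataset("p0", rng.integers(0, 2, 40),
                          rng.choice(["ability", "maze", "rotations", "luck"], 40),
                          rng.normal(size=40))
        total = None
        for opt in ("ability", "maze", "rotations", "luck"):
            t = quartile_proportions([ds], opt, "path_length").set_index(["bin", "outcome"])
            col = t["proportion"]
            total = col if total is None else total + col
        filled = total.dropna()
        np.testing.assert_allclose(filled, 1.0)

    def test_eight_probe_fixture_matches_hand_count(self):
        # factor quartiles by rank: bins (0,0,1,1,2,2,3,3); outcomes alternate
        ds = make_dataset(
            "p0",
            [1, 0, 1, 0, 1, 0, 1, 0],
            ["ability", "maze", "ability", "ability", "maze", "maze", "ability", "maze"],
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
        )
        t = quartile_proportions([ds], "ability", "path_length").set_index(["bin", "outcome"])
        assert t.loc[(0, 1), "proportion"] == 1.0  # probe 0: ability
        assert t.loc[(0, 0), "proportion"] == 0.0  # probe 1: maze
        assert t.loc[(1, 1), "proportion"] == 1.0  # probe 2
        assert t.loc[(1, 0), "proportion"] == 1.0  # probe 3: ability
        assert t.loc[(2, 1), "proportion"] == 0.0  # probe 4: maze
        assert t.loc[(3, 0), "proportion"] == 0.0  # probe 7: maze


class TestInteractionF:
    def test_identical_cells_give_zero(self):
        cells = np.ones((5, 4, 2)) * 0.3
        assert rm_anova_interaction_F(cells) == 0.0

    def test_matches_brute_force_sums_of_squares(self, rng):
        """Independent oracle: explicit loops over the classical repeated-
        measures decomposition."""
        y = rng.uniform(0, 1, size=(5, 4, 2))
        n, a, b = y.shape
        grand = y.mean()
        ss_ab = 0.0
        for i in range(a):
            for j in range(b):
                ss_ab += (y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean() + grand) ** 2
        ss_ab *= n
        ss_err = 0.0
        for s in range(n):
            for i in range(a):
                for j in range(b):
                    pred = (
                        y[:, i, j].mean() + y[s, i, :].mean() + y[s, :, j].mean()
                        - y[:, i, :].mean() - y[:, :, j].mean() - y[s].mean() + grand
                    )
                    ss_err += (y[s, i, j] - pred) ** 2
        f_oracle = (ss_ab / ((a - 1) * (b - 1))) / (ss_err / ((a - 1) * (b - 1) * (n - 1)))
        assert rm_anova_interaction_F(y) == pytest.approx(f_oracle, abs=1e-10)

    def test_matches_pingouin_two_way_rm_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.uniform(0, 1, size=(6, 4, 2))
        rows = []
        for s in range(6):
            for i in range(4):
                for j in range(2):
                    rows.append({"subject": s, "A": i, "B": j, "y": y[s, i, j]})
        df = pd.DataFrame(rows)
        table = pg.rm_anova(data=df, dv="y", within=["A", "B"], subject="subject")
        f_pg = float(table.loc[table["Source"] == "A * B", "F"].iloc[0])
        assert rm_anova_interaction_F(y) == pytest.approx(f_pg, rel=1e-6)

    def test_pipeline_detects_planted_interaction(self, rng):
        datasets = []
        for p in range(8):
            n = 48
            factor = rng.normal(size=n)
            outcome = rng.integers(0, 2, n)
            # maze attributions likelier for losses with long paths
            p_maze = 1 / (1 + np.exp(-(2 * factor * (1 - 2 * outcome))))
            att = np.where(rng.random(n) < p_maze, "maze", "luck")
            datasets.append(make_dataset(f"p{p}", outcome, att, factor))
        res = interaction_permutation_test(datasets, "maze", "path_length",
                                           n_perm=300, seed=5)
        assert res.p_value < 0.02

    def test_too_few_participants_rejected(self, rng):
        ds = make_dataset("p0", rng.integers(0, 2, 24),
                          rng.choice(["maze", "luck"], 24), rng.normal(size=24))
        with pytest.raises(ValueError):
            interaction_permutation_test([ds, ds], "maze", "path_length", n_perm=10)


class TestBH:
    def test_single_small_p_rejected(self):
        reject, thr = bh_adjust([0.04], alpha=0.05)
        assert reject.all() and thr == 0.04

    def test_all_ones_nothing_rejected(self):
        reject, thr = bh_adjust([1.0, 1.0, 1.0])
        assert not reject.any() and thr == 0.0

    def test_step_up_example(self):
        reject, thr = bh_adjust([0.001, 0.01, 0.03, 0.2], alpha=0.05)
        np.testing.assert_array_equal(reject, [True, True, True, False])
        assert thr == 0.03

    def test_monotone_in_alpha_and_contiguous(self, rng):
        p = rng.uniform(size=30)
        r1, _ = bh_adjust(p, alpha=0.01)
        r2, _ = bh_adjust(p, alpha=0.10)
        assert set(np.flatnonzero(r1)) <= set(np.flatnonzero(r2))
        # never rejects a p above the largest rejected p
        for rej in (r1, r2):
            if rej.any():
                assert p[~rej].min() > p[rej].max() or not (~rej).any()


class TestCorrelation:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert correlation_permutation(x, x, n_perm=99, seed=0).statistic == pytest.approx(1.0)
        assert correlation_permutation(x, -x, n_perm=99, seed=0).statistic == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_permutation([1, 1, 1], [1, 2, 3], n_perm=10)

    def test_null_calibration(self, rng):
        hits = 0
        reps = 300
        for _ in range(reps):
            x, y = rng.normal(size=(2, 40))
            if correlation_permutation(x, y, n_perm=99, seed=int(rng.integers(2**31))).p_value <= 0.05:
                hits += 1
        assert 0.02 <= hits / reps <= 0.09


class TestUpdateAnalyses:
    def test_outcome_effect_detected_in_synthetic_cohort(self, small_cohort):
        res = outcome_update_test(small_cohort[0], n_perm=300, seed=1)
        assert res.statistic > 0  # wins raise skill estimates
        assert res.p_value < 0.05

    def test_attribution_effect_sign_for_wins(self, small_cohort):
        # generated with internal rates above external: larger updates
        res = attribution_update_test(small_cohort[0], outcome=1, n_perm=300, seed=1)
        assert res.statistic > 0
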