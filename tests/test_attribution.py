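"""Attribution-choice models: scores, softmax, likelihood, transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asrc.attribution import (
    FEATURE_SETS,
    OPTIONS,
    AttributionModel,
    AttributionModelSpec,
    OptionWeights,
    bias_preferences,
    build_features,
    choice_probabilities,
    feature_effect,
    log_likelihood,
    option_scores,
    param_names,
)
from asrc.task import ParticipantDataset


def make_dataset(outcomes, attributions, reports=None, rng=None):
    n = len(outcomes)
    rng = rng or np.random.default_rng(0)
    if reports is None:
        reports = rng.uniform(0, 1, n)
    return ParticipantDataset(
        participant_id="p0",
        probe=np.arange(n),
        session=np.array([1] * (n // 2) + [2] * (n - n // 2)),
        outcome=np.asarray(outcomes),
        attribution=np.asarray(attributions, dtype=object),
        skill_report=np.asarray(reports, dtype=float),
        path_length=rng.integers(5, 20, n).astype(float),
        prop_nonup=rng.uniform(0, 1, n),
        prop_correct_keys=rng.uniform(0, 1, n),
        prop_pauses=rng.uniform(0, 0.5, n),
        time_limit=np.full(n, 30.0),
        difficulty=rng.normal(0, 1, n),
    )


class TestSpecs:
    @pytest.mark.parametrize(
        "feature_set,n_params",
        [
            ("bias", 6),
            ("bias_skill", 12),
            ("bias_performance", 18),
            ("bias_performance_task", 30),
            ("bias_skill_task", 24),
            ("full", 36),
        ],
    )
    def test_parameter_counts(self, feature_set, n_params):
        assert AttributionModelSpec(feature_set).n_params == n_params

    def test_unknown_feature_set_rejected(self):
        with pytest.raises(ValueError):
            AttributionModelSpec("everything")


class TestScores:
    def test_zero_weights_give_zero_scores(self):
        w = OptionWeights.zeros(2)
        scores = option_scores(w, np.array([1.0, 0.7]), "win")
        np.testing.assert_array_equal(scores, np.zeros(4))

    def test_bias_only_example(self):
        w = OptionWeights(win=np.array([[1.0], [0.5], [-0.5]]), loss=np.zeros((3, 1)))
        scores = option_scores(w, np.array([1.0]), "win")
        np.testing.assert_allclose(scores, [1.0, 0.5, -0.5, -1.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=6))
    def test_scores_sum_to_zero_for_any_weights(self, flat):
        w = OptionWeights(win=np.array(flat).reshape(3, 2), loss=np.zeros((3, 2)))
        scores = option_scores(w, np.array([1.0, 0.3]), 1)
        assert abs(scores.sum()) < 1e-12

    def test_feature_mismatch_rejected(self):
        w = OptionWeights.zeros(2)
        with pytest.raises(ValueError):
            option_scores(w, np.array([1.0, 0.3, 0.4]), "win")


class TestChoiceProbabilities:
    def test_zero_scores_give_chance_level(self):
        np.testing.assert_allclose(choice_probabilities(np.zeros(4)), 0.25)

    def test_dominant_score_approaches_one(self):
        p = choice_probabilities(np.array([200.0, 0.0, 0.0, -200.0]))
        assert p[0] > 0.999
        assert np.isfinite(p).all()

    def test_overflow_guarded(self):
        p = choice_probabilities(np.array([1e4, 0.0, -1e4, 0.0]))
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-20, 20), min_size=4, max_size=4),
        st.floats(-50, 50),
    )
    def test_translation_invariance(self, scores, c):
        scores = np.array(scores)
        np.testing.assert_allclose(
            choice_probabilities(scores), choice_probabilities(scores + c), atol=1e-12
        )

    def test_matches_exponential_sum_loop(self):
        scores = np.array([1.0, 0.5, -0.5, -1.0])
        expected = [np.exp(s) / sum(np.exp(x) for x in scores) for s in scores]
        np.testing.assert_allclose(choice_probabilities(scores), expected, atol=1e-12)


class TestLikelihood:
    def test_uniform_weights_give_chance_per_probe(self):
        ds = make_dataset([1, 0, 1, 0], ["ability", "maze", "luck", "rotations"])
        spec = AttributionModelSpec("bias")
        ll = log_likelihood(OptionWeights.zeros(spec), spec, ds)
        assert ll == pytest.approx(4 * np.log(0.25))

    def test_dominant_score_gives_near_zero_loglik(self):
        ds = make_dataset([1], ["ability"])
        spec = AttributionModelSpec("bias")
        w = OptionWeights(win=np.array([[50.0], [0.0], [0.0]]), loss=np.zeros((3, 1)))
        assert log_likelihood(w, spec, ds) == pytest.approx(0.0, abs=1e-6)

    def test_missing_attributions_excluded(self):
        ds = make_dataset([1, 1, 0], ["ability", "missing", "maze"])
        spec = AttributionModelSpec("bias")
        ll = log_likelihood(OptionWeights.zeros(spec), spec, ds)
        assert ll == pytest.approx(2 * np.log(0.25))

    def test_all_missing_rejected(self):
        ds = make_dataset([1, 0], ["missing", "missing"])
        spec = AttributionModelSpec("bias")
        with pytest.raises(ValueError):
            log_likelihood(OptionWeights.zeros(spec), spec, ds)

    def test_matches_per_row_loop_oracle(self, rng):
        n = 30
        ds = make_dataset(
            rng.integers(0, 2, n),
            rng.choice(["ability", "maze", "rotations", "luck"], n),
            rng=rng,
        )
        spec = AttributionModelSpec("full")
        w = OptionWeights(
            win=rng.normal(0, 0.7, (3, 6)), loss=rng.normal(0, 0.7, (3, 6))
        )
        features = build_features(ds, spec)
        oracle = 0.0
        for t in range(n):
            scores = option_scores(w, features[t], int(ds.outcome[t]))
            probs = choice_probabilities(scores)
            oracle += np.log(probs[OPTIONS.index(ds.attribution[t])])
        assert log_likelihood(w, spec, ds) == pytest.approx(oracle, abs=1e-10)


class TestFeatures:
    def test_bias_column_and_zscoring(self, small_cohort):
        ds = small_cohort[0][0]
        spec = AttributionModelSpec("full")
        f = build_features(ds, spec)
        assert f.shape == (len(ds), 6)
        np.testing.assert_array_equal(f[:, 0], 1.0)
        # z-scored columns have near-zero participant-level mean
        for j in range(2, 6):
            assert abs(f[:, j].mean()) < 1e-10

    def test_skill_feature_is_lagged_previous_report(self, small_cohort):
        ds = small_cohort[0][0]
        spec = AttributionModelSpec("bias_skill")
        f = build_features(ds, spec)
        z = (ds.skill_report - ds.skill_report.mean()) / ds.skill_report.std(ddof=1)
        assert f[0, 1] == 0.0
        np.testing.assert_allclose(f[1:, 1], z[:-1])


class TestTransforms:
    def test_zero_biases_give_quarter_preferences(self):
        prefs = bias_preferences(OptionWeights.zeros(3))
        np.testing.assert_allclose(prefs.to_numpy(), 0.25)

    def test_preferences_sum_to_one_per_valence(self, rng):
        w = OptionWeights(win=rng.normal(0, 1, (3, 4)), loss=rng.normal(0, 1, (3, 4)))
        prefs = bias_preferences(w)
        np.testing.assert_allclose(prefs.sum(axis=1), 1.0)

    def test_asymmetric_bias_cross_checked_by_direct_evaluation(self):
        w = OptionWeights(win=np.array([[1.0], [0.0], [-1.0]]), loss=np.zeros((3, 1)))
        prefs = bias_preferences(w)
        scores = np.array([1.0, 0.0, -1.0, 0.0])
        expected = np.exp(scores) / np.exp(scores).sum()
        np.testing.assert_allclose(prefs.loc["win"].to_numpy(), expected, atol=1e-12)

    def test_zero_weights_give_zero_effect(self, rng):
        ds = make_dataset(rng.integers(0, 2, 20),
                          rng.choice(["ability", "maze"], 20), rng=rng)
        spec = AttributionModelSpec("bias_skill")
        eff = feature_effect(OptionWeights.zeros(spec), ds, spec, "skill_estimate",
                             "ability", "win")
        assert eff == 0.0

    def test_effects_sum_to_zero_over_options(self, rng):
        ds = make_dataset(rng.integers(0, 2, 30),
                          rng.choice(["ability", "maze", "luck"], 30), rng=rng)
        spec = AttributionModelSpec("full")
        w = OptionWeights(win=rng.normal(0, 1, (3, 6)), loss=rng.normal(0, 1, (3, 6)))
        for feat in spec.features:
            total = sum(
                feature_effect(w, ds, spec, feat, opt, "loss") for opt in OPTIONS
            )
            assert abs(total) < 1e-12

    def test_analytic_gradient_matches_finite_differences(self, rng):
        """The average marginal effect equals a central finite difference of
        the softmax probability with respect to the feature at 0."""
        ds = make_dataset(rng.integers(0, 2, 25),
                          rng.choice(["ability", "maze"], 25), rng=rng)
        spec = AttributionModelSpec("full")
        w = OptionWeights(win=rng.normal(0, 0.8, (3, 6)), loss=rng.normal(0, 0.8, (3, 6)))
        h = 1e-5
        features = build_features(ds, spec)
        for valence, o in (("win", 1), ("loss", 0)):
            feats = features[ds.outcome == o]
            for feat in ("skill_estimate", "path_length"):
                col = 1 + spec.features.index(feat)
                for opt in OPTIONS:
                    a = OPTIONS.index(opt)
                    diffs = []
                    for row in feats:
                        up, down = row.copy(), row.copy()
                        up[col], down[col] = h, -h
                        p_up = choice_probabilities(option_scores(w, up, valence))[a]
                        p_dn = choice_probabilities(option_scores(w, down, valence))[a]
                        diffs.append((p_up - p_dn) / (2 * h))
                    analytic = feature_effect(w, ds, spec, feat, opt, valence)
                    assert analytic == pytest.approx(np.mean(diffs), abs=1e-6)


class TestModel:
    def test_theta_loglik_matches_public_api(self, small_cohort):
        datasets, _ = small_cohort
        model = AttributionModel(datasets, spec="bias_skill")
        rng = np.random.default_rng(5)
        theta = rng.normal(0, 0.5, model.n_params)
        w = OptionWeights.from_vector(theta, model.spec.n_features)
        for p in range(len(datasets)):
            assert model._theta_loglik(p, theta) == pytest.approx(
                log_likelihood(w, model.spec, datasets[p]), abs=1e-10
            )

    def test_param_names_cover_layout(self):
        spec = AttributionModelSpec("bias_skill")
        names = param_names(spec)
        assert len(names) == spec.n_params
        assert names[0] == "w[win,ability,bias]"
        assert names[-1] == "w[loss,rotations,skill_estimate]"
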