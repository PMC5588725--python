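import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from maxsnippet.featurization import FeatureEncoding, FeatureMatrix, Snippet, encode_cohort
from maxsnippet.model import (
    AdamState,
    DetectorParams,
    EarlyStoppingConfig,
    FitConfig,
    FittingError,
    ChecksumError,
    adam_step,
    bagged_fit,
    bagged_predict,
    fit,
    load_model,
    negative_log_likelihood,
    nll_gradient,
    predict,
    repertoire_probability,
    save_model,
    snippet_logit,
    snippet_score,
)


def _fm(X, pid="P"):
    X = np.asarray(X, dtype=np.float64)
    snippets = [Snippet("X" * X.shape[1], 0, i, pid) for i in range(X.shape[0])]
    return FeatureMatrix(pid, X, snippets)


def _random_instance(rng, n_patients=4, max_snippets=10, n_features=30, scale=0.5):
    fms, labels = [], []
    for i in range(n_patients):
        n = int(rng.integers(1, max_snippets + 1))
        fms.append(_fm(rng.normal(0, 1, (n, n_features)), pid=f"P{i}"))
        labels.append(i % 2)
    params = DetectorParams(
        b0=float(rng.normal(0, scale)), W=rng.normal(0, scale, n_features)
    )
    return params, fms, labels


def brute_force_nll(params, fms, labels):
    """Independent high-precision oracle: enumerate every snippet sigmoid."""
    total = np.longdouble(0)
    for fm, y in zip(fms, labels):
        scores = []
        for row in fm.X:
            z = np.longdouble(params.b0)
            for w, f in zip(params.W, row):
                z += np.longdouble(w) * np.longdouble(f)
            scores.append(1 / (1 + np.exp(-z)))
        p = max(scores)
        total += -(np.log(p) if y == 1 else np.log(1 - p))
    return float(total)


class TestScoring:
    def test_logit_zero_case(self):
        params = DetectorParams(0.0, np.zeros(3))
        assert snippet_logit([1.0, 2.0, 3.0], params) == 0.0

    def test_logit_dot_product(self):
        params = DetectorParams(2.0, np.array([1.0, 0.0, 0.0]))
        assert snippet_logit([3.0, 9.0, 9.0], params) == 5.0

    def test_logit_matches_elementwise_oracle(self, rng):
        for _ in range(20):
            w = rng.normal(0, 1, 30)
            f = rng.normal(0, 1, 30)
            b0 = float(rng.normal())
            expected = b0 + sum(wi * fi for wi, fi in zip(w, f))
            got = snippet_logit(f, DetectorParams(b0, w))
            assert math.isclose(got, expected, rel_tol=1e-12, abs_tol=1e-12)

    def test_logit_rejects_nonfinite_and_mismatch(self):
        params = DetectorParams(0.0, np.zeros(2))
        with pytest.raises(ValueError):
            snippet_logit([np.nan, 1.0], params)
        with pytest.raises(ValueError):
            snippet_logit([1.0], params)

    def test_sigmoid_at_zero(self):
        assert snippet_score(0.0) == 0.5

    def test_sigmoid_saturates_without_overflow(self):
        assert snippet_score(1000.0) == pytest.approx(1.0)
        assert snippet_score(-1000.0) == pytest.approx(0.0, abs=1e-300)

    @given(st.floats(-50, 50))
    def test_sigmoid_symmetry(self, x):
        assert snippet_score(x) + snippet_score(-x) == pytest.approx(1.0, abs=1e-12)

    def test_max_pooling(self):
        assert repertoire_probability([0.2, 0.7, 0.4]) == (0.7, 1)
        assert repertoire_probability([0.3]) == (0.3, 0)

    def test_max_pooling_appending_smaller_is_noop(self):
        p, _ = repertoire_probability([0.2, 0.9, 0.4])
        p2, i2 = repertoire_probability([0.2, 0.9, 0.4, 0.9, 0.1])
        assert (p2, i2) == (p, 1)  # ties resolve to the first index

    def test_empty_repertoire_rejected(self):
        with pytest.raises(ValueError):
            repertoire_probability([])


class TestLikelihood:
    def test_closed_form_at_zero_params(self):
        params = DetectorParams(0.0, np.zeros(4))
        fms = [_fm(np.random.rand(3, 4)), _fm(np.random.rand(5, 4))]
        nll = negative_log_likelihood(params, fms, [1, 0])
        assert nll == pytest.approx(2 * math.log(2), rel=1e-15)

    def test_positive_patient_with_saturated_score(self):
        params = DetectorParams(50.0, np.zeros(2))
        nll = negative_log_likelihood(params, [_fm([[0.0, 0.0]])], [1])
        assert 0 <= nll < 1e-20

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            params, fms, labels = _random_instance(rng)
            ours = negative_log_likelihood(params, fms, labels)
            oracle = brute_force_nll(params, fms, labels)
            assert ours == pytest.approx(oracle, rel=1e-10)

    def test_regularization_terms(self):
        params = DetectorParams(0.0, np.array([1.0, -2.0]))
        fms = [_fm([[0.0, 0.0]]), _fm([[0.0, 0.0]])]
        base = negative_log_likelihood(params, fms, [1, 0])
        with_l1 = negative_log_likelihood(params, fms, [1, 0], l1=0.5)
        with_l2 = negative_log_likelihood(params, fms, [1, 0], l2=0.5)
        assert with_l1 == pytest.approx(base + 0.5 * 3.0)
        assert with_l2 == pytest.approx(base + 0.5 * 5.0)


class TestGradient:
    def test_finite_difference_agreement(self, rng):
        h = 1e-6
        for _ in range(10):
            params, fms, labels = _random_instance(rng, n_features=8)
            db0, dW = nll_gradient(params, fms, labels)
            num_b0 = (
                negative_log_likelihood(DetectorParams(params.b0 + h, params.W), fms, labels)
                - negative_log_likelihood(DetectorParams(params.b0 - h, params.W), fms, labels)
            ) / (2 * h)
            assert db0 == pytest.approx(num_b0, rel=1e-5, abs=1e-7)
            for j in range(0, 8, 3):
                Wp, Wm = params.W.copy(), params.W.copy()
                Wp[j] += h
                Wm[j] -= h
                num = (
                    negative_log_likelihood(DetectorParams(params.b0, Wp), fms, labels)
                    - negative_log_likelihood(DetectorParams(params.b0, Wm), fms, labels)
                ) / (2 * h)
                assert dW[j] == pytest.approx(num, rel=1e-5, abs=1e-7)

    def test_single_snippet_reduces_to_logistic_regression(self):
        x = np.array([0.5, -1.5, 2.0])
        params = DetectorParams(0.3, np.array([1.0, 0.2, -0.7]))
        db0, dW = nll_gradient(params, [_fm(x[None, :])], [1])
        p = snippet_score(snippet_logit(x, params))
        assert db0 == pytest.approx(p - 1)
        np.testing.assert_allclose(dW, (p - 1) * x, rtol=1e-12)

    def test_tie_uses_first_index(self):
        # two identical snippets: gradient must equal the single-snippet value
        x = np.array([1.0, 2.0])
        params = DetectorParams(0.0, np.array([0.1, 0.1]))
        _, dW_two = nll_gradient(params, [_fm(np.vstack([x, x]))], [0])
        _, dW_one = nll_gradient(params, [_fm(x[None, :])], [0])
        np.testing.assert_array_equal(dW_two, dW_one)


class TestAdam:
    def test_hand_computed_first_step(self):
        config = FitConfig(step_size=0.01, beta1=0.9, beta2=0.999, epsilon=1e-8)
        state = AdamState.initialize(np.array([1.0, -1.0]))
        g = np.array([0.5, -2.0])
        new = adam_step(state, g, config)
        # t=1: m_hat = g, v_hat = g^2 -> step = lr * g / (|g| + eps)
        expected = state.theta - 0.01 * g / (np.abs(g) + 1e-8)
        np.testing.assert_allclose(new.theta, expected, rtol=1e-12)

    def test_zero_gradient_never_moves(self):
        config = FitConfig()
        state = AdamState.initialize(np.array([3.0]))
        for _ in range(5):
            state = adam_step(state, np.zeros(1), config)
        assert state.theta[0] == 3.0


@pytest.fixture(scope="module")
def small_separable(tiny_cohort, tiny_features):
    cohort, truth = tiny_cohort
    return tiny_features, cohort.labels, truth


class TestFit:
    def test_separable_cohort_reaches_full_training_accuracy(self, small_separable, tiny_fit):
        fms, labels, _ = small_separable
        preds = [predict(tiny_fit.params, fm) for fm in fms]
        correct = sum(
            (p.diagnosis == "positive") == bool(y) for p, y in zip(preds, labels)
        )
        assert correct == len(labels)
        assert tiny_fit.train_nll < 0.5

    def test_every_restart_improves_on_its_initialization(self, tiny_fit):
        assert all(tiny_fit.converged_flags)

    def test_train_nll_is_min_over_restarts(self, tiny_fit):
        assert tiny_fit.train_nll == min(r.final_nll for r in tiny_fit.per_restart)

    def test_restart_superset_monotonicity(self, small_separable):
        fms, labels, _ = small_separable
        nll1 = fit(fms, labels, FitConfig(n_restarts=1, n_iterations=100, seed=3)).train_nll
        nll5 = fit(fms, labels, FitConfig(n_restarts=5, n_iterations=100, seed=3)).train_nll
        assert nll5 <= nll1

    def test_deterministic_under_seed(self, small_separable):
        fms, labels, _ = small_separable
        config = FitConfig(n_restarts=3, n_iterations=50, seed=11)
        a = fit(fms, labels, config)
        b = fit(fms, labels, config)
        np.testing.assert_array_equal(a.params.W, b.params.W)
        assert a.train_nll == b.train_nll

    def test_patient_order_invariance(self, small_separable, rng):
        fms, labels, _ = small_separable
        config = FitConfig(n_restarts=3, n_iterations=50, seed=11)
        a = fit(fms, labels, config)
        perm = rng.permutation(len(fms))
        b = fit([fms[i] for i in perm], [labels[i] for i in perm], config)
        np.testing.assert_array_equal(a.params.W, b.params.W)

    def test_single_label_cohort_rejected(self, small_separable):
        fms, _, _ = small_separable
        with pytest.raises(FittingError):
            fit(fms, [1] * len(fms), FitConfig(n_restarts=1, n_iterations=5))

    def test_engines_agree(self, small_separable):
        fms, labels, _ = small_separable
        base = dict(n_restarts=4, n_iterations=150, seed=5)
        dense = fit(fms, labels, FitConfig(engine="dense", **base))
        cat = fit(fms, labels, FitConfig(engine="categorical", **base))
        np.testing.assert_allclose(cat.params.W, dense.params.W, atol=2e-4)
        assert cat.train_nll == pytest.approx(dense.train_nll, rel=1e-3, abs=1e-4)

    def test_engine_matches_float64_reference_loop(self, small_separable):
        """One restart of the float32 engine against the reference Adam path."""
        fms, labels, _ = small_separable
        config = FitConfig(n_restarts=1, n_iterations=40, seed=9, engine="dense")
        result = fit(fms, labels, config)

        from maxsnippet.model import _init_weights

        order = sorted(range(len(fms)), key=lambda i: fms[i].patient_id)
        fms_sorted = [fms[i] for i in order]
        labels_sorted = [labels[i] for i in order]
        W0 = _init_weights(config, (), fms[0].X.shape[1])[0].astype(np.float64)
        state = AdamState.initialize(W0)
        for _ in range(config.n_iterations):
            params = DetectorParams(state.theta[0], state.theta[1:])
            db0, dW = nll_gradient(params, fms_sorted, labels_sorted)
            state = adam_step(state, np.concatenate([[db0], dW]), config)
        np.testing.assert_allclose(result.params.W, state.theta[1:], atol=5e-4)
        ref_nll = negative_log_likelihood(
            DetectorParams(state.theta[0], state.theta[1:]), fms_sorted, labels_sorted
        )
        assert result.train_nll == pytest.approx(ref_nll, rel=1e-3, abs=1e-3)

    def test_l2_shrinks_weights(self, small_separable):
        fms, labels, _ = small_separable
        base = dict(n_restarts=2, n_iterations=150, seed=5)
        free = fit(fms, labels, FitConfig(**base))
        reg = fit(fms, labels, FitConfig(l2=1.0, **base))
        assert np.linalg.norm(reg.params.W) < np.linalg.norm(free.params.W)

    def test_early_stopping_runs(self, small_separable):
        fms, labels, _ = small_separable
        config = FitConfig(
            n_restarts=2,
            n_iterations=200,
            seed=5,
            early_stopping=EarlyStoppingConfig(holdout_fraction=0.25, patience=2, check_every=10),
        )
        result = fit(fms, labels, config)
        assert np.isfinite(result.train_nll)


class TestPredict:
    def test_low_logits_negative(self):
        params = DetectorParams(-10.0, np.zeros(2))
        pred = predict(params, _fm(np.zeros((3, 2))))
        assert pred.diagnosis == "negative"
        assert pred.probability == pytest.approx(4.5398e-5, rel=1e-3)

    def test_one_high_logit_positive(self):
        params = DetectorParams(0.0, np.array([10.0]))
        pred = predict(params, _fm([[0.0], [1.0], [0.0]]))
        assert pred.diagnosis == "positive"
        assert pred.argmax_snippet.offset == 1

    def test_exact_half_is_negative_and_flagged(self):
        params = DetectorParams(0.0, np.zeros(2))
        pred = predict(params, _fm(np.zeros((4, 2))))
        assert pred.probability == 0.5
        assert pred.diagnosis == "negative"
        assert pred.boundary_flag

    def test_probability_equals_argmax_score(self, small_separable, tiny_fit):
        fms, _, _ = small_separable
        pred = predict(tiny_fit.params, fms[0])
        assert pred.probability == pred.argmax_score


class TestBagging:
    def test_bagging_one_equals_plain_fit(self, small_separable):
        fms, labels, _ = small_separable
        config = FitConfig(n_restarts=2, n_iterations=50, seed=5, bagging=1)
        [member] = bagged_fit(fms, labels, config)
        plain = fit(fms, labels, FitConfig(n_restarts=2, n_iterations=50, seed=5))
        np.testing.assert_array_equal(member.params.W, plain.params.W)

    def test_ensemble_probability_within_member_range(self, small_separable):
        fms, labels, _ = small_separable
        config = FitConfig(n_restarts=2, n_iterations=60, seed=5, bagging=3)
        members = bagged_fit(fms, labels, config)
        for fm in fms[:3]:
            probs = [predict(m.params, fm).probability for m in members]
            ens = bagged_predict(members, fm)
            assert min(probs) <= ens.probability <= max(probs)

    def test_identical_members_give_member_probability(self, small_separable, tiny_fit):
        fms, _, _ = small_separable
        ens = bagged_predict([tiny_fit, tiny_fit], fms[0])
        assert ens.probability == predict(tiny_fit.params, fms[0]).probability


class TestSerialization:
    def test_round_trip_predicts_identically(self, small_separable, tiny_fit, tmp_path):
        fms, _, _ = small_separable
        enc = FeatureEncoding("atchley", 6)
        path = tmp_path / "model.json"
        save_model(path, tiny_fit.params, enc, tiny_fit.config, tiny_fit.train_nll)
        params, enc2, meta = load_model(path)
        assert enc2 == enc
        assert meta["train_nll"] == pytest.approx(tiny_fit.train_nll)
        for fm in fms[:2]:
            assert predict(params, fm).probability == predict(tiny_fit.params, fm).probability

    def test_fit_config_yaml_round_trip(self, tmp_path):
        config = FitConfig(
            n_restarts=7, n_iterations=123, l2=0.5, seed=42,
            early_stopping=EarlyStoppingConfig(holdout_fraction=0.3, patience=4),
        )
        path = tmp_path / "config.yaml"
        config.to_file(path)
        assert FitConfig.from_file(path) == config

    def test_checksum_mismatch_refused(self, tiny_fit, tmp_path):
        path = tmp_path / "model.json"
        save_model(path, tiny_fit.params, FeatureEncoding("atchley", 6))
        payload = json.loads(path.read_text())
        payload["atchley_table_checksum"] = "0" * 64
        path.write_text(json.dumps(payload))
        with pytest.raises(ChecksumError):
            load_model(path)
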