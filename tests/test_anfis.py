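import json
import math

import numpy as np
import pytest

from braintex import (
    AnfisModel,
    DataError,
    FuzzyRule,
    MembershipFunction,
    ModelSchemaError,
    fuzzify,
    initialize_from_data,
    load_model,
    loss,
    make_feature_clusters,
    membership,
    predict,
    predict_batch,
    predict_scores,
    rule_strengths,
    save_model,
    train,
)
from braintex.anfis import _loss_and_grads, _one_hot, dataset_loss


def tiny_model(n_classes=2):
    """2 features, 2 membership functions each, 2 rules."""
    classes = ("normal", "benign", "malignant")[:n_classes]
    return AnfisModel(
        feature_names=("f0", "f1"),
        classes=classes,
        mfs_per_feature=(
            (MembershipFunction(-1.0, 0.8), MembershipFunction(1.0, 0.6)),
            (MembershipFunction(-0.5, 1.2), MembershipFunction(0.7, 0.9)),
        ),
        rules=(
            FuzzyRule((0, 0), tuple([1.0] + [0.0] * (n_classes - 1))),
            FuzzyRule((1, 1), tuple([0.0] * (n_classes - 1) + [1.0])),
        ),
        feature_means=(0.0, 0.0),
        feature_stds=(1.0, 1.0),
    )


class TestMembership:
    def test_center_gives_one(self):
        assert membership(2.0, MembershipFunction(2.0, 0.5)) == 1.0

    def test_one_sigma_closed_form(self):
        mf = MembershipFunction(1.0, 0.3)
        assert membership(1.3, mf) == pytest.approx(math.exp(-0.5))

    def test_even_symmetry(self):
        mf = MembershipFunction(0.4, 0.7)
        assert membership(0.4 + 0.9, mf) == pytest.approx(membership(0.4 - 0.9, mf))

    def test_non_finite_rejected(self):
        with pytest.raises(DataError):
            membership(float("nan"), MembershipFunction(0.0, 1.0))

    def test_zero_width_rejected(self):
        with pytest.raises(DataError):
            MembershipFunction(0.0, 0.0)


class TestFuzzifyAndRules:
    def test_degrees_match_membership_calls(self):
        m = tiny_model()
        degrees = fuzzify([0.3, -0.2], m)
        assert len(degrees) == 2 and degrees[0].shape == (2,)
        for f, x in enumerate([0.3, -0.2]):
            for j, mf in enumerate(m.mfs_per_feature[f]):
                assert degrees[f][j] == pytest.approx(membership(x, mf))

    def test_at_centers_all_one(self):
        m = tiny_model()
        degrees = fuzzify([-1.0, -0.5], m)
        assert degrees[0][0] == 1.0 and degrees[1][0] == 1.0

    def test_strengths_equal_products(self):
        m = tiny_model()
        degrees = fuzzify([0.1, 0.2], m)
        w, wbar = rule_strengths(degrees, m)
        for r, rule in enumerate(m.rules):
            expected = np.prod([degrees[f][j] for f, j in enumerate(rule.antecedent)])
            assert w[r] == pytest.approx(expected)
        assert wbar.sum() == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            fuzzify([0.1], tiny_model())


class TestPredict:
    def test_single_rule_scores_its_consequent(self):
        m = AnfisModel(
            feature_names=("f0",),
            classes=("normal", "benign", "malignant"),
            mfs_per_feature=((MembershipFunction(0.0, 1.0),),),
            rules=(FuzzyRule((0,), (1.0, 0.0, 0.0)),),
            feature_means=(0.0,),
            feature_stds=(1.0,),
        )
        assert np.allclose(predict_scores([5.0], m), [1.0, 0.0, 0.0])
        assert predict([5.0], m) == "normal"

    def test_scores_are_convex_combinations(self):
        m = tiny_model(3)
        scores = predict_scores([0.4, -0.1], m)
        Y = np.array([r.consequent for r in m.rules])
        assert (scores >= Y.min(axis=0) - 1e-12).all()
        assert (scores <= Y.max(axis=0) + 1e-12).all()

    def test_tie_breaks_toward_earlier_class(self):
        m = tiny_model(3)
        # symmetric input between equal consequents -> argmax picks first max
        scores = np.array([0.4, 0.4, 0.2])
        assert m.classes[int(np.argmax(scores))] == "normal"

    def test_matches_double_loop_oracle(self):
        m = tiny_model(3)
        x = [0.25, -0.75]
        degrees = fuzzify(x, m)
        w, wbar = rule_strengths(degrees, m)
        oracle = np.zeros(3)
        for r, rule in enumerate(m.rules):
            for c in range(3):
                oracle[c] += wbar[r] * rule.consequent[c]
        assert np.allclose(predict_scores(x, m), oracle)


class TestLoss:
    def test_exact_match_zero(self):
        assert loss([0.0, 1.0, 0.0], [0.0, 1.0, 0.0]) == 0.0

    def test_unit_example(self):
        assert loss([1.0, 0.0, 0.0], [0.0, 1.0, 0.0]) == pytest.approx(2.0)

    def test_matches_brute_force(self, rng):
        s, t, q = rng.normal(size=3), rng.normal(size=3), rng.uniform(0.5, 2, 3)
        expected = sum(q[c] * (s[c] - t[c]) ** 2 for c in range(3))
        assert loss(s, t, q) == pytest.approx(expected)


class TestGradients:
    def test_analytic_matches_central_differences(self, rng):
        m = tiny_model()
        X = rng.normal(size=(6, 2))
        labels = ["normal" if i % 2 else "benign" for i in range(6)]
        Z = m.standardize(X)
        T = _one_hot(labels, m.classes)
        C, S, A, Y = m._arrays()
        q = np.ones(2)
        _, gC, gS, gY = _loss_and_grads(Z, T, C, S, A, Y, q)
        eps = 1e-6

        def numeric(which, arr, idx):
            hi, lo = arr.copy(), arr.copy()
            hi[idx] += eps
            lo[idx] -= eps
            args_hi = {"C": C, "S": S, "Y": Y, which: hi}
            args_lo = {"C": C, "S": S, "Y": Y, which: lo}
            th, *_ = _loss_and_grads(Z, T, args_hi["C"], args_hi["S"], A, args_hi["Y"], q)
            tl, *_ = _loss_and_grads(Z, T, args_lo["C"], args_lo["S"], A, args_lo["Y"], q)
            return (th - tl) / (2 * eps)

        for which, arr, grad in (("C", C, gC), ("S", S, gS), ("Y", Y, gY)):
            for idx in np.ndindex(arr.shape):
                num = numeric(which, arr, idx)
                denom = max(abs(num), abs(grad[idx]), 1e-8)
                assert abs(num - grad[idx]) / denom < 1e-5

    def test_zero_momentum_step_is_plain_gradient_descent(self, rng):
        m = tiny_model()
        X = rng.normal(size=(5, 2))
        labels = ["normal", "benign", "normal", "benign", "normal"]
        Z = m.standardize(X)
        T = _one_hot(labels, m.classes)
        C, S, A, Y = m._arrays()
        _, gC, gS, gY = _loss_and_grads(Z, T, C, S, A, Y, np.ones(2))
        eta = 0.01
        trained, _ = train(m, list(zip(X, labels)), epochs=1, learning_rate=eta, momentum=0.0)
        C2, S2, A2, Y2 = trained._arrays()
        assert np.allclose(C2, C - eta * gC)
        assert np.allclose(S2, np.maximum(S - eta * gS, 1e-3))
        assert np.allclose(Y2, Y - eta * gY)


class TestTraining:
    def test_self_generated_data_loss_non_increasing(self, rng):
        m = tiny_model()
        X = rng.normal(size=(20, 2))
        labels = [predict(x, m) for x in X]
        ds = list(zip(X, labels))
        _, trace = train(m, ds, epochs=50)
        assert trace.errors[-1] <= trace.errors[0]
        assert all(e >= 0 for e in trace.errors)

    def test_separated_clusters_high_accuracy(self):
        data = make_feature_clusters(50, separation=10.0, seed=1)
        model = initialize_from_data(data, mfs_per_feature=2, seed=1)
        model, trace = train(model, data, epochs=200)
        X = np.array([x for x, _ in data])
        labels = [lab for _, lab in data]
        preds = predict_batch(X, model)
        assert np.mean([p == t for p, t in zip(preds, labels)]) >= 0.95

    def test_parameter_recovery_up_to_permutation(self):
        gen = AnfisModel(
            feature_names=("f0",),
            classes=("normal", "benign"),
            mfs_per_feature=((MembershipFunction(-2.0, 0.8), MembershipFunction(2.0, 0.8)),),
            rules=(FuzzyRule((0,), (1.0, 0.0)), FuzzyRule((1,), (0.0, 1.0))),
            feature_means=(0.0,),
            feature_stds=(1.0,),
        )
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(-2, 0.5, 100), rng.normal(2, 0.5, 100)])
        ds = [([v], predict([v], gen)) for v in x]
        m = initialize_from_data(ds, mfs_per_feature=2, seed=0,
                                 classes=("normal", "benign"), feature_names=("f0",))
        m, _ = train(m, ds, epochs=200)
        mu, sd = m.feature_means[0], m.feature_stds[0]
        recovered = sorted(mu + sd * mf.center for mf in m.mfs_per_feature[0])
        assert recovered[0] == pytest.approx(-2.0, abs=0.3)
        assert recovered[1] == pytest.approx(2.0, abs=0.3)

    def test_deterministic_under_fixed_seed(self, tmp_path):
        data = make_feature_clusters(10, separation=5.0, seed=3)
        runs = []
        for i in range(2):
            m = initialize_from_data(data, mfs_per_feature=2, seed=3)
            m, _ = train(m, data, epochs=20, seed=3)
            save_model(m, tmp_path / f"m{i}.json")
            runs.append((tmp_path / f"m{i}.json").read_bytes())
        assert runs[0] == runs[1]

    def test_empty_dataset_rejected(self):
        with pytest.raises(DataError):
            train(tiny_model(), [], epochs=1)

    def test_loss_decreases_on_dataset_metric(self, rng):
        data = make_feature_clusters(20, separation=6.0, seed=2)
        m0 = initialize_from_data(data, mfs_per_feature=2, seed=2)
        X = np.array([x for x, _ in data])
        labels = [lab for _, lab in data]
        m1, _ = train(m0, data, epochs=100)
        assert dataset_loss(m1, X, labels) < dataset_loss(m0, X, labels)


class TestInitialization:
    def test_quantile_centers_for_uniform_data(self, rng):
        x = rng.uniform(0, 1, 500)
        ds = [([v], "normal" if v < 0.5 else "benign") for v in x]
        m = initialize_from_data(ds, mfs_per_feature=2, seed=0,
                                 classes=("normal", "benign"), feature_names=("f0",))
        mu, sd = m.feature_means[0], m.feature_stds[0]
        raw_centers = sorted(mu + sd * mf.center for mf in m.mfs_per_feature[0])
        assert raw_centers[0] == pytest.approx(np.quantile(x, 1 / 3), abs=0.05)
        assert raw_centers[1] == pytest.approx(np.quantile(x, 2 / 3), abs=0.05)

    def test_all_widths_positive(self):
        data = make_feature_clusters(10, separation=3.0, seed=0)
        m = initialize_from_data(data, mfs_per_feature=2, seed=0)
        assert all(mf.width > 0 for mfs in m.mfs_per_feature for mf in mfs)

    def test_invalid_mf_count(self):
        with pytest.raises(DataError):
            initialize_from_data([([0.0], "normal")], mfs_per_feature=0)

    def test_grid_used_for_few_features(self):
        ds = [(np.random.default_rng(i).normal(size=2), "normal") for i in range(10)]
        m = initialize_from_data(ds, mfs_per_feature=2, seed=0, feature_names=("a", "b"))
        assert len(m.rules) == 4  # 2^2 grid

    def test_class_median_rules_for_many_features(self):
        data = make_feature_clusters(5, separation=4.0, seed=0)
        m = initialize_from_data(data, mfs_per_feature=2, seed=0)
        assert len(m.rules) == 3
        for c, rule in enumerate(m.rules):
            assert rule.consequent[c] == 1.0


class TestSerialization:
    def test_round_trip_bit_identical_predictions(self, tmp_path, rng):
        data = make_feature_clusters(10, separation=5.0, seed=4)
        m = initialize_from_data(data, mfs_per_feature=2, seed=4)
        m, _ = train(m, data, epochs=30)
        save_model(m, tmp_path / "m.json")
        m2 = load_model(tmp_path / "m.json")
        X = rng.normal(size=(20, 14)) * 3
        s1 = [predict_scores(x, m) for x in X]
        s2 = [predict_scores(x, m2) for x in X]
        assert all(np.array_equal(a, b) for a, b in zip(s1, s2))

    def test_version_tag_present(self, tmp_path):
        save_model(tiny_model(), tmp_path / "m.json")
        doc = json.loads((tmp_path / "m.json").read_text())
        assert doc["schema_version"] == 1

    def test_missing_field_raises_schema_error(self, tmp_path):
        save_model(tiny_model(), tmp_path / "m.json")
        doc = json.loads((tmp_path / "m.json").read_text())
        del doc["rules"]
        (tmp_path / "bad.json").write_text(json.dumps(doc))
        with pytest.raises(ModelSchemaError):
            load_model(tmp_path / "bad.json")
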