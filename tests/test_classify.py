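import numpy as np
import pytest

from gazeseg import (
    CLASSES,
    ClassModel,
    build_transition_model,
    classify_samples,
    extract_features,
    fit_class_distributions,
    majority_label,
    viterbi_classify,
)
from gazeseg.classify import COV_RIDGE, EPS_COS
from gazeseg.segment import Segmentation

from reference import brute_force_viterbi


def _segmentation_from_nodes(node_times, node_values, breakpoints, n_samples):
    return Segmentation(np.asarray(breakpoints), np.asarray(node_times, float),
                        np.asarray(node_values, float), n_samples)


def _random_model(rng, k=4):
    classes = CLASSES[:k]
    T, initial = build_transition_model(classes)
    mean = rng.normal(0, 3, (k, 2))
    cov = np.array([np.diag(rng.uniform(0.5, 2, 2)) for _ in range(k)])
    return ClassModel(classes, mean, cov, T, initial)


class TestExtractFeatures:
    def test_three_four_five_triangle(self):
        seg = _segmentation_from_nodes([0, 1], [[0, 0], [3, 4]], [0], 10)
        f = extract_features(seg)
        assert f[0, 0] == pytest.approx(np.log(5.0))
        assert f[0, 1] == 0.0  # first segment: neutral angle

    def test_perpendicular_directions_give_zero(self):
        seg = _segmentation_from_nodes([0, 1, 2], [[0, 0], [1, 0], [1, 1]], [0, 5], 10)
        f = extract_features(seg)
        assert f[1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_reversal_hits_clamp(self):
        seg = _segmentation_from_nodes([0, 1, 2], [[0, 0], [2, 0], [0, 0]], [0, 5], 10)
        f = extract_features(seg)
        assert f[1, 1] == pytest.approx(np.arctanh(-1 + EPS_COS))

    def test_speed_clamp_for_stationary_segment(self):
        seg = _segmentation_from_nodes([0, 1], [[2, 2], [2, 2]], [0], 4)
        f = extract_features(seg)
        assert np.isfinite(f[0, 0])
        assert f[0, 0] == pytest.approx(np.log(1e-3))


class TestFitClassDistributions:
    def test_degenerate_spread_regularized(self):
        feats = np.array([[1.0, 2.0]] * 5 + [[0.0, 0.0], [0.1, 0.1], [0.2, -0.1]])
        labels = ["saccade"] * 5 + ["fixation"] * 3
        model = fit_class_distributions(feats, labels)
        i = model.classes.index("saccade")
        np.testing.assert_allclose(model.mean[i], [1.0, 2.0])
        np.testing.assert_allclose(model.cov[i], COV_RIDGE * np.eye(2))

    def test_parameter_recovery_from_clusters(self):
        rng = np.random.default_rng(0)
        mu_f, mu_s = np.array([0.0, 0.0]), np.array([5.0, -1.0])
        n = 400
        feats = np.vstack([rng.normal(mu_f, 0.5, (n, 2)), rng.normal(mu_s, 0.5, (n, 2))])
        labels = ["fixation"] * n + ["saccade"] * n
        model = fit_class_distributions(feats, labels)
        se = 0.5 / np.sqrt(n)
        for cls, mu in (("fixation", mu_f), ("saccade", mu_s)):
            i = model.classes.index(cls)
            assert np.all(np.abs(model.mean[i] - mu) < 3 * se)

    def test_permutation_invariance(self, rng):
        feats = rng.normal(0, 1, (30, 2))
        labels = (["fixation"] * 10 + ["saccade"] * 10 + ["pursuit"] * 10)
        m1 = fit_class_distributions(feats, labels)
        perm = rng.permutation(30)
        m2 = fit_class_distributions(feats[perm], [labels[i] for i in perm])
        np.testing.assert_allclose(m1.mean, m2.mean)
        np.testing.assert_allclose(m1.cov, m2.cov)

    def test_too_few_segments_errors_naming_class(self):
        feats = np.zeros((4, 2))
        labels = ["fixation", "fixation", "fixation", "pso"]
        with pytest.raises(ValueError, match="pso"):
            fit_class_distributions(feats, labels)

    def test_round_trip_serialization(self, rng, tmp_path):
        model = _random_model(rng)
        path = tmp_path / "model.json"
        model.save(path)
        back = ClassModel.load(path)
        assert back.classes == model.classes
        np.testing.assert_allclose(back.mean, model.mean)
        np.testing.assert_allclose(back.transitions, model.transitions)


class TestMajorityLabel:
    def _seg(self, n=10):
        return _segmentation_from_nodes([0, 1], [[0, 0], [1, 1]], [0], n)

    def test_simple_majority(self):
        labels = np.array(["saccade"] * 7 + ["fixation"] * 3, dtype=object)
        assert majority_label(self._seg(), labels) == ["saccade"]

    def test_outlier_majority_excluded(self):
        labels = np.array(["blink"] * 6 + ["saccade"] * 4, dtype=object)
        assert majority_label(self._seg(), labels) == [None]

    def test_tie_breaks_to_canonical_order(self):
        labels = np.array(["pursuit"] * 5 + ["fixation"] * 5, dtype=object)
        assert majority_label(self._seg(), labels) == ["fixation"]

    def test_multi_segment_assignment(self):
        seg = _segmentation_from_nodes([0, 1, 2], [[0, 0], [1, 1], [2, 2]], [0, 5], 10)
        labels = np.array(["fixation"] * 5 + ["saccade"] * 5, dtype=object)
        assert majority_label(seg, labels) == ["fixation", "saccade"]


class TestTransitionModel:
    def test_rows_stochastic_and_initial_uniform(self):
        T, initial = build_transition_model()
        np.testing.assert_allclose(T.sum(axis=1), 1.0)
        np.testing.assert_allclose(initial, 0.25)

    def test_pso_structure(self):
        T, _ = build_transition_model()
        i = {c: k for k, c in enumerate(CLASSES)}
        assert T[i["fixation"], i["pso"]] == 0.0
        assert T[i["pursuit"], i["pso"]] == 0.0
        assert T[i["pso"], i["saccade"]] == 0.0
        assert T[i["saccade"], i["pso"]] == pytest.approx(0.25)
        assert T[i["pso"], i["pso"]] == pytest.approx(1 / 3)

    def test_cross_class_half_of_within_class(self):
        T, _ = build_transition_model()
        i = {c: k for k, c in enumerate(CLASSES)}
        assert T[i["fixation"], i["pursuit"]] / T[i["fixation"], i["fixation"]] == pytest.approx(0.5)
        assert T[i["pursuit"], i["fixation"]] / T[i["pursuit"], i["pursuit"]] == pytest.approx(0.5)
        assert T[i["fixation"], i["fixation"]] == pytest.approx(2 / 5)
        assert T[i["fixation"], i["pursuit"]] == pytest.approx(1 / 5)


class TestViterbi:
    def test_matches_brute_force(self, rng):
        for _ in range(60):
            model = _random_model(rng)
            m = int(rng.integers(1, 8))
            feats = rng.normal(0, 3, (m, 2))
            path, ll = viterbi_classify(feats, model)
            bpath, bll = brute_force_viterbi(feats, model)
            assert path == bpath
            assert ll == pytest.approx(bll, rel=1e-10)

    def test_identical_emissions_tie_breaks_canonically(self):
        T, initial = build_transition_model()
        mean = np.zeros((4, 2))
        cov = np.array([np.eye(2)] * 4)
        model = ClassModel(CLASSES, mean, cov, T, initial)
        path, _ = viterbi_classify(np.array([[0.3, -0.2]]), model)
        assert path == ["fixation"]

    def test_forbidden_transitions_never_decoded(self, rng):
        model = _random_model(rng)
        for _ in range(50):
            m = int(rng.integers(2, 20))
            feats = rng.normal(0, 3, (m, 2))
            path, _ = viterbi_classify(feats, model)
            for a, b in zip(path, path[1:]):
                assert not (b == "pso" and a not in ("saccade", "pso"))
                assert not (a == "pso" and b == "saccade")

    def test_separable_high_speed_segment_is_saccade(self, rng):
        n = 50
        feats = np.vstack([
            rng.normal([0.0, 0.0], 0.3, (n, 2)),
            rng.normal([5.5, 0.0], 0.3, (n, 2)),
        ])
        labels = ["fixation"] * n + ["saccade"] * n
        model = fit_class_distributions(feats, labels)
        test = np.array([[0.1, 0.0], [5.4, 0.1], [-0.1, 0.2]])
        path, _ = viterbi_classify(test, model)
        assert path == ["fixation", "saccade", "fixation"]


class TestClassifySamples:
    def test_half_open_assignment(self):
        seg = _segmentation_from_nodes([0, 1, 2], [[0, 0], [1, 1], [2, 2]], [0, 5], 10)
        out = classify_samples(seg, ["fixation", "saccade"])
        assert list(out[:5]) == ["fixation"] * 5
        assert list(out[5:]) == ["saccade"] * 5
        assert len(out) == seg.n_samples

    def test_single_segment(self):
        seg = _segmentation_from_nodes([0, 1], [[0, 0], [1, 1]], [0], 7)
        out = classify_samples(seg, ["pursuit"])
        assert set(out) == {"pursuit"}
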