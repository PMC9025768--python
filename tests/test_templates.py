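"""Template-builder tests: silhouette vs brute force, K selection,
centroid-distance ranking, template averaging and typing rules."""

import numpy as np
import pytest

from pvckit.preprocess import BeatWindow, window_pre_samples, window_total_samples
from pvckit.synthetic import make_beat_morphology, r_offset_samples
from pvckit.templates import (RuleConfig, Template, build_template,
                              build_typed_templates, classify_template,
                              qrs_features, rank_by_centroid_distance,
                              select_k_and_cluster, silhouette_coefficient)


def brute_force_silhouette(X, labels):
    """Direct double-loop transcription of the silhouette definition."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j])
                     for j in range(n) if labels[j] == lab])
            for lab in set(labels) if lab != labels[i]
        )
        denom = max(a, b)
        vals.append((b - a) / denom if denom > 0 else 0.0)
    return float(np.mean(vals))


class TestSilhouette:
    def test_two_tight_separated_clusters(self):
        X = np.array([0.0, 0.1, 10.0, 10.1])
        labels = [0, 0, 1, 1]
        sc = silhouette_coefficient(X, labels)
        assert sc > 0.97
        assert sc == pytest.approx(brute_force_silhouette(X, labels), abs=1e-12)

    def test_coincident_points_zero_by_convention(self):
        X = np.zeros(6)
        assert silhouette_coefficient(X, [0, 0, 0, 1, 1, 1]) == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_coefficient(np.arange(4.0), [0, 0, 0, 0])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 13)
            d = rng.integers(1, 4)
            X = rng.normal(size=(n, d))
            k = rng.integers(2, min(4, n) + 1)
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2:
                labels[0] = (labels[0] + 1) % k
            assert silhouette_coefficient(X, labels) == pytest.approx(
                brute_force_silhouette(X, labels), abs=1e-12)


class TestKSelection:
    @pytest.mark.parametrize("k_true", [2, 3])
    def test_recovers_blob_count(self, k_true):
        rng = np.random.default_rng(k_true)
        X = np.concatenate([rng.normal(8 * j, 0.5, size=(50, 4))
                            for j in range(k_true)])
        cl = select_k_and_cluster(X, seed=0)
        assert cl.k == k_true
        assert sorted(cl.sizes) == [50] * k_true

    def test_two_points_force_k2(self):
        cl = select_k_and_cluster(np.array([[0.0], [5.0]]), k_min=2, k_max=8)
        assert cl.k == 2

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            select_k_and_cluster(np.array([[1.0]]))

    def test_deterministic_with_fixed_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 8))
        c1 = select_k_and_cluster(X, seed=3)
        c2 = select_k_and_cluster(X, seed=3)
        assert c1.k == c2.k
        np.testing.assert_array_equal(c1.labels, c2.labels)


class TestRanking:
    def test_hand_example_with_stable_tie(self):
        emb = np.array([5.0, 1.0, 3.0])
        order = rank_by_centroid_distance([0, 1, 2], emb, 3.0)
        # distances: 4, 4, 0 -> member at value 3 first, then tie broken by
        # original order (value 5 before value 1)
        assert list(order) == [2, 0, 1]

    def test_single_member(self):
        assert list(rank_by_centroid_distance([4], np.zeros((5, 2)),
                                              [0, 0])) == [4]

    def test_equidistant_preserves_order(self):
        emb = np.array([[1.0], [-1.0], [1.0]])
        assert list(rank_by_centroid_distance([0, 1, 2], emb, [0.0])) == [0, 1, 2]


def _beats_from(kind, fs, n):
    wave = make_beat_morphology(kind, fs)
    r = r_offset_samples(fs)
    n_pre, total = window_pre_samples(fs), window_total_samples(fs)
    hw = wave[r - n_pre: r - n_pre + total]
    return [BeatWindow(1000 + i, hw.copy(), n_pre, total - n_pre)
            for i in range(n)]


class TestBuildTemplate:
    def test_mean_of_identical_beats_is_the_beat(self):
        beats = _beats_from("normal", 250, 30)
        tpl = build_template(np.arange(30), beats)
        np.testing.assert_allclose(tpl.tw, beats[0].hw)
        assert tpl.member_count == 30

    def test_pointwise_mean(self):
        b1 = BeatWindow(10, [0.0, 2.0], 1, 1)
        b2 = BeatWindow(20, [2.0, 0.0], 1, 1)
        tpl = build_template([0, 1], [b1, b2])
        np.testing.assert_allclose(tpl.tw, [1.0, 1.0])

    def test_small_cluster_uses_all_members(self):
        beats = _beats_from("normal", 250, 12)
        tpl = build_template(np.arange(12), beats)
        assert tpl.member_count == 12

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            build_template([], [])


class TestTemplateTyping:
    @pytest.fixture
    def fs(self):
        return 250.0

    @pytest.fixture
    def dominant(self, fs):
        return Template(tw=_beats_from("normal", fs, 1)[0].hw, type="Non_PVC")

    def test_pvc_morphology_typed_pvc(self, fs, dominant):
        pvc = Template(tw=_beats_from("pvc", fs, 1)[0].hw)
        n_pre = window_pre_samples(fs)
        assert classify_template(pvc, dominant, fs, n_pre) == "PVC"

    def test_dominant_against_itself_is_non_pvc(self, fs, dominant):
        assert classify_template(dominant, dominant, fs,
                                 window_pre_samples(fs)) == "Non_PVC"

    def test_high_correlation_template_is_non_pvc(self, fs, dominant):
        near = Template(tw=dominant.tw * 1.3 + 0.01)  # corr = 1
        assert classify_template(near, dominant, fs,
                                 window_pre_samples(fs)) == "Non_PVC"

    def test_length_mismatch_rejected(self, fs, dominant):
        bad = Template(tw=dominant.tw[:-3])
        with pytest.raises(ValueError):
            classify_template(bad, dominant, fs, window_pre_samples(fs))

    def test_qrs_features_contrast(self, fs, dominant):
        pvc = Template(tw=_beats_from("pvc", fs, 1)[0].hw)
        n_pre = window_pre_samples(fs)
        fn = qrs_features(dominant, dominant, fs, n_pre)
        fp = qrs_features(pvc, dominant, fs, n_pre)
        assert fp.width_ms > 120 > fn.width_ms
        assert fp.height > 1.2 * fn.height
        assert fp.corr_with_dominant < 0.8
        assert fn.corr_with_dominant == pytest.approx(1.0)


class TestTypedTemplateSet:
    def test_one_template_per_cluster_with_single_dominant(self, trained_ae):
        from pvckit.autoencoder import encode
        model, raw, fil, is_pvc = trained_ae
        emb = encode(model, raw)
        cl = select_k_and_cluster(emb, seed=0)
        tpls = build_typed_templates(cl, emb, fil, 250.0)
        assert len(tpls) == cl.k
        assert sum(t.type == "Non_PVC" for t in tpls) >= 1
        # clean segment with >= 5% PVC must yield at least one PVC template
        assert any(t.type == "PVC" for t in tpls)
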