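import numpy as np
import pytest
from oracles import quantize_bruteforce

from odlocate.dictionary_model import (
    DiscPatchClassifier,
    VisualDictionary,
    build_dictionary,
    load_bundle,
    quantize,
    save_bundle,
)


def _histogram_cloud(rng, n, hot_bins, dim=256, noise=0.02):
    """Synthetic normalized histograms concentrated on given bins."""
    X = rng.random((n, dim)) * noise
    for b in hot_bins:
        X[:, b] += 1.0
    return X / X.sum(axis=1, keepdims=True)


@pytest.fixture
def separable_set(rng):
    a = _histogram_cloud(rng, 30, [10, 20])
    b = _histogram_cloud(rng, 30, [200, 210])
    X = np.vstack([a, b])
    y = np.array(["optic_disc"] * 30 + ["non_optic_disc"] * 30)
    return X, y


class TestBuildDictionary:
    def test_recovers_separated_cluster_means(self, rng):
        a = _histogram_cloud(rng, 50, [5], noise=0.001)
        b = _histogram_cloud(rng, 50, [250], noise=0.001)
        d = build_dictionary(np.vstack([a, b]), k=2, seed=0)
        means = np.array([a.mean(0), b.mean(0)])
        for m in means:
            assert min(np.linalg.norm(c - m) for c in d.centroids) < 0.01

    def test_deterministic_under_seed(self, rng):
        X = rng.random((40, 256))
        d1 = build_dictionary(X, k=5, seed=3)
        d2 = build_dictionary(X, k=5, seed=3)
        np.testing.assert_array_equal(d1.centroids, d2.centroids)

    def test_rejects_fewer_features_than_k(self, rng):
        with pytest.raises(ValueError):
            build_dictionary(rng.random((3, 256)), k=8, seed=0)


class TestQuantize:
    def test_centroid_maps_to_itself(self, rng):
        d = build_dictionary(rng.random((20, 256)), k=5, seed=0)
        assert quantize(d.centroids[3], d) == 3

    def test_tie_broken_toward_smaller_index(self):
        c = np.zeros((3, 4))
        c[1, 0] = 1.0
        c[2, 1] = 2.0
        d = VisualDictionary(centroids=c, k=3, seed=0)
        x = np.array([0.5, 0.0, 0.0, 0.0])  # equidistant from words 0 and 1
        assert quantize(x, d) == 0

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 10))
            cents = rng.random((k, 32))
            d = VisualDictionary(centroids=cents, k=k, seed=0)
            x = rng.random(32)
            assert quantize(x, d) == quantize_bruteforce(x, cents)

    def test_dimension_mismatch_rejected(self, rng):
        d = build_dictionary(rng.random((10, 256)), k=3, seed=0)
        with pytest.raises(ValueError):
            quantize(np.zeros(17), d)


class TestDiscPatchClassifier:
    def test_separable_training_set_fits_cleanly(self, separable_set):
        X, y = separable_set
        clf = DiscPatchClassifier(random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.95
        assert clf.disc_probability(X[:1])[0] > 0.5

    def test_probabilities_bounded_and_deterministic(self, separable_set, rng):
        X, y = separable_set
        clf1 = DiscPatchClassifier(random_state=5).fit(X, y)
        clf2 = DiscPatchClassifier(random_state=5).fit(X, y)
        q = rng.random((10, 256))
        q /= q.sum(axis=1, keepdims=True)
        p1, p2 = clf1.disc_probability(q), clf2.disc_probability(q)
        assert ((p1 >= 0) & (p1 <= 1)).all()
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        X = rng.random((10, 256))
        with pytest.raises(ValueError):
            DiscPatchClassifier().fit(X, np.array(["optic_disc"] * 10))

    @pytest.mark.parametrize("mode", ["raw", "word", "both"])
    def test_feature_modes_all_train(self, separable_set, mode):
        X, y = separable_set
        clf = DiscPatchClassifier(feature_mode=mode, random_state=0).fit(X, y)
        assert clf.predict_proba(X).shape == (60, 2)

    def test_sklearn_params_roundtrip(self):
        clf = DiscPatchClassifier(k=4, n_trees=10)
        clf.set_params(**clf.get_params())
        assert clf.get_params()["k"] == 4


class TestBundle:
    def test_roundtrip_preserves_predictions(self, separable_set, tmp_path, rng):
        X, y = separable_set
        clf = DiscPatchClassifier(random_state=1).fit(X, y)
        save_bundle(tmp_path / "m", clf)
        loaded = load_bundle(tmp_path / "m")
        q = rng.random((5, 256))
        q /= q.sum(axis=1, keepdims=True)
        np.testing.assert_array_equal(
            clf.disc_probability(q), loaded.disc_probability(q)
        )
        np.testing.assert_allclose(
            clf.dictionary_.centroids, loaded.dictionary_.centroids
        )

    def test_version_mismatch_refused(self, separable_set, tmp_path):
        import json

        X, y = separable_set
        clf = DiscPatchClassifier(random_state=1).fit(X, y)
        save_bundle(tmp_path / "m", clf)
        manifest = json.loads((tmp_path / "m" / "manifest.json").read_text())
        manifest["format_version"] = 99
        (tmp_path / "m" / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(ValueError, match="version"):
            load_bundle(tmp_path / "m")
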