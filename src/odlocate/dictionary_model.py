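"""Visual dictionary (bag of visual words) and the random-forest patch model.

Training patches are summarized as 256-bin LBP histograms.  A k-means
visual dictionary is built over those histograms; each patch is quantized to
its nearest word by squared Euclidean distance (smallest index on ties).
The random forest is then fit on the patch feature — by default the raw
histogram concatenated with the one-hot word assignment, so both the
quantization and the classifier contribute — and predicts the probability
that a patch shows the optic disc as the forest's soft-vote average.

:class:`DiscPatchClassifier` is the scikit-learn-style estimator that owns
both pieces; the module-level functions mirror the underlying operations
for use as standalone primitives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .texture import LBPHistogram

__all__ = [
    "VisualDictionary",
    "ForestConfig",
    "DiscPatchClassifier",
    "build_dictionary",
    "quantize",
    "train_model",
    "predict",
    "save_bundle",
    "load_bundle",
]

POSITIVE = "optic_disc"
NEGATIVE = "non_optic_disc"

_BUNDLE_VERSION = 1


@dataclass
class VisualDictionary:
    """k centroid vectors in LBP-histogram space (the visual words)."""

    centroids: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=np.float64)
        if self.k < 2:
            raise ValueError("dictionary needs k >= 2")
        if c.shape[0] != self.k:
            raise ValueError(f"expected {self.k} centroids, got {c.shape[0]}")
        if (c < -1e-12).any():
            raise ValueError("centroids must be non-negative")
        self.centroids = np.clip(c, 0.0, None)

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]


@dataclass
class ForestConfig:
    n_trees: int = 100
    feature_mode: str = "both"  # raw | word | both


def _as_matrix(features) -> np.ndarray:
    rows = [
        f.bins if isinstance(f, LBPHistogram) else np.asarray(f, dtype=np.float64)
        for f in features
    ]
    return np.vstack(rows)


def build_dictionary(features, k: int, seed: int) -> VisualDictionary:
    """k-means (k-means++ init, seeded) over LBP-histogram features."""
    X = _as_matrix(features)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} features, got {X.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                random_state=seed)
    km.fit(X)
    return VisualDictionary(centroids=km.cluster_centers_, k=k, seed=seed)


def quantize(x, dictionary: VisualDictionary) -> int:
    """Nearest visual word by squared Euclidean distance; first index on ties."""
    v = x.bins if isinstance(x, LBPHistogram) else np.asarray(x, dtype=np.float64)
    if v.shape != (dictionary.dim,):
        raise ValueError(
            f"feature dimension {v.shape} does not match dictionary ({dictionary.dim},)"
        )
    d = ((dictionary.centroids - v) ** 2).sum(axis=1)
    return int(np.argmin(d))


class DiscPatchClassifier(ClassifierMixin, BaseEstimator):
    """Visual-dictionary + random-forest classifier of image patches.

    Parameters
    ----------
    k : int
        Dictionary size (number of visual words).  Small by default: a
        few dozen training patches cannot support a large vocabulary.
    n_trees : int
        Forest size.
    feature_mode : {"raw", "word", "both"}
        What the forest consumes: the raw 256-bin LBP histogram, the one-hot
        word assignment, or their concatenation (default).
    random_state : int
        Seeds both k-means and the forest.

    Attributes
    ----------
    dictionary_ : VisualDictionary
    forest_ : RandomForestClassifier
    classes_ : ndarray of the two class labels
    """

    def __init__(self, k: int = 8, n_trees: int = 100,
                 feature_mode: str = "both", random_state: int = 0):
        self.k = k
        self.n_trees = n_trees
        self.feature_mode = feature_mode
        self.random_state = random_state

    def fit(self, X, y, dictionary: VisualDictionary | None = None):
        if self.feature_mode not in ("raw", "word", "both"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        X = _as_matrix(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("features and labels differ in length")
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        self.dictionary_ = dictionary or build_dictionary(
            X, self.k, self.random_state
        )
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features="sqrt",
            bootstrap=True,
            random_state=self.random_state,
        )
        self.forest_.fit(self._design(X), y)
        self.classes_ = self.forest_.classes_
        return self

    def _design(self, X: np.ndarray) -> np.ndarray:
        """Forest input per feature_mode: raw histogram, one-hot word, or both."""
        words = np.array([quantize(x, self.dictionary_) for x in X])
        onehot = np.zeros((X.shape[0], self.dictionary_.k))
        onehot[np.arange(X.shape[0]), words] = 1.0
        if self.feature_mode == "raw":
            return X
        if self.feature_mode == "word":
            return onehot
        return np.hstack([X, onehot])

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        X = _as_matrix(X)
        if X.shape[1] != self.dictionary_.dim:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match training "
                f"({self.dictionary_.dim})"
            )
        return self.forest_.predict_proba(self._design(X))

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def disc_probability(self, X) -> np.ndarray:
        """Probability of the optic-disc class for each row of X."""
        proba = self.predict_proba(X)
        idx = int(np.flatnonzero(self.classes_ == POSITIVE)[0])
        return proba[:, idx]


def train_model(train_features, train_labels, dictionary: VisualDictionary,
                cfg: ForestConfig | None = None, seed: int = 0) -> DiscPatchClassifier:
    """Fit the patch classifier on features/labels with a prebuilt dictionary."""
    cfg = cfg or ForestConfig()
    clf = DiscPatchClassifier(
        k=dictionary.k, n_trees=cfg.n_trees,
        feature_mode=cfg.feature_mode, random_state=seed,
    )
    return clf.fit(train_features, train_labels, dictionary=dictionary)


def predict(model: DiscPatchClassifier, feature,
            dictionary: VisualDictionary | None = None) -> float:
    """Probability that a single patch feature is the optic disc."""
    return float(model.disc_probability([feature])[0])


def save_bundle(path, model: DiscPatchClassifier) -> None:
    """Serialize model + dictionary to a versioned directory bundle."""
    check_is_fitted(model, "forest_")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": _BUNDLE_VERSION,
        "k": model.dictionary_.k,
        "seed": model.random_state,
        "n_trees": model.n_trees,
        "feature_mode": model.feature_mode,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    np.savetxt(path / "dictionary.csv", model.dictionary_.centroids, delimiter=",")
    joblib.dump(model.forest_, path / "forest.joblib")


def load_bundle(path) -> DiscPatchClassifier:
    """Load a bundle written by :func:`save_bundle`; refuses other versions."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    version = manifest.get("format_version")
    if version != _BUNDLE_VERSION:
        raise ValueError(
            f"bundle format version {version!r} not supported "
            f"(expected {_BUNDLE_VERSION})"
        )
    centroids = np.loadtxt(path / "dictionary.csv", delimiter=",", ndmin=2)
    model = DiscPatchClassifier(
        k=manifest["k"], n_trees=manifest["n_trees"],
        feature_mode=manifest["feature_mode"], random_state=manifest["seed"],
    )
    model.dictionary_ = VisualDictionary(
        centroids=centroids, k=manifest["k"], seed=manifest["seed"]
    )
    model.forest_ = joblib.load(path / "forest.joblib")
    model.classes_ = model.forest_.classes_
    return model
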