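"""Anomaly detector battery: native scorers, an adapter contract, and AUROC.

Native scorers (simple, deterministic, oracle-verifiable):

``knn``   mean Euclidean distance to the k nearest *other* profile rows;
``hist``  histogram-based score: per dimension an equal-width histogram over
          the observed range, per-sample density = bin count / n, score is
          the summed negative log density (independence across dimensions);
``ecdf``  parameter-free ECDF-tail score: per dimension the smaller of the
          left tail P(X <= z) and right tail P(X >= z) under the empirical
          CDF, aggregated as a summed negative log tail.

Everything else (LOF, IsolationForest, OCSVM, ...) attaches through the
adapter contract: fit on the full profile matrix, return one real score per
entity, higher = more anomalous. Detector scores are evaluated against
known-anomaly labels with the exact Mann-Whitney form of the AUROC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.neighbors import NearestNeighbors

from .profiles import ProfileMatrix

logger = logging.getLogger(__name__)

EPS = 1e-12  # guard inside logs (empty bins, out-of-range tails)


class Detector:
    """fit-then-score contract: train on the profile matrix, score rows.

    ``score_training()`` scores the training entities themselves (for kNN
    this excludes self-distance); ``score(X)`` scores arbitrary rows against
    the trained model, which is what the Shapley engine perturbs.
    """

    def fit(self, X: np.ndarray) -> "Detector":
        raise NotImplementedError

    def score(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def score_training(self) -> np.ndarray:
        return self.score(self._X)


class KNNDetector(Detector):
    """Mean Euclidean distance to the k nearest neighbors (standardized profiles)."""

    def __init__(self, k: int = 20):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k

    def fit(self, X: np.ndarray) -> "KNNDetector":
        if self.k >= X.shape[0]:
            raise ValueError(f"k={self.k} must be < n_entities={X.shape[0]}")
        self._X = np.asarray(X, dtype=float)
        self._nn = NearestNeighbors(n_neighbors=self.k, algorithm="auto").fit(self._X)
        return self

    def score(self, X: np.ndarray) -> np.ndarray:
        dist, _ = self._nn.kneighbors(np.atleast_2d(X), n_neighbors=self.k)
        return dist.mean(axis=1)

    def score_training(self) -> np.ndarray:
        # k+1 neighbors, drop the zero self-distance column
        dist, _ = self._nn.kneighbors(self._X, n_neighbors=self.k + 1)
        return dist[:, 1:].mean(axis=1)


class HistogramDetector(Detector):
    """Summed negative log of per-dimension histogram densities (HBOS-style)."""

    def __init__(self, n_bins: int = 10):
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        self.n_bins = n_bins

    def fit(self, X: np.ndarray) -> "HistogramDetector":
        X = np.asarray(X, dtype=float)
        self._X = X
        self._n = X.shape[0]
        self._lo = X.min(axis=0)
        self._hi = X.max(axis=0)
        self._active = self._hi > self._lo  # zero-range dims contribute 0
        self._counts = np.zeros((X.shape[1], self.n_bins))
        for d in np.flatnonzero(self._active):
            self._counts[d] = np.histogram(
                X[:, d], bins=self.n_bins, range=(self._lo[d], self._hi[d])
            )[0]
        return self

    def _bin_index(self, x: np.ndarray, d: int) -> np.ndarray:
        width = (self._hi[d] - self._lo[d]) / self.n_bins
        idx = np.floor((x - self._lo[d]) / width).astype(int)
        return np.clip(idx, -1, self.n_bins)  # out-of-range marked below

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = np.zeros(X.shape[0])
        for d in np.flatnonzero(self._active):
            x = X[:, d]
            in_range = (x >= self._lo[d]) & (x <= self._hi[d])
            idx = np.zeros(X.shape[0], dtype=int)
            idx[in_range] = np.clip(
                self._bin_index(x[in_range], d), 0, self.n_bins - 1
            )
            density = np.where(in_range, self._counts[d][idx] / self._n, 0.0)
            scores += -np.log(density + EPS)
        return scores


class ECDFTailDetector(Detector):
    """Parameter-free tail score from per-dimension empirical CDFs.

    tail_d(z) = min(P(X_d <= z), P(X_d >= z)) over the training sample;
    score = sum_d -log(tail_d). Dimensions where all training values are
    identical contribute 0.
    """

    def fit(self, X: np.ndarray) -> "ECDFTailDetector":
        X = np.asarray(X, dtype=float)
        self._X = X
        self._n = X.shape[0]
        self._sorted = np.sort(X, axis=0)
        self._degenerate = self._sorted[0] == self._sorted[-1]
        return self

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = self._n
        scores = np.zeros(X.shape[0])
        for d in range(X.shape[1]):
            if self._degenerate[d]:
                continue
            col = self._sorted[:, d]
            left = np.searchsorted(col, X[:, d], side="right") / n
            right = (n - np.searchsorted(col, X[:, d], side="left")) / n
            tail = np.maximum(np.minimum(left, right), EPS)
            scores += -np.log(tail)
        return scores


class SklearnAdapter(Detector):
    """Wrap an external estimator under the fit-then-score contract.

    ``score_fn(estimator, X) -> scores`` must return higher-is-more-anomalous
    values; the built-in registry covers scikit-learn's LOF, IsolationForest
    and one-class SVM.
    """

    def __init__(self, make_estimator: Callable, score_fn: Callable,
                 training_score_fn: Optional[Callable] = None):
        self._make = make_estimator
        self._score_fn = score_fn
        self._training_score_fn = training_score_fn

    def fit(self, X: np.ndarray) -> "SklearnAdapter":
        self._X = np.asarray(X, dtype=float)
        self._est = self._make()
        self._est.fit(self._X)
        return self

    def score(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self._score_fn(self._est, np.atleast_2d(X)), dtype=float)

    def score_training(self) -> np.ndarray:
        if self._training_score_fn is not None:
            return np.asarray(self._training_score_fn(self._est), dtype=float)
        return self.score(self._X)


@dataclass(frozen=True)
class DetectorSpec:
    """Declarative detector choice for an ensemble run."""

    name: str
    kind: str = ""  # native_knn | native_hist | native_ecdf_tail | adapter:<id>
    hyperparameters: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self):
        if not self.kind:
            object.__setattr__(self, "kind", _KIND_ALIASES.get(self.name, self.name))


_KIND_ALIASES = {
    "knn": "native_knn",
    "hist": "native_hist",
    "hbos": "native_hist",
    "ecdf": "native_ecdf_tail",
    "lof": "adapter:lof",
    "iforest": "adapter:iforest",
    "ocsvm": "adapter:ocsvm",
}


def make_detector(spec: DetectorSpec) -> Detector:
    hp = dict(spec.hyperparameters)
    kind = spec.kind
    if kind == "native_knn":
        return KNNDetector(k=hp.get("k", 20))
    if kind == "native_hist":
        return HistogramDetector(n_bins=hp.get("n_bins", 10))
    if kind == "native_ecdf_tail":
        return ECDFTailDetector()
    if kind.startswith("adapter:"):
        return _builtin_adapter(kind.split(":", 1)[1], hp, spec.seed)
    raise ValueError(f"unknown detector kind {kind!r}")


def _builtin_adapter(name: str, hp: dict, seed: Optional[int]) -> SklearnAdapter:
    if name == "lof":
        from sklearn.neighbors import LocalOutlierFactor

        nn = hp.get("n_neighbors", 20)
        return SklearnAdapter(
            lambda: LocalOutlierFactor(n_neighbors=nn, novelty=True),
            lambda est, X: -est.score_samples(X),
        )
    if name == "iforest":
        from sklearn.ensemble import IsolationForest

        return SklearnAdapter(
            lambda: IsolationForest(
                n_estimators=hp.get("n_estimators", 100),
                random_state=seed if seed is not None else 0,
            ),
            lambda est, X: -est.score_samples(X),
        )
    if name == "ocsvm":
        from sklearn.svm import OneClassSVM

        return SklearnAdapter(
            lambda: OneClassSVM(nu=hp.get("nu", 0.5), gamma=hp.get("gamma", "scale")),
            lambda est, X: -est.score_samples(X),
        )
    raise ValueError(f"no built-in adapter named {name!r}")


@dataclass
class ScoreMatrix:
    """Per-detector anomaly scores; higher = more anomalous in every column."""

    entity_ids: list[str]
    scores: np.ndarray  # (n_entities, n_detectors)
    detector_names: list[str]

    def __post_init__(self):
        if np.isnan(self.scores).any():
            raise ValueError("scores must not contain NaN")

    def column(self, name: str) -> np.ndarray:
        return self.scores[:, self.detector_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.detector_names)
        df.insert(0, "entity_id", self.entity_ids)
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_ensemble(profiles: ProfileMatrix, specs: list[DetectorSpec]
                 ) -> tuple[ScoreMatrix, dict[str, Detector]]:
    """Fit every detector on the profile matrix and collect per-entity scores.

    A failing adapter drops its column with a logged warning; the run
    continues. Returns the score matrix and the fitted detectors (needed
    later by the explanation engine).
    """
    if not specs:
        raise ValueError("need at least one detector spec")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("detector names must be unique within an ensemble")
    cols, kept, fitted = [], [], {}
    for spec in specs:
        try:
            det = make_detector(spec).fit(profiles.values)
            cols.append(det.score_training())
            kept.append(spec.name)
            fitted[spec.name] = det
        except Exception as exc:  # noqa: BLE001 - adapter isolation by contract
            logger.warning("detector %r failed and was dropped: %s", spec.name, exc)
    if not cols:
        raise RuntimeError("every detector in the ensemble failed")
    return ScoreMatrix(list(profiles.entity_ids), np.column_stack(cols), kept), fitted


def evaluate_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exact AUROC in Mann-Whitney form: the probability that a random
    positive outranks a random negative, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
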