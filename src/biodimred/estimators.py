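"""Custom scikit-learn-compatible estimators used by the preset registry.

Three estimators have no direct scikit-learn equivalent:

* :class:`KernelNaiveBayes` — naive Bayes with a per-feature Gaussian
  kernel density estimate per class (Silverman bandwidth) instead of a
  single Gaussian.
* :class:`RUSBoostClassifier` — multiclass AdaBoost (SAMME) where each
  boosting round trains on a random per-class undersample of size ``N``,
  the member count of the smallest class; the boosting weights drive the
  sampling probabilities.
* :class:`ClippedKNeighborsClassifier` — k-NN whose ``k`` is clipped to
  the training-set size at fit time, so large presets (k=100) remain
  usable on small folds.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "KernelNaiveBayes",
    "RUSBoostClassifier",
    "ClippedKNeighborsClassifier",
    "RegularizedQuadraticDiscriminant",
]


class RegularizedQuadraticDiscriminant(ClassifierMixin, BaseEstimator):
    """Quadratic discriminant with ridge-shrunk class covariances.

    Each class gets a Gaussian with its own covariance
    ``S_c + reg * tr(S_c)/p * I`` — the shrinkage keeps the discriminant
    defined when a class has fewer members than features (the
    pseudo-quadratic variant).  Priors are empirical class frequencies.
    """

    def __init__(self, reg: float = 0.1):
        self.reg = reg

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        p = X.shape[1]
        self.log_priors_ = np.log(counts / counts.sum())
        self.means_, self._precisions, self._logdets = [], [], []
        for c in self.classes_:
            Xc = X[y == c]
            mu = Xc.mean(axis=0)
            S = np.cov(Xc, rowvar=False, bias=False)
            S = np.atleast_2d(S)
            S = S + self.reg * max(np.trace(S) / p, 1e-12) * np.eye(p)
            sign, logdet = np.linalg.slogdet(S)
            self.means_.append(mu)
            self._precisions.append(np.linalg.inv(S))
            self._logdets.append(logdet)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        scores = np.empty((X.shape[0], len(self.classes_)))
        for ci in range(len(self.classes_)):
            z = X - self.means_[ci]
            maha = np.einsum("ij,jk,ik->i", z, self._precisions[ci], z)
            scores[:, ci] = (
                -0.5 * maha - 0.5 * self._logdets[ci] + self.log_priors_[ci]
            )
        return self.classes_[np.argmax(scores, axis=1)]


class ClippedKNeighborsClassifier(KNeighborsClassifier):
    """k-NN that never requests more neighbors than training points."""

    def fit(self, X, y):
        n = np.asarray(X).shape[0]
        if self.n_neighbors > n:
            self.n_neighbors = n
        return super().fit(X, y)


class KernelNaiveBayes(ClassifierMixin, BaseEstimator):
    """Naive Bayes with per-feature Gaussian KDE class-conditionals.

    For class c and feature j the density is the average of Gaussian
    kernels centered on the training values, with Silverman's bandwidth
    ``sigma * (4 / (3 n))**(1/5)`` floored at ``min_bandwidth`` times the
    overall feature scale.  Features are treated as independent (the naive
    assumption); priors are the empirical class frequencies.
    """

    def __init__(self, min_bandwidth: float = 1e-3, chunk_features: int = 64):
        self.min_bandwidth = min_bandwidth
        self.chunk_features = chunk_features

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        self.log_priors_ = np.log(counts / counts.sum())
        scale = X.std(axis=0)
        floor = self.min_bandwidth * max(float(scale.max()), 1e-12)
        self.train_, self.bandwidth_ = [], []
        for c in self.classes_:
            Xc = X[y == c]
            n_c = Xc.shape[0]
            h = Xc.std(axis=0) * (4.0 / (3.0 * n_c)) ** 0.2
            self.train_.append(Xc)
            self.bandwidth_.append(np.maximum(h, floor))
        self.n_features_in_ = X.shape[1]
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.classes_)))
        for ci, (Xc, h) in enumerate(zip(self.train_, self.bandwidth_)):
            total = np.zeros(X.shape[0])
            n_c = Xc.shape[0]
            for j0 in range(0, X.shape[1], self.chunk_features):
                j1 = min(j0 + self.chunk_features, X.shape[1])
                # (m, n_c, block): kernel log densities per feature
                z = (X[:, None, j0:j1] - Xc[None, :, j0:j1]) / h[None, None, j0:j1]
                ll = logsumexp(-0.5 * z * z, axis=1)
                ll -= np.log(n_c * h[j0:j1] * np.sqrt(2 * np.pi))[None, :]
                total += ll.sum(axis=1)
            out[:, ci] = total + self.log_priors_[ci]
        return out

    def predict(self, X):
        check_is_fitted(self, "classes_")
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


class RUSBoostClassifier(ClassifierMixin, BaseEstimator):
    """Boosting with per-round random undersampling (RUSBoost).

    Let ``N`` be the member count of the smallest class.  Each of the
    ``n_estimators`` rounds draws ``N`` points from every class without
    replacement — classes with more members are undersampled — with
    within-class probabilities proportional to the current boosting
    weights, fits a fresh base tree, and reweights misclassified points
    via multiclass AdaBoost (SAMME).
    """

    def __init__(self, estimator=None, n_estimators: int = 30,
                 learning_rate: float = 0.1, random_state: int | None = None):
        self.estimator = estimator
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        K = len(self.classes_)
        class_rows = [np.flatnonzero(y_idx == c) for c in range(K)]
        self.sample_size_per_class_ = int(min(len(r) for r in class_rows))
        N = self.sample_size_per_class_

        base = self.estimator or DecisionTreeClassifier(max_leaf_nodes=21)
        n = X.shape[0]
        w = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        for _ in range(self.n_estimators):
            sample = []
            for rows in class_rows:
                p = w[rows] / w[rows].sum()
                take = rng.choice(rows, size=N, replace=False, p=p)
                sample.append(take)
            sample = np.concatenate(sample)
            model = clone(base)
            if "random_state" in model.get_params():
                model.set_params(random_state=int(rng.integers(2**31)))
            model.fit(X[sample], y_idx[sample])
            pred = model.predict(X)
            miss = pred != y_idx
            err = float(w[miss].sum())
            if err <= 0:
                self.estimators_.append(model)
                self.alphas_.append(1.0)
                break
            if err >= 1.0 - 1.0 / K:  # no better than chance: skip round
                continue
            alpha = self.learning_rate * (
                np.log((1.0 - err) / err) + np.log(K - 1.0)
            )
            w *= np.exp(alpha * miss)
            w /= w.sum()
            self.estimators_.append(model)
            self.alphas_.append(alpha)
        if not self.estimators_:  # all rounds at chance: keep one model
            model = clone(base)
            model.fit(X, y_idx)
            self.estimators_.append(model)
            self.alphas_.append(1.0)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        for model, alpha in zip(self.estimators_, self.alphas_):
            pred = model.predict(X)
            votes[np.arange(X.shape[0]), pred] += alpha
        return self.classes_[np.argmax(votes, axis=1)]
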