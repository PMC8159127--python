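"""Preset registry: the 24 classifier variants of the benchmark grid.

Each variant name (e.g. "Fine Gaussian SVM", "Ensemble RUS Boosted Trees")
resolves to exactly one :class:`ClassifierSpec` with its hyperparameters
fully resolved — some depend on the feature count, notably the Gaussian
SVM kernel scales: fine ``sqrt(p)/4``, medium ``sqrt(p)``, coarse
``4 sqrt(p)`` (the RBF is ``exp(-||x-z||^2 / scale^2)``, i.e.
``gamma = 1/scale^2``).  Numeric tiers follow the well-known GUI presets
the row labels name: decision trees allow 100/20/4 splits
(fine/medium/coarse), k-NN uses k = 1/10/100, ensembles use 30 learners
and subspace ensembles draw half the features per learner.  All resolved
parameters are serialized into every report row.

A "Logistic Regression" preset is included for the EEG benchmark lists;
multiclass SVMs use one-vs-one voting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .estimators import (
    ClippedKNeighborsClassifier,
    KernelNaiveBayes,
    RegularizedQuadraticDiscriminant,
    RUSBoostClassifier,
)

__all__ = [
    "ClassifierSpec",
    "VARIANTS",
    "ECG_VARIANTS",
    "EEG_VARIANTS",
    "resolve_spec",
    "build_classifier",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """One benchmark entry: family, preset name and resolved parameters."""

    family: str
    variant: str
    params: dict = field(default_factory=dict)


def _tree(splits):
    def build(p, seed):
        return (
            DecisionTreeClassifier(max_leaf_nodes=splits + 1, random_state=seed),
            {"max_splits": splits},
        )
    return "tree", build


def _gaussian_svm(scale_of_p):
    def build(p, seed):
        scale = scale_of_p(p)
        return (
            SVC(kernel="rbf", gamma=1.0 / scale**2, C=1.0, random_state=seed),
            {"kernel": "rbf", "kernel_scale": scale, "C": 1.0},
        )
    return "svm", build


def _poly_svm(degree):
    def build(p, seed):
        if degree == 1:
            model = SVC(kernel="linear", C=1.0, random_state=seed)
            return model, {"kernel": "linear", "C": 1.0}
        model = SVC(kernel="poly", degree=degree, gamma="scale", coef0=1.0,
                    C=1.0, random_state=seed)
        return model, {"kernel": "poly", "degree": degree, "coef0": 1.0, "C": 1.0}
    return "svm", build


def _knn(k, metric="minkowski", power=2, weights="uniform"):
    def build(p, seed):
        cls = ClippedKNeighborsClassifier if k > 1 else KNeighborsClassifier
        model = cls(n_neighbors=k, metric=metric, p=power, weights=weights)
        return model, {"k": k, "metric": metric, "p": power, "weights": weights}
    return "knn", build


_N_LEARNERS = 30
_SUBSPACE_FRACTION = 0.5


def _build_boosted(p, seed):
    model = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_leaf_nodes=21),
        n_estimators=_N_LEARNERS, learning_rate=0.1, random_state=seed,
    )
    return model, {"n_learners": _N_LEARNERS, "learning_rate": 0.1,
                   "base_max_splits": 20}


def _build_bagged(p, seed):
    model = RandomForestClassifier(n_estimators=_N_LEARNERS, random_state=seed)
    return model, {"n_learners": _N_LEARNERS}


def _subspace(base_factory, base_params):
    def build(p, seed):
        model = BaggingClassifier(
            estimator=base_factory(),
            n_estimators=_N_LEARNERS,
            max_features=max(1, int(np.ceil(_SUBSPACE_FRACTION * p))),
            bootstrap=False,
            bootstrap_features=False,
            random_state=seed,
        )
        return model, {"n_learners": _N_LEARNERS,
                       "subspace_dim": max(1, int(np.ceil(_SUBSPACE_FRACTION * p))),
                       **base_params}
    return "ensemble", build


def _build_rusboost(p, seed):
    model = RUSBoostClassifier(
        estimator=DecisionTreeClassifier(max_leaf_nodes=21),
        n_estimators=_N_LEARNERS, learning_rate=0.1, random_state=seed,
    )
    return model, {"n_learners": _N_LEARNERS, "learning_rate": 0.1,
                   "undersample": "minority count per class"}


def _simple(family, factory, params=None):
    def build(p, seed):
        return factory(), dict(params or {})
    return family, build


#: variant name -> (family, builder(n_features, seed) -> (model, params))
VARIANTS = {
    "Fine Tree": _tree(100),
    "Medium Tree": _tree(20),
    "Coarse Tree": _tree(4),
    "Linear Discriminant": _simple(
        "lda", lambda: LinearDiscriminantAnalysis(), {"solver": "svd"}),
    "Quadratic Discriminant": _simple(
        "qda", lambda: RegularizedQuadraticDiscriminant(reg=0.1),
        {"reg": 0.1}),
    "Logistic Regression": _simple(
        "lda", lambda: LogisticRegression(max_iter=1000), {"max_iter": 1000}),
    "Naive Bayes": _simple("nbayes", lambda: GaussianNB()),
    "Kernel Naive Bayes": _simple(
        "nbayes", lambda: KernelNaiveBayes(), {"kernel": "gaussian-kde"}),
    "Linear SVM": _poly_svm(1),
    "Quadratic SVM": _poly_svm(2),
    "Cubic SVM": _poly_svm(3),
    "Fine Gaussian SVM": _gaussian_svm(lambda p: np.sqrt(p) / 4.0),
    "Medium Gaussian SVM": _gaussian_svm(lambda p: np.sqrt(p)),
    "Coarse Gaussian SVM": _gaussian_svm(lambda p: 4.0 * np.sqrt(p)),
    "Fine KNN": _knn(1),
    "Medium KNN": _knn(10),
    "Coarse KNN": _knn(100),
    "Cosine KNN": _knn(10, metric="cosine"),
    "Cubic KNN": _knn(10, power=3),
    "Weighted KNN": _knn(10, weights="distance"),
    "Ensemble Boosted Trees": ("ensemble", _build_boosted),
    "Ensemble Bagged Trees": ("ensemble", _build_bagged),
    "Ensemble Subspace Discriminant": _subspace(
        LinearDiscriminantAnalysis, {"base": "lda"}),
    "Ensemble Subspace KNN": _subspace(
        lambda: KNeighborsClassifier(n_neighbors=1), {"base": "1-nn"}),
    "Ensemble RUS Boosted Trees": ("ensemble", _build_rusboost),
}

_ALIASES = {
    "Ensemble RUSBoosted Trees": "Ensemble RUS Boosted Trees",
    "Fine Trees": "Fine Tree",
    "Medium Trees": "Medium Tree",
    "Coarse Trees": "Coarse Tree",
}

#: the 24-variant ECG benchmark list, in table order
ECG_VARIANTS = [v for v in VARIANTS if v != "Logistic Regression"]

#: the EEG benchmark list additionally includes logistic regression
EEG_VARIANTS = list(VARIANTS)


def _canonical(name: str) -> str:
    name = _ALIASES.get(name, name)
    if name not in VARIANTS:
        raise ValueError(
            f"unknown classifier variant {name!r}; valid variants: "
            + ", ".join(VARIANTS)
        )
    return name


def resolve_spec(name: str, n_features: int) -> ClassifierSpec:
    """Resolve a variant name to its spec for a given feature count."""
    name = _canonical(name)
    family, builder = VARIANTS[name]
    _, params = builder(n_features, 0)
    return ClassifierSpec(family=family, variant=name, params=params)


def build_classifier(name: str, n_features: int, random_state: int = 0):
    """Return an untrained model with preset hyperparameters resolved."""
    name = _canonical(name)
    _, builder = VARIANTS[name]
    model, _ = builder(n_features, random_state)
    return model
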