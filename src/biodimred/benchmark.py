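"""Evaluation protocol producing classifier-accuracy tables.

The default protocol is stratified 5-fold cross-validation with a fold
assignment drawn once per run and shared by every classifier variant and
every representation, so column-wise comparisons are paired.  Accuracy is
the percentage of correct predictions pooled over held-out folds.

Dimensionality reduction is fitted inside each fold — never on the test
portion.  LPP and the CS projector are fitted on the training rows and
applied to the held-out rows; Laplacian eigenmaps, which has no
out-of-sample map, uses the transductive mode (train and test embedded
jointly, test labels hidden).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._rng import child_seeds
from .dimred import (
    DisconnectedGraphError,
    build_adjacency_graph,
    cs_project,
    embed_transductive_le,
    lpp_fit,
    lpp_transform,
)
from .presets import build_classifier, resolve_spec
from .records import PatternMatrix

__all__ = [
    "evaluate_protocol",
    "run_reduction_grid",
    "best_accuracy",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = [
    "variant", "representation", "dim", "accuracy", "per_class_recall",
    "params", "seed", "protocol",
]

#: neighbor count used when the harness builds LE/LPP graphs
DEFAULT_GRAPH_K = 10


def _folds(labels: np.ndarray, protocol: dict, seed: int):
    """Resolve the evaluation protocol into (train, test) index pairs."""
    labels = labels.astype(str)
    if "kfold" in protocol:
        q = int(protocol["kfold"])
        counts = pd.Series(labels).value_counts()
        if counts.min() < q:
            raise ValueError(
                f"class {counts.idxmin()!r} has {counts.min()} members, "
                f"fewer than {q} folds"
            )
        skf = StratifiedKFold(n_splits=q, shuffle=True, random_state=seed)
        return list(skf.split(np.zeros(labels.size), labels))
    if "holdout" in protocol:
        frac = float(protocol["holdout"])
        train, test = train_test_split(
            np.arange(labels.size), test_size=frac, stratify=labels,
            random_state=seed,
        )
        return [(train, test)]
    raise ValueError(f"protocol must contain 'kfold' or 'holdout': {protocol}")


def _protocol_tag(protocol: dict) -> str:
    if "kfold" in protocol:
        return f"kfold{protocol['kfold']}"
    return f"holdout{protocol['holdout']}"


def _score(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, dict]:
    acc = 100.0 * float(np.mean(y_true == y_pred))
    recalls = {}
    for c in sorted(set(y_true.tolist())):
        mask = y_true == c
        recalls[str(c)] = 100.0 * float(np.mean(y_pred[mask] == c))
    return acc, recalls


def _eval_specs_on_folds(fold_data, labels, specs, seed, tag, rep, dim, rows):
    """Train every spec on identical fold representations; append rows."""
    for si, name in enumerate(specs):
        y_pred = np.empty(labels.size, dtype=object)
        for Xtr, Xte, train, test in fold_data:
            model = build_classifier(name, Xtr.shape[1], random_state=seed)
            model.fit(Xtr, labels[train].astype(str))
            y_pred[test] = model.predict(Xte)
        acc, recalls = _score(labels.astype(str), y_pred.astype(str))
        spec = resolve_spec(name, fold_data[0][0].shape[1])
        rows.append({
            "variant": spec.variant,
            "representation": rep,
            "dim": dim,
            "accuracy": acc,
            "per_class_recall": json.dumps(recalls),
            "params": json.dumps(spec.params, default=float),
            "seed": seed,
            "protocol": tag,
        })


def evaluate_protocol(
    X: PatternMatrix,
    specs: list[str],
    protocol: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified evaluation of classifier variants in the original space.

    Every spec sees the identical fold assignment (paired comparison).
    Returns a long-format report with one row per variant.
    """
    protocol = protocol or {"kfold": 5}
    if len(X.classes) < 2:
        raise ValueError("need at least 2 classes")
    folds = _folds(X.labels, protocol, seed)
    fold_data = [(X.X[tr], X.X[te], tr, te) for tr, te in folds]
    rows: list[dict] = []
    _eval_specs_on_folds(
        fold_data, X.labels, specs, seed, _protocol_tag(protocol),
        "none", X.n_features, rows,
    )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def _connected_le(Xtr, Xte, k, m):
    """Transductive LE, doubling k (documented fallback) until connected."""
    n_union = Xtr.shape[0] + Xte.shape[0]
    kk = min(k, n_union - 1)
    while True:
        try:
            return embed_transductive_le(Xtr, Xte, k=kk, m=m)
        except DisconnectedGraphError:
            if kk >= n_union - 1:
                raise
            kk = min(2 * kk, n_union - 1)


def _connected_graph(Xtr, k):
    n = Xtr.shape[0]
    kk = min(k, n - 1)
    while True:
        try:
            return build_adjacency_graph(Xtr, k=kk)
        except DisconnectedGraphError:
            if kk >= n - 1:
                raise
            kk = min(2 * kk, n - 1)


def run_reduction_grid(
    X: PatternMatrix,
    methods: list[str],
    dims: list[int],
    specs: list[str],
    protocol: dict | None = None,
    seed: int = 0,
    graph_k: int = DEFAULT_GRAPH_K,
) -> pd.DataFrame:
    """Benchmark every (method, dimension, classifier) combination.

    ``methods`` is a subset of {"none", "cs", "le", "lpp"}; "none" rows
    evaluate the original space and ignore ``dims``.  Reduction is fitted
    per fold on the training portion only (transductively for LE), and the
    identical folds serve every method, dimension and classifier.
    """
    protocol = protocol or {"kfold": 5}
    bad = [m for m in methods if m not in {"none", "cs", "le", "lpp"}]
    if bad:
        raise ValueError(f"unknown reduction methods: {bad}")
    bad_dims = [d for d in dims if d >= X.n_features]
    if bad_dims and set(methods) - {"none"}:
        raise ValueError(
            f"dims {bad_dims} not below the feature count {X.n_features}"
        )
    folds = _folds(X.labels, protocol, seed)
    tag = _protocol_tag(protocol)
    rows: list[dict] = []
    cs_seeds = child_seeds(seed, len(folds))

    if "none" in methods:
        fold_data = [(X.X[tr], X.X[te], tr, te) for tr, te in folds]
        _eval_specs_on_folds(fold_data, X.labels, specs, seed, tag,
                             "none", X.n_features, rows)

    for method in [m for m in ("cs", "le", "lpp") if m in methods]:
        for dim in dims:
            fold_data = []
            for fi, (tr, te) in enumerate(folds):
                Xtr, Xte = X.X[tr], X.X[te]
                try:
                    if method == "cs":
                        emb, proj = cs_project(Xtr, dim, seed=cs_seeds[fi])
                        Ztr, Zte = emb.Y, proj.transform(Xte).Y
                    elif method == "lpp":
                        graph = _connected_graph(Xtr, graph_k)
                        model = lpp_fit(Xtr, graph, l=dim)
                        Ztr = lpp_transform(model, Xtr).Y
                        Zte = lpp_transform(model, Xte).Y
                    else:  # le, transductive; test labels never consulted
                        Ztr, Zte = _connected_le(Xtr, Xte, graph_k, dim)
                except Exception as exc:
                    raise RuntimeError(
                        f"reduction failed for method={method!r}, dim={dim}: {exc}"
                    ) from exc
                fold_data.append((Ztr, Zte, tr, te))
            _eval_specs_on_folds(fold_data, X.labels, specs, seed, tag,
                                 method, dim, rows)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def best_accuracy(report: pd.DataFrame, representation: str,
                  dim: int | None = None) -> float:
    """Best accuracy over classifier variants for one representation."""
    sub = report[report["representation"] == representation]
    if dim is not None:
        sub = sub[sub["dim"] == dim]
    if sub.empty:
        raise ValueError(
            f"no rows for representation={representation!r}, dim={dim}"
        )
    return float(sub["accuracy"].max())
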