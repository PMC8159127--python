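"""Config-driven experiment orchestration, table export and 3-D plots.

An :class:`ExperimentConfig` (usually loaded from YAML) fully describes a
run: the dataset (synthetic ECG/EEG or an external database), generator
parameters under a ``synthetic:`` block, the reduction methods and target
dimensions, the classifier list and the evaluation protocol.  A run writes
its pattern CSV, the long- and wide-format accuracy tables, the fully
resolved config and a manifest with a content hash per output, and is
deterministic given its seed (stage seeds are split from the master seed,
so e.g. adding a classifier does not perturb data generation).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import child_seeds
from .benchmark import run_reduction_grid
from .dimred import EmbeddingResult
from .eeg import ChannelConfig, epoch_stimulus_locked, preprocess_record, select_and_concatenate
from .presets import ECG_VARIANTS, _canonical
from .records import PatternMatrix
from .synth_ecg import make_ecg_pattern_set
from .synth_eeg import P300Config, generate_p300_record

__all__ = [
    "ExperimentConfig",
    "ConfigError",
    "run_config",
    "export_table",
    "wide_to_long",
    "plot_embedding_3d",
]


class ConfigError(ValueError):
    """Invalid experiment configuration (raised before any compute)."""


@dataclass
class ExperimentConfig:
    """Fully parameterized experiment description."""

    dataset: str = "synthetic-ecg"
    synthetic: dict = field(default_factory=dict)
    channel_config: str = "cfg8"
    methods: list[str] = field(default_factory=lambda: ["none", "cs", "le", "lpp"])
    dims: list[int] = field(default_factory=lambda: [2, 3, 25])
    classifiers: list[str] = field(default_factory=lambda: list(ECG_VARIANTS))
    protocol: dict = field(default_factory=lambda: {"kfold": 5})
    seed: int = 0
    output_dir: str = "runs/run0"
    external_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.dataset not in {
            "synthetic-ecg", "synthetic-eeg", "external-mitdb", "external-epfl",
        }:
            raise ConfigError(f"unknown dataset {self.dataset!r}")
        if self.dataset.startswith("external") and not self.external_path:
            raise ConfigError(
                f"dataset {self.dataset!r} requires an explicit external_path"
            )
        for m in self.methods:
            if m not in {"none", "cs", "le", "lpp"}:
                raise ConfigError(f"unknown reduction method {m!r}")
        for name in self.classifiers:
            _canonical(name)  # raises on unknown variants
        p = self.expected_feature_count()
        if p is not None:
            bad = [d for d in self.dims if d >= p]
            if bad and set(self.methods) - {"none"}:
                raise ConfigError(
                    f"dims {bad} must be below the feature count {p}"
                )

    def expected_feature_count(self) -> int | None:
        """Feature count implied by the config, before any compute."""
        if self.dataset == "synthetic-ecg":
            return int(self.synthetic.get("target_len", 301))
        if self.dataset == "synthetic-eeg":
            cfg = ChannelConfig.preset(self.channel_config)
            epoch_len = int(round(
                float(self.synthetic.get("epoch_s", 1.0))
                * float(self.synthetic.get("out_fs", 128.0))
            ))
            return len(cfg) * epoch_len
        return None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_patterns(cfg: ExperimentConfig, seed: int) -> PatternMatrix:
    syn = dict(cfg.synthetic)
    if cfg.dataset == "synthetic-ecg":
        per_class = int(syn.pop("per_class", 60))
        syn.pop("target_len", None)
        return make_ecg_pattern_set(per_class, seed=seed, **syn)
    if cfg.dataset == "synthetic-eeg":
        out_fs = float(syn.pop("out_fs", 128.0))
        epoch_s = float(syn.pop("epoch_s", 1.0))
        order = int(syn.pop("filter_order", 7))
        cutoff = float(syn.pop("cutoff_hz", 9.0))
        p300 = P300Config(seed=seed, **syn)
        record = generate_p300_record(p300)
        record = preprocess_record(record, order=order, cutoff=cutoff, out_fs=out_fs)
        epochs = epoch_stimulus_locked(record, duration=epoch_s)
        return select_and_concatenate(epochs, ChannelConfig.preset(cfg.channel_config))
    if cfg.dataset == "external-mitdb":
        from .external import load_mitdb_patterns
        return load_mitdb_patterns(cfg.external_path)
    raise ConfigError(f"dataset {cfg.dataset!r} not supported by run_config")


def run_config(cfg: ExperimentConfig) -> Path:
    """Execute an experiment end-to-end; returns the run directory.

    Outputs: ``patterns.csv``, ``report_long.csv``, ``report_wide.csv``,
    ``config.yaml`` (fully resolved) and ``manifest.json`` (content hash
    per output).  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_seed, eval_seed = child_seeds(cfg.seed, 2)

    patterns = _build_patterns(cfg, data_seed)
    try:
        report = run_reduction_grid(
            patterns, cfg.methods, cfg.dims, cfg.classifiers,
            protocol=cfg.protocol, seed=eval_seed,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'benchmark' failed: {exc}") from exc

    patterns.to_csv(out / "patterns.csv")
    report.to_csv(out / "report_long.csv", index=False)
    (out / "report_wide.csv").write_text(export_table(report, layout="wide"))
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    manifest = {
        name: _sha256(out / name)
        for name in ("patterns.csv", "report_long.csv", "report_wide.csv",
                     "config.yaml")
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


# ---------------------------------------------------------------------------
# table export
# ---------------------------------------------------------------------------

def _column_name(rep: str, dim) -> str:
    if rep == "none":
        return "Original"
    return f"{rep.upper()} {int(dim)}"


def export_table(report: pd.DataFrame, layout: str = "wide") -> str:
    """Render a report as CSV text.

    ``wide``: classifiers as rows, representation x dimension as columns,
    accuracies rounded to 1 decimal.  ``long``: the raw row-per-result
    format.  The wide -> long -> wide round trip is lossless.
    """
    if report.empty:
        raise ValueError("report is empty")
    if layout == "long":
        return report.to_csv(index=False)
    if layout != "wide":
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    frame = report.copy()
    frame["column"] = [
        _column_name(r, d) for r, d in zip(frame["representation"], frame["dim"])
    ]
    wide = frame.pivot_table(
        index="variant", columns="column", values="accuracy", sort=False,
    )
    # column order: Original first, then methods in first-appearance order
    cols = list(dict.fromkeys(frame["column"]))
    wide = wide.reindex(
        index=list(dict.fromkeys(frame["variant"])), columns=cols
    )
    out = wide.map(lambda v: f"{v:.1f}" if pd.notna(v) else "")
    out.index.name = "Classifier"
    return out.to_csv()


def wide_to_long(text: str) -> pd.DataFrame:
    """Parse a wide-format table back to (variant, representation, dim,
    accuracy) rows."""
    import io

    wide = pd.read_csv(io.StringIO(text), index_col=0)
    rows = []
    for variant, series in wide.iterrows():
        for col, val in series.items():
            if pd.isna(val):
                continue
            if col == "Original":
                rep, dim = "none", None
            else:
                rep, dim_s = col.rsplit(" ", 1)
                rep, dim = rep.lower(), int(dim_s)
            rows.append({
                "variant": variant, "representation": rep, "dim": dim,
                "accuracy": float(val),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_embedding_3d(
    emb: EmbeddingResult | np.ndarray,
    labels,
    path: str | Path,
) -> Path:
    """Scatter an embedding in 3-D (first three columns; 2-D fallback).

    One color per class with a deterministic mapping by sorted label and a
    legend entry per class.  Rejects 1-D embeddings.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    Y = emb.Y if isinstance(emb, EmbeddingResult) else np.asarray(emb, float)
    labels = np.asarray(labels).astype(str)
    if Y.shape[1] < 2:
        raise ValueError("plot_embedding_3d needs at least 2 dimensions")
    classes = sorted(set(labels.tolist()))
    cmap = plt.get_cmap("tab10")

    fig = plt.figure(figsize=(6, 5), dpi=100)
    if Y.shape[1] >= 3:
        ax = fig.add_subplot(111, projection="3d")
        for i, c in enumerate(classes):
            mask = labels == c
            ax.scatter(Y[mask, 0], Y[mask, 1], Y[mask, 2],
                       s=8, color=cmap(i % 10), label=c)
    else:
        ax = fig.add_subplot(111)
        for i, c in enumerate(classes):
            mask = labels == c
            ax.scatter(Y[mask, 0], Y[mask, 1], s=8, color=cmap(i % 10), label=c)
    ax.legend(loc="best", fontsize=8)
    path = Path(path)
    fig.savefig(path, metadata={"Software": None})
    plt.close(fig)
    return path
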