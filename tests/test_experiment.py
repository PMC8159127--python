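"""Experiment orchestration, table export and plotting."""

import json

import numpy as np
import pandas as pd
import pytest

from biodimred import ExperimentConfig, export_table, plot_embedding_3d, run_config
from biodimred.dimred import EmbeddingResult
from biodimred.experiment import ConfigError, wide_to_long


def _small_cfg(tmp_path, **over):
    base = dict(
        dataset="synthetic-ecg",
        synthetic={"per_class": 12},
        methods=["none", "cs"],
        dims=[2, 3],
        classifiers=["Fine KNN", "Linear Discriminant", "Fine Tree"],
        protocol={"kfold": 3},
        seed=5,
        output_dir=str(tmp_path / "run"),
    )
    base.update(over)
    return ExperimentConfig(**base)


def test_minimal_run_produces_expected_rows(tmp_path):
    out = run_config(_small_cfg(tmp_path))
    report = pd.read_csv(out / "report_long.csv")
    # 3 original-space rows + |methods\{none}| x |dims| x |specs|
    assert len(report) == 3 + 1 * 2 * 3
    manifest = json.loads((out / "manifest.json").read_text())
    assert set(manifest) == {"patterns.csv", "report_long.csv",
                             "report_wide.csv", "config.yaml"}


def test_same_seed_byte_identical_reports(tmp_path):
    a = run_config(_small_cfg(tmp_path, output_dir=str(tmp_path / "a")))
    b = run_config(_small_cfg(tmp_path, output_dir=str(tmp_path / "b")))
    assert (a / "report_long.csv").read_bytes() == (b / "report_long.csv").read_bytes()


def test_dim_validation_happens_before_compute(tmp_path):
    cfg = _small_cfg(tmp_path, dims=[301])
    with pytest.raises(ConfigError, match="below the feature count"):
        run_config(cfg)


def test_config_validation_errors(tmp_path):
    with pytest.raises(ConfigError, match="external_path"):
        _small_cfg(tmp_path, dataset="external-mitdb").validate()
    with pytest.raises(ConfigError, match="unknown"):
        _small_cfg(tmp_path, dataset="csv-files").validate()
    with pytest.raises(ValueError, match="variant"):
        _small_cfg(tmp_path, classifiers=["Mystery Model"]).validate()


def test_yaml_round_trip(tmp_path):
    cfg = _small_cfg(tmp_path)
    path = tmp_path / "cfg.yaml"
    import yaml
    from dataclasses import asdict
    path.write_text(yaml.safe_dump(asdict(cfg)))
    back = ExperimentConfig.from_yaml(path)
    assert back == cfg
    (tmp_path / "bad.yaml").write_text("dataset: synthetic-ecg\nbogus: 1\n")
    with pytest.raises(ConfigError, match="bogus"):
        ExperimentConfig.from_yaml(tmp_path / "bad.yaml")


def _fake_report():
    rows = []
    for variant in ["Fine KNN", "Cubic SVM"]:
        rows.append({"variant": variant, "representation": "none",
                     "dim": 301, "accuracy": 95.238})
        for d in (2, 3):
            rows.append({"variant": variant, "representation": "cs",
                         "dim": d, "accuracy": 50.0 + d})
    return pd.DataFrame(rows)


def test_wide_table_formatting():
    text = export_table(_fake_report(), layout="wide")
    lines = text.strip().splitlines()
    assert lines[0] == "Classifier,Original,CS 2,CS 3"
    assert lines[1].startswith("Fine KNN,95.2,52.0,53.0")


def test_wide_long_round_trip_lossless():
    wide1 = export_table(_fake_report(), layout="wide")
    long = wide_to_long(wide1)
    # re-render from the parsed long table: identical text
    long2 = long.copy()
    long2["dim"] = long2["dim"].fillna(301)
    wide2 = export_table(long2, layout="wide")
    assert wide1 == wide2


def test_single_cell_table():
    rep = pd.DataFrame([{"variant": "Fine KNN", "representation": "none",
                         "dim": 10, "accuracy": 80.0}])
    text = export_table(rep, layout="wide")
    assert text.strip().splitlines() == ["Classifier,Original", "Fine KNN,80.0"]


def test_plot_has_legend_per_class(tmp_path):
    rng = np.random.default_rng(0)
    Y = rng.normal(size=(80, 3))
    labels = np.repeat([f"c{i}" for i in range(8)], 10)
    emb = EmbeddingResult(Y=Y, eigvals=np.arange(3) + 0.1, method="le", m=3)
    path = plot_embedding_3d(emb, labels, tmp_path / "e.png")
    assert path.exists() and path.stat().st_size > 0


def test_plot_2d_fallback_and_1d_rejection(tmp_path):
    rng = np.random.default_rng(0)
    labels = np.repeat(["a", "b"], 10)
    p2 = plot_embedding_3d(rng.normal(size=(20, 2)), labels, tmp_path / "f.png")
    assert p2.exists()
    with pytest.raises(ValueError, match="at least 2"):
        plot_embedding_3d(rng.normal(size=(20, 1)), labels, tmp_path / "g.png")


def test_plot_deterministic_bytes(tmp_path):
    rng = np.random.default_rng(2)
    Y = rng.normal(size=(30, 3))
    labels = np.repeat(["a", "b", "c"], 10)
    p1 = plot_embedding_3d(Y, labels, tmp_path / "a.png")
    p2 = plot_embedding_3d(Y, labels, tmp_path / "b.png")
    assert p1.read_bytes() == p2.read_bytes()
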