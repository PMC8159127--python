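"""Optional loaders for the real databases (external mode only).

These readers are never exercised by the test suite; they exist so the
same pipeline can run on the real recordings when the files are available
locally.  ``wfdb`` is an optional dependency (``pip install
biodimred[external]``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .records import PatternMatrix, SignalRecord
from .segmentation import SegmentationSpec, segment_r_centered
from .synth_ecg import BEAT_CLASSES

__all__ = ["MITBIH_ANNOTATION_MAP", "load_mitdb_record", "load_mitdb_patterns",
           "load_epfl_mat"]

#: MIT-BIH beat annotation codes -> the 8 class labels used here
MITBIH_ANNOTATION_MAP = {
    "N": "N", "A": "A", "L": "L", "R": "R", "V": "V", "F": "F",
    "/": "/", "f": "f",
}


def load_mitdb_record(path: str | Path, channel: int = 0) -> SignalRecord:
    """Read one MIT-BIH record (``path`` without extension) via wfdb."""
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - external mode only
        raise ImportError(
            "reading MIT-BIH records requires the optional 'wfdb' package "
            "(pip install biodimred[external])"
        ) from exc
    path = str(path)
    rec = wfdb.rdrecord(path, channels=[channel])
    ann = wfdb.rdann(path, "atr")
    events = [
        (int(s), MITBIH_ANNOTATION_MAP[sym])
        for s, sym in zip(ann.sample, ann.symbol)
        if sym in MITBIH_ANNOTATION_MAP
    ]
    return SignalRecord(
        data=rec.p_signal.T,
        fs=float(rec.fs),
        channel_names=list(rec.sig_name),
        events=events,
        meta={"kind": "mitdb", "record": path},
    )


def load_mitdb_patterns(
    directory: str | Path,
    records: list[str] | None = None,
    spec: SegmentationSpec | None = None,
) -> PatternMatrix:
    """Segment every annotated beat of the given MIT-BIH records.

    Uses the annotated R positions directly (the database annotation is
    the reference R location) and keeps only the 8 mapped classes.
    """
    directory = Path(directory)
    spec = spec or SegmentationSpec()
    if records is None:
        records = sorted(p.stem for p in directory.glob("*.hea"))
    blocks = []
    for name in records:
        rec = load_mitdb_record(directory / name)
        r = rec.event_indices
        if r.size < 3:
            continue
        blocks.append(segment_r_centered(rec, r, spec))
    if not blocks:
        raise ValueError(f"no usable records under {directory}")
    X = np.vstack([b.X for b in blocks])
    labels = np.concatenate([b.labels for b in blocks])
    keep = np.isin(labels.astype(str), BEAT_CLASSES)
    return PatternMatrix(X[keep], labels[keep], meta={"kind": "mitdb-patterns"})


def load_epfl_mat(path: str | Path) -> dict:
    """Load one EPFL P300 session MAT-file (raw variables, unprocessed)."""
    from scipy.io import loadmat

    return loadmat(str(path), squeeze_me=True)
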