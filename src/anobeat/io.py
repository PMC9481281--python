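"""File formats: delimited-text beat matrices, plain-text annotated
records, and an optional WFDB adapter for PhysioNet-style data.

Beat matrices are CSV with 250 sample columns and a final ``label``
column.  Records are a pair of text files: ``<base>.csv`` (one sample per
line, with the sampling rate in a header comment) and ``<base>.ann.tsv``
(tab-separated ``sample_index<TAB>label`` rows).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BEAT_CLASSES, BEAT_LEN, BeatMatrix, ECGRecord

logger = logging.getLogger(__name__)

__all__ = [
    "write_beats",
    "read_beats",
    "write_record",
    "read_record",
    "map_annotation_symbols",
    "read_wfdb_record",
]


def write_beats(matrix: BeatMatrix, path) -> None:
    """One beat per row, 250 sample columns then the class label."""
    df = pd.DataFrame(matrix.beats,
                      columns=[f"s{i}" for i in range(BEAT_LEN)])
    df["label"] = matrix.labels
    df.to_csv(path, index=False)


def read_beats(path) -> BeatMatrix:
    """Read a delimited-text beat matrix, validating row length and labels."""
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        logger.warning("empty beat file %s", path)
        return BeatMatrix.empty()
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column")
    values = df.drop(columns="label")
    if values.shape[1] != BEAT_LEN:
        raise ValueError(
            f"{path}: expected {BEAT_LEN} sample columns, got {values.shape[1]}"
        )
    arr = values.to_numpy(dtype=np.float64)
    bad = np.nonzero(~np.all(np.isfinite(arr), axis=1))[0]
    if bad.size:
        raise ValueError(f"{path}: non-finite samples in row {int(bad[0])}")
    labels = df["label"].to_numpy(dtype="U1")
    bad_lab = np.nonzero(~np.isin(labels, BEAT_CLASSES))[0]
    if bad_lab.size:
        raise ValueError(
            f"{path}: unknown label {df['label'].iloc[bad_lab[0]]!r} "
            f"in row {int(bad_lab[0])}"
        )
    return BeatMatrix(arr, labels)


def write_record(record: ECGRecord, base) -> None:
    base = Path(base)
    header = f"# fs={record.fs}"
    np.savetxt(base.with_suffix(".csv"), record.samples,
               header=header, comments="")
    with open(base.with_suffix(".ann.tsv"), "w") as fh:
        for r, lab in zip(record.r_peaks, record.beat_labels):
            fh.write(f"{int(r)}\t{lab}\n")


def read_record(base) -> ECGRecord:
    base = Path(base)
    sig_path = base.with_suffix(".csv")
    with open(sig_path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# fs="):
        raise ValueError(f"{sig_path}: missing '# fs=' header line")
    fs = float(first.split("=", 1)[1])
    samples = np.loadtxt(sig_path, skiprows=1)
    ann_path = base.with_suffix(".ann.tsv")
    peaks, labels = [], []
    if ann_path.exists():
        with open(ann_path) as fh:
            for line in fh:
                if line.strip():
                    idx, lab = line.split("\t")
                    peaks.append(int(idx))
                    labels.append(lab.strip())
    return ECGRecord(np.atleast_1d(samples), fs,
                     np.asarray(peaks, dtype=np.int64),
                     np.asarray(labels, dtype="U1"))


def map_annotation_symbols(
    symbols: np.ndarray, indices: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Keep annotations whose symbol is one of N/A/L/R/V.

    Returns ``(kept_indices, kept_labels, n_dropped)``; unknown symbols
    (rhythm changes, paced beats, artefacts ...) are dropped and counted.
    """
    symbols = np.asarray(symbols)
    indices = np.asarray(indices, dtype=np.int64)
    keep = np.isin(symbols, BEAT_CLASSES)
    return indices[keep], symbols[keep].astype("U1"), int((~keep).sum())


def read_wfdb_record(path, lead: str = "II") -> ECGRecord:
    """Load a PhysioNet WFDB record + annotations as an :class:`ECGRecord`.

    Requires the optional ``wfdb`` package.  Selects the requested lead
    (default II) from multi-lead signals and maps annotation symbols via
    :func:`map_annotation_symbols`.
    """
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install wfdb); synthetic/text records do not need it"
        ) from exc

    rec = wfdb.rdrecord(str(path))
    names = [n.strip().upper() for n in rec.sig_name]
    want = lead.strip().upper()
    if want not in names:
        raise ValueError(
            f"record {path} has leads {rec.sig_name}, not lead {lead!r}"
        )
    sig = rec.p_signal[:, names.index(want)]
    ann = wfdb.rdann(str(path), "atr")
    peaks, labels, dropped = map_annotation_symbols(
        np.asarray(ann.symbol), np.asarray(ann.sample))
    if dropped:
        logger.info("%s: dropped %d annotations with unmapped symbols",
                    path, dropped)
    return ECGRecord(sig, float(rec.fs), peaks, labels)
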