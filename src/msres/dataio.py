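"""Reading and writing datasets in the CinC-2017 on-disk layout.

A dataset directory holds one MATLAB level-4 ``.mat`` file per record — a
single row vector of ADC integers at 300 Hz, 1000 units per millivolt —
plus a headerless ``REFERENCE.csv`` of ``name,label`` rows with labels in
``{N, A, O, ~}``.  For the binary AF task the four raw labels collapse to
``A -> 1`` and ``N, O, ~ -> 0``.  A plain one-column ``.csv`` per record is
accepted as a text-only fallback container.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

from .errors import DataFormatError
from .synth import SyntheticRecord

__all__ = [
    "RecordFile",
    "LabelTable",
    "ADC_GAIN",
    "read_record",
    "write_record",
    "load_labels",
    "write_labels",
    "record_from_synthetic",
    "write_dataset",
    "load_dataset",
    "inspect_dataset",
]

#: ADC integer units per millivolt (device convention).
ADC_GAIN = 1000.0

#: Raw rhythm labels: normal, AF, other rhythm, too noisy.
RAW_LABELS = ("N", "A", "O", "~")


@dataclass(frozen=True)
class RecordFile:
    """One on-disk record: a named 1-D sample vector in millivolts."""

    name: str
    samples: np.ndarray  # mV
    fs: float = 300.0

    def __post_init__(self) -> None:
        if np.asarray(self.samples).ndim != 1 or len(self.samples) == 0:
            raise DataFormatError(f"record {self.name!r}: sample vector must be 1-D and non-empty")
        if self.fs <= 0:
            raise DataFormatError(f"record {self.name!r}: fs must be > 0")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class LabelTable:
    """Record-name -> label mapping with the binarized AF target.

    ``entries`` is a list of ``(name, raw_label, binary_label)`` with
    ``binary_label = 1`` iff ``raw_label == "A"``.
    """

    entries: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DataFormatError(f"duplicate record names in label table: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def binary(self) -> dict[str, int]:
        return {name: b for name, _, b in self.entries}

    def binary_counts(self) -> dict[int, int]:
        counts = {0: 0, 1: 0}
        for _, _, b in self.entries:
            counts[b] += 1
        return counts


def binarize_label(raw: str) -> int:
    """Map a raw rhythm label to the binary AF target (A -> 1, else 0)."""
    if raw not in RAW_LABELS:
        raise DataFormatError(f"unknown label {raw!r}; expected one of {RAW_LABELS}")
    return 1 if raw == "A" else 0


def write_record(
    record: RecordFile | SyntheticRecord,
    directory: str | Path,
    fmt: str = "mat",
    overwrite: bool = True,
) -> Path:
    """Write one record as ``<dir>/<name>.<fmt>``; returns the path.

    ``mat`` stores ADC integers (mV x 1000) in a level-4 MATLAB container,
    ``csv`` stores the same integers one per line.
    """
    if isinstance(record, SyntheticRecord):
        record = record_from_synthetic(record)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt not in ("mat", "csv"):
        raise ValueError(f"unsupported format {fmt!r}")
    path = directory / f"{record.name}.{fmt}"
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists and overwrite=False")
    adc = np.clip(np.round(np.asarray(record.samples) * ADC_GAIN), -32768, 32767).astype(np.int16)
    if fmt == "mat":
        savemat(str(path), {"val": adc[None, :]}, format="4")
    else:
        np.savetxt(path, adc, fmt="%d")
    return path


def read_record(path: str | Path, fs: float = 300.0) -> RecordFile:
    """Read one record (``.mat`` or ``.csv``); samples are returned in mV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"record file not found: {path}")
    if path.suffix == ".mat":
        try:
            contents = loadmat(str(path))
        except Exception as exc:  # scipy raises assorted errors on corrupt input
            raise DataFormatError(f"cannot parse MAT record {path}: {exc}") from exc
        arrays = {k: v for k, v in contents.items() if not k.startswith("__")}
        if len(arrays) != 1:
            raise DataFormatError(f"{path}: expected a single variable, found {sorted(arrays)}")
        val = next(iter(arrays.values()))
        val = np.asarray(val)
        if val.ndim != 2 or min(val.shape) != 1:
            raise DataFormatError(f"{path}: multi-channel content of shape {val.shape} unsupported")
        adc = val.ravel()
    elif path.suffix == ".csv":
        try:
            adc = np.loadtxt(path, dtype=float, ndmin=1)
        except Exception as exc:
            raise DataFormatError(f"cannot parse CSV record {path}: {exc}") from exc
        if adc.ndim != 1:
            raise DataFormatError(f"{path}: multi-channel content unsupported")
    else:
        raise DataFormatError(f"{path}: unsupported record extension {path.suffix!r}")
    return RecordFile(name=path.stem, samples=adc.astype(float) / ADC_GAIN, fs=fs)


def load_labels(csv_path: str | Path) -> LabelTable:
    """Load a headerless ``name,label`` CSV and binarize the labels."""
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise FileNotFoundError(f"label file not found: {csv_path}")
    try:
        df = pd.read_csv(csv_path, header=None, names=["name", "label"], dtype=str,
                         keep_default_na=False)
    except pd.errors.EmptyDataError:
        return LabelTable(())
    entries = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = row.label
        if raw not in RAW_LABELS:
            raise DataFormatError(
                f"{csv_path}, row {i + 1} ({row.name!r}): unknown label {raw!r}"
            )
        entries.append((row.name, raw, binarize_label(raw)))
    return LabelTable(tuple(entries))


def write_labels(entries: list[tuple[str, str]], csv_path: str | Path) -> Path:
    """Write ``(name, raw_label)`` pairs as a headerless REFERENCE.csv."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    with open(csv_path, "w") as fh:
        for name, raw in entries:
            fh.write(f"{name},{raw}\n")
    return csv_path


def record_from_synthetic(rec: SyntheticRecord) -> RecordFile:
    if not rec.name:
        raise ValueError("synthetic record has no name; set one before writing")
    return RecordFile(name=rec.name, samples=np.asarray(rec.samples), fs=rec.fs)


def write_dataset(
    records: list[SyntheticRecord] | list[RecordFile],
    directory: str | Path,
    labels: dict[str, str] | None = None,
    fmt: str = "mat",
) -> Path:
    """Write records plus REFERENCE.csv in the archive layout.

    For synthetic records the raw label defaults to ``A`` for AF and ``N``
    otherwise; for plain records a ``labels`` mapping must be supplied.
    """
    directory = Path(directory)
    entries = []
    for rec in records:
        write_record(rec, directory, fmt=fmt)
        if isinstance(rec, SyntheticRecord):
            raw = "A" if rec.label == 1 else "N"
        else:
            if labels is None or rec.name not in labels:
                raise ValueError(f"no raw label provided for record {rec.name!r}")
            raw = labels[rec.name]
        entries.append((rec.name, raw))
    write_labels(entries, directory / "REFERENCE.csv")
    return directory


def load_dataset(directory: str | Path) -> tuple[list[RecordFile], LabelTable]:
    """Load every labeled record of a dataset directory."""
    directory = Path(directory)
    table = load_labels(directory / "REFERENCE.csv")
    records = []
    for name, _, _ in table.entries:
        mat = directory / f"{name}.mat"
        csv = directory / f"{name}.csv"
        records.append(read_record(mat if mat.exists() else csv))
    return records, table


def inspect_dataset(directory: str | Path) -> dict:
    """Record count, duration range and label histogram of a dataset."""
    records, table = load_dataset(directory)
    durations = [r.duration for r in records]
    raw_counts: dict[str, int] = {}
    for _, raw, _ in table.entries:
        raw_counts[raw] = raw_counts.get(raw, 0) + 1
    return {
        "n_records": len(records),
        "duration_min": min(durations) if durations else None,
        "duration_max": max(durations) if durations else None,
        "raw_label_counts": raw_counts,
        "binary_label_counts": table.binary_counts(),
    }
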