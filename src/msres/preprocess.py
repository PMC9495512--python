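"""Fixed-window segmentation and normalization of ECG records.

The pipeline turns variable-length records (9-61 s at 300 Hz) into a
population of fixed 9 s / 2,700-sample segments: an optional start clip
(sensor-mounting artifacts), a non-overlapping moving window (step 9 s,
trailing partial windows discarded), and per-segment min-max scaling to
[0, 1].  Stratified hold-out splitting and stratified k-fold assignment
operate on the resulting segment population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataio import RecordFile
from .errors import EmptyRecordError

__all__ = [
    "Segment",
    "SegmentSet",
    "clip_start",
    "segment_record",
    "segment_count",
    "normalize01",
    "segment_records",
    "stratified_split",
    "make_folds",
]

WINDOW_SECONDS = 9.0
WINDOW_SAMPLES = 2700


@dataclass(frozen=True)
class Segment:
    """One fixed-length window cut from a record."""

    values: np.ndarray
    label: int
    source: str
    start_index: int  # 0-based sample offset into the source record


class SegmentSet:
    """A matrix of fixed-length segments with labels and provenance.

    Rows of ``matrix`` (float32, n x window) align with ``labels`` (0/1),
    ``sources`` (record names) and ``starts`` (sample offsets).
    """

    def __init__(self, matrix, labels, sources, starts=None):
        self.matrix = np.ascontiguousarray(matrix, dtype=np.float32)
        self.labels = np.asarray(labels, dtype=np.int64)
        self.sources = np.asarray(sources, dtype=object)
        if starts is None:
            starts = np.zeros(len(self.labels), dtype=np.int64)
        self.starts = np.asarray(starts, dtype=np.int64)
        n = self.matrix.shape[0]
        if not (len(self.labels) == len(self.sources) == len(self.starts) == n):
            raise ValueError("matrix rows, labels, sources and starts must align")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def window_samples(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_segments(cls, segments: list[Segment]) -> "SegmentSet":
        if not segments:
            return cls(np.empty((0, WINDOW_SAMPLES), dtype=np.float32), [], [])
        return cls(
            np.stack([s.values for s in segments]),
            [s.label for s in segments],
            [s.source for s in segments],
            [s.start_index for s in segments],
        )

    def select(self, idx) -> "SegmentSet":
        idx = np.asarray(idx)
        return SegmentSet(self.matrix[idx], self.labels[idx], self.sources[idx], self.starts[idx])

    def class_counts(self) -> dict[int, int]:
        return {0: int(np.sum(self.labels == 0)), 1: int(np.sum(self.labels == 1))}


def clip_start(record: RecordFile, clip_seconds: float) -> RecordFile:
    """Drop the first ``round(clip_seconds * fs)`` samples of a record."""
    if clip_seconds < 0:
        raise ValueError("clip_seconds must be >= 0")
    k = int(round(clip_seconds * record.fs))
    if k == 0:
        return record
    if k >= len(record.samples):
        raise EmptyRecordError(
            f"clipping {clip_seconds} s removes all of record {record.name!r} "
            f"({record.duration:.1f} s)"
        )
    return replace(record, samples=record.samples[k:])


def segment_count(n_samples: int, window: int, step: int) -> int:
    """Number of complete windows: 0 below one window, else floor((n-w)/s)+1."""
    if n_samples < window:
        return 0
    return (n_samples - window) // step + 1


def segment_record(
    record: RecordFile,
    window_s: float = WINDOW_SECONDS,
    step_s: float = WINDOW_SECONDS,
    label: int = 0,
    normalize: bool = False,
) -> list[Segment]:
    """Cut a record into half-open windows ``[i*step, i*step + window)``.

    Windows are non-overlapping at the defaults (step = window = 9 s); a
    record shorter than one window yields an empty list; trailing partial
    windows are discarded.
    """
    if window_s <= 0 or step_s <= 0:
        raise ValueError("window_s and step_s must be > 0")
    w = int(round(window_s * record.fs))
    s = int(round(step_s * record.fs))
    x = np.asarray(record.samples)
    out = []
    for i in range(segment_count(len(x), w, s)):
        vals = x[i * s : i * s + w].astype(np.float32)
        if normalize:
            vals = normalize01(vals)
        out.append(Segment(vals, label, record.name, i * s))
    return out


def normalize01(x: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1] along the last axis; constant input -> zeros.

    A constant segment carries no morphology, and (x - min)/(max - min) is
    undefined for it, so it maps to all-zeros by convention.
    """
    x = np.asarray(x)
    lo = x.min(axis=-1, keepdims=True)
    hi = x.max(axis=-1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)
    return out.astype(x.dtype) if x.dtype.kind == "f" else out


def segment_records(
    records: list[RecordFile],
    labels: dict[str, int],
    window_s: float = WINDOW_SECONDS,
    step_s: float = WINDOW_SECONDS,
    clip_s: float = 0.0,
    normalize: bool = True,
) -> SegmentSet:
    """Clip, segment and (optionally) normalize a list of labeled records."""
    segments: list[Segment] = []
    for rec in records:
        if clip_s > 0:
            rec = clip_start(rec, clip_s)
        segments.extend(
            segment_record(rec, window_s, step_s, label=labels[rec.name], normalize=normalize)
        )
    return SegmentSet.from_segments(segments)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` (sums exactly)."""
    ideal = weights * total / weights.sum() if weights.sum() > 0 else np.zeros_like(weights)
    base = np.floor(ideal).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(ideal - base), kind="stable")
        base[order[:rem]] += 1
    return base


def stratified_split(
    segset: SegmentSet,
    test_fraction: float = 0.2,
    seed: int = 0,
    group_by_record: bool = False,
) -> tuple[SegmentSet, SegmentSet]:
    """Random stratified train/test partition of a segment population.

    With ``group_by_record=False`` (the default) segments split individually
    and the train size is exactly ``floor((1 - test_fraction) * n)``; with
    ``group_by_record=True`` whole records are assigned to one side, which
    avoids same-record segments leaking across the boundary at the cost of
    only approximate sizes.
    """
    if not 0 <= test_fraction < 1:
        raise ValueError("test_fraction must lie in [0, 1)")
    n = len(segset)
    if n == 0:
        raise ValueError("cannot split an empty segment set")
    rng = np.random.default_rng(seed)
    if group_by_record:
        names, first = np.unique(segset.sources.astype(str), return_index=True)
        rec_labels = segset.labels[first]
        test_names: set[str] = set()
        n_test_rec = int(round(test_fraction * len(names)))
        counts = np.array([np.sum(rec_labels == c) for c in (0, 1)], dtype=float)
        alloc = _largest_remainder(counts, n_test_rec)
        for c, n_c in zip((0, 1), alloc):
            pool = names[rec_labels == c]
            test_names.update(rng.permutation(pool)[:n_c])
        mask = np.array([s in test_names for s in segset.sources.astype(str)])
    else:
        n_train = int(np.floor((1 - test_fraction) * n))
        n_test = n - n_train
        counts = np.array([np.sum(segset.labels == c) for c in (0, 1)], dtype=float)
        alloc = _largest_remainder(counts, n_test)
        mask = np.zeros(n, dtype=bool)
        for c, n_c in zip((0, 1), alloc):
            idx = np.flatnonzero(segset.labels == c)
            mask[rng.permutation(idx)[:n_c]] = True
    return segset.select(~mask), segset.select(mask)


def make_folds(segset: SegmentSet, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified k-fold assignment: returns a fold id in [0, k) per segment.

    Every segment lands in exactly one fold, overall fold sizes differ by at
    most one, and each class is spread as evenly as possible (per-fold class
    counts within one of each other).
    """
    n = len(segset)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of segments ({n})")
    rng = np.random.default_rng(seed)
    fold_of = np.full(n, -1, dtype=np.int64)
    fold_sizes = np.zeros(k, dtype=int)
    for c in (0, 1):
        idx = rng.permutation(np.flatnonzero(segset.labels == c))
        n_c = len(idx)
        base, extra = divmod(n_c, k)
        per_fold = np.full(k, base, dtype=int)
        if extra:
            # Extras go to the currently smallest folds (stable tie-break),
            # keeping overall fold sizes within one of each other.
            smallest = np.argsort(fold_sizes, kind="stable")[:extra]
            per_fold[smallest] += 1
        pos = 0
        for f in range(k):
            fold_of[idx[pos : pos + per_fold[f]]] = f
            pos += per_fold[f]
        fold_sizes += per_fold
    return fold_of
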