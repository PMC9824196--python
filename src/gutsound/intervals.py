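"""Annotation algebra: interval tracks, the 10 ms unification rule,
multi-rater consensus, and interval <-> frame-label conversion.

Conventions
-----------
* Intervals are half-open ``[start_s, end_s)`` in seconds, so shared
  boundaries are never double-counted.
* Adjacent bowel-sound labels separated by at most ``gap_ms`` (10 ms by
  default) are merged into one event; wider gaps keep events independent.
* Consensus keeps the time points marked by at least ``min_raters`` raters,
  evaluated on a millisecond raster, then re-unifies.
* A frame inherits a positive label when bowel-sound intervals cover at
  least ``threshold`` (default half) of its span.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import LabelParseError, ValidationError
from .features import FrameGrid

BS_LABEL = "BS"
UNIFY_GAP_MS = 10.0


@dataclass(frozen=True, order=True)
class LabelInterval:
    """One labelled event span, half-open ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    label: str = BS_LABEL

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_s < self.end_s):
            raise ValidationError(
                f"interval ({self.start_s}, {self.end_s}): need 0 <= start < end"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class IntervalTrack:
    """A sorted list of labelled intervals over one clip.

    ``clip_duration_s`` may be None for tracks read from bare label files;
    operations that need a duration fall back to the last interval end.
    """

    intervals: Tuple[LabelInterval, ...]
    clip_duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        ivs = tuple(sorted(self.intervals, key=lambda iv: (iv.start_s, iv.end_s)))
        object.__setattr__(self, "intervals", ivs)
        if self.clip_duration_s is not None:
            if self.clip_duration_s <= 0:
                raise ValidationError("clip_duration_s: must be positive")
            for iv in ivs:
                if iv.end_s > self.clip_duration_s + 1e-9:
                    raise ValidationError(
                        f"interval ending at {iv.end_s} s exceeds clip duration "
                        f"{self.clip_duration_s} s"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def duration_s(self) -> float:
        if self.clip_duration_s is not None:
            return self.clip_duration_s
        return self.intervals[-1].end_s if self.intervals else 0.0

    def is_disjoint(self, tol: float = 1e-12) -> bool:
        return all(
            b.start_s >= a.end_s - tol
            for a, b in zip(self.intervals, self.intervals[1:])
        )

    def select(self, label: str = BS_LABEL) -> "IntervalTrack":
        return IntervalTrack(
            tuple(iv for iv in self.intervals if iv.label == label),
            clip_duration_s=self.clip_duration_s,
        )


@dataclass(frozen=True)
class FrameLabels:
    """Binary per-frame labels aligned to a :class:`FrameGrid`."""

    values: np.ndarray
    grid: FrameGrid
    positive_fraction_threshold: float = 0.5

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.uint8)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != self.grid.n_frames:
            raise ValidationError("values: length must equal grid.n_frames")
        if not (0.0 < self.positive_fraction_threshold <= 1.0):
            raise ValidationError("positive_fraction_threshold: must be in (0, 1]")

    def __len__(self) -> int:
        return len(self.values)


def unify_intervals(track: IntervalTrack, gap_ms: float = UNIFY_GAP_MS) -> IntervalTrack:
    """Merge adjacent labels separated by at most ``gap_ms`` milliseconds.

    The merge is transitive (a chain of small gaps collapses to one event);
    gaps strictly wider than ``gap_ms`` keep events independent. Idempotent.
    """
    gap_s = gap_ms / 1000.0
    merged: List[LabelInterval] = []
    for iv in track.intervals:
        if merged and iv.start_s - merged[-1].end_s <= gap_s:
            prev = merged[-1]
            merged[-1] = LabelInterval(
                prev.start_s, max(prev.end_s, iv.end_s), prev.label
            )
        else:
            merged.append(iv)
    return IntervalTrack(tuple(merged), clip_duration_s=track.clip_duration_s)


def _resolve_duration(tracks: Sequence[IntervalTrack]) -> float:
    stated = {t.clip_duration_s for t in tracks if t.clip_duration_s is not None}
    if len(stated) > 1:
        raise ValidationError(f"inconsistent clip durations across tracks: {sorted(stated)}")
    if stated:
        return stated.pop()
    return max((t.duration_s for t in tracks), default=0.0)


def rasterize(track: IntervalTrack, duration_s: float, resolution_ms: float = 1.0) -> np.ndarray:
    """Boolean occupancy vector of the track on a uniform raster."""
    res_s = resolution_ms / 1000.0
    n = int(round(duration_s / res_s))
    out = np.zeros(n, dtype=bool)
    for iv in track.intervals:
        a = int(round(iv.start_s / res_s))
        b = int(round(iv.end_s / res_s))
        out[max(a, 0) : min(b, n)] = True
    return out


def _runs_to_intervals(mask: np.ndarray, res_s: float, label: str) -> List[LabelInterval]:
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return [LabelInterval(a * res_s, b * res_s, label) for a, b in zip(starts, ends)]


def consensus(
    tracks: Sequence[IntervalTrack],
    min_raters: int = 2,
    grid_resolution_ms: float = 1.0,
    label: str = BS_LABEL,
) -> IntervalTrack:
    """Time spans marked by at least ``min_raters`` raters.

    Each rater track is rasterized at ``grid_resolution_ms``, votes are
    summed per raster cell, runs of cells with enough votes become intervals,
    and the 10 ms unification rule is applied to the result.

    With three raters the default ``min_raters=2`` implements majority
    agreement; pass ``min_raters=3`` for strict unanimity.
    """
    if min_raters < 1:
        raise ValidationError("min_raters: must be >= 1")
    if len(tracks) < min_raters:
        raise ValidationError(
            f"need at least min_raters={min_raters} tracks, got {len(tracks)}"
        )
    duration_s = _resolve_duration(tracks)
    res_s = grid_resolution_ms / 1000.0
    n = int(round(duration_s / res_s))
    votes = np.zeros(n, dtype=np.int32)
    for t in tracks:
        votes += rasterize(t.select(label), duration_s, grid_resolution_ms)
    mask = votes >= min_raters
    out = IntervalTrack(
        tuple(_runs_to_intervals(mask, res_s, label)),
        clip_duration_s=duration_s if n else None,
    )
    return unify_intervals(out)


def intervals_to_frame_labels(
    track: IntervalTrack, grid: FrameGrid, threshold: float = 0.5
) -> FrameLabels:
    """Frame ``i`` is positive iff intervals cover >= ``threshold`` of its span."""
    starts = grid.starts_s()
    ends = starts + grid.frame_length_s
    overlap = np.zeros(grid.n_frames)
    for iv in track.intervals:
        overlap += np.clip(
            np.minimum(ends, iv.end_s) - np.maximum(starts, iv.start_s), 0.0, None
        )
    # tiny tolerance so exact-threshold overlaps survive float rounding
    positive = overlap >= threshold * grid.frame_length_s - 1e-9
    return FrameLabels(
        values=positive.astype(np.uint8),
        grid=grid,
        positive_fraction_threshold=threshold,
    )


def frame_labels_to_intervals(
    labels: FrameLabels, grid: Optional[FrameGrid] = None, label: str = BS_LABEL
) -> IntervalTrack:
    """Maximal runs of positive frames -> intervals, then 10 ms unification.

    A run from frame ``a`` to frame ``b`` becomes
    ``[start(a), start(b) + frame_length)``.
    """
    grid = grid or labels.grid
    mask = labels.values.astype(bool)
    if not mask.any():
        return IntervalTrack((), clip_duration_s=grid.span_end_s)
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    out = []
    for a, b in zip(edges[0::2], edges[1::2]):
        start = grid.origin_s + a * grid.hop_s
        end = grid.origin_s + (b - 1) * grid.hop_s + grid.frame_length_s
        out.append(LabelInterval(start, end, label))
    return unify_intervals(
        IntervalTrack(tuple(out), clip_duration_s=grid.span_end_s)
    )


# ---------------------------------------------------------------------------
# Audacity label-track files: tab-separated "start<TAB>end<TAB>label" lines.

def read_label_track(path, clip_duration_s: Optional[float] = None) -> IntervalTrack:
    """Parse an Audacity label track (TSV, seconds).

    Zero-length point labels are skipped; ``start > end`` or non-numeric
    fields raise :class:`LabelParseError` with the line number.
    """
    path = Path(path)
    intervals: List[LabelInterval] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise LabelParseError(f"{path}:{lineno}: expected 'start<TAB>end<TAB>label'")
            try:
                start, end = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise LabelParseError(f"{path}:{lineno}: non-numeric time field") from exc
            if start > end:
                raise LabelParseError(f"{path}:{lineno}: start {start} > end {end}")
            if start == end:
                continue  # Audacity point label; carries no duration
            label = parts[2] if len(parts) > 2 and parts[2] else BS_LABEL
            intervals.append(LabelInterval(start, end, label))
    return IntervalTrack(tuple(intervals), clip_duration_s=clip_duration_s)


def write_label_track(track: IntervalTrack, path, decimals: int = 6) -> None:
    """Write an Audacity-compatible label track (>= 3 decimals of precision)."""
    if decimals < 3:
        raise ValidationError("decimals: need >= 3 for millisecond precision")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for iv in track.intervals:
            fh.write(f"{iv.start_s:.{decimals}f}\t{iv.end_s:.{decimals}f}\t{iv.label}\n")
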