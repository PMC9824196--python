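"""The featurized-dataset container shared by training and evaluation."""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .features import FrameGrid
from .intervals import IntervalTrack


@dataclass(frozen=True)
class ClipData:
    """One featurized recording: patches + frame labels + ground truth."""

    subject_id: str
    clip_id: str
    patches: np.ndarray  # [n_frames, height, width], float32
    labels: np.ndarray  # [n_frames], uint8
    truth: IntervalTrack
    grid: FrameGrid

    def __post_init__(self) -> None:
        if len(self.patches) != len(self.labels):
            raise ValidationError("patches and labels disagree on frame count")
        if len(self.patches) != self.grid.n_frames:
            raise ValidationError("patches do not match grid.n_frames")


FrameDataset = List[ClipData]


def stack_frames(clips: Sequence[ClipData]) -> Tuple[np.ndarray, np.ndarray]:
    """Concatenate patches and labels across clips for training."""
    if not clips:
        raise ValidationError("no clips to stack")
    x = np.concatenate([c.patches for c in clips], axis=0)
    y = np.concatenate([c.labels for c in clips], axis=0)
    return x, y


def subjects_of(clips: Sequence[ClipData]) -> List[str]:
    """Unique subject ids in first-appearance order."""
    seen: dict = {}
    for c in clips:
        seen.setdefault(c.subject_id, None)
    return list(seen)
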