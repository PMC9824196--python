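"""WAV audio I/O and canonicalization.

The pipeline's canonical format is mono float audio in [-1, 1] at 48 kHz
(the nominal smartphone recording rate). Arbitrary PCM WAV input is scaled
on read, averaged to mono if multi-channel, and can be resampled on ingest.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.io.wavfile
import scipy.signal

from .errors import AudioFormatError, EmptyAudioError, ValidationError

log = logging.getLogger(__name__)

CANONICAL_RATE_HZ = 48_000


@dataclass(frozen=True)
class AudioClip:
    """A mono recording plus the metadata needed to group it by subject.

    Parameters
    ----------
    samples
        Float waveform, values in [-1, 1].
    sample_rate_hz
        Sampling rate in Hz.
    subject_id, side, session
        Optional provenance: who recorded, which side of the abdomen
        (``left``/``right``) and which session (``morning``/``evening``).
    """

    samples: np.ndarray
    sample_rate_hz: int
    subject_id: str = ""
    side: Optional[str] = None
    session: Optional[str] = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValidationError("samples: need a non-empty 1-D waveform")
        if not np.isfinite(samples).all():
            raise ValidationError("samples: waveform contains non-finite values")
        peak = float(np.abs(samples).max())
        if peak > 1.0 + 1e-9:
            raise ValidationError(f"samples: peak amplitude {peak:.4g} exceeds full scale 1.0")
        if not (isinstance(self.sample_rate_hz, (int, np.integer)) and self.sample_rate_hz > 0):
            raise ValidationError("sample_rate_hz: must be a positive integer")
        if self.side not in (None, "left", "right"):
            raise ValidationError("side: must be 'left', 'right' or None")
        if self.session not in (None, "morning", "evening"):
            raise ValidationError("session: must be 'morning', 'evening' or None")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def with_metadata(self, **kwargs) -> "AudioClip":
        return replace(self, **kwargs)


def _scale_to_float(data: np.ndarray) -> np.ndarray:
    """Scale integer PCM to [-1, 1]; pass floats through."""
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32768.0
    if data.dtype == np.int32:
        return data.astype(np.float64) / 2147483648.0
    if data.dtype == np.uint8:
        return (data.astype(np.float64) - 128.0) / 128.0
    if data.dtype in (np.float32, np.float64):
        return data.astype(np.float64)
    raise AudioFormatError(f"unsupported WAV sample format: {data.dtype}")


def read_wav(path) -> AudioClip:
    """Read a RIFF/WAVE file into a canonical float :class:`AudioClip`.

    Multi-channel audio is averaged to mono (with a logged warning);
    metadata fields are left unset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = scipy.io.wavfile.read(str(path))
    except ValueError as exc:
        raise AudioFormatError(f"cannot decode {path}: {exc}") from exc
    if data.size == 0:
        raise EmptyAudioError(f"{path}: zero-length audio")
    samples = _scale_to_float(np.asarray(data))
    if samples.ndim == 2:
        log.warning("%s: averaging %d channels to mono", path, samples.shape[1])
        samples = samples.mean(axis=1)
    # 16/24/32-bit PCM full-scale negative values can map slightly below -1
    samples = np.clip(samples, -1.0, 1.0)
    return AudioClip(samples=samples, sample_rate_hz=int(rate))


def write_wav(path, clip: AudioClip, dtype: str = "pcm16") -> None:
    """Write a clip as mono WAV, either 16-bit PCM (default) or float32."""
    path = Path(path)
    if dtype == "pcm16":
        data = np.round(clip.samples * 32767.0).astype(np.int16)
    elif dtype == "float32":
        data = clip.samples.astype(np.float32)
    else:
        raise ValidationError(f"dtype: unknown WAV sample format {dtype!r}")
    scipy.io.wavfile.write(str(path), clip.sample_rate_hz, data)


def resample(clip: AudioClip, target_hz: int) -> AudioClip:
    """Band-limited resampling to ``target_hz``; identity when rates match."""
    if target_hz <= 0:
        raise ValidationError("target_hz: must be positive")
    if target_hz == clip.sample_rate_hz:
        return clip
    g = math.gcd(target_hz, clip.sample_rate_hz)
    up, down = target_hz // g, clip.sample_rate_hz // g
    samples = scipy.signal.resample_poly(clip.samples, up, down)
    samples = np.clip(samples, -1.0, 1.0)
    return AudioClip(
        samples=samples,
        sample_rate_hz=int(target_hz),
        subject_id=clip.subject_id,
        side=clip.side,
        session=clip.session,
    )


def canonicalize(clip: AudioClip, rate_hz: int = CANONICAL_RATE_HZ) -> AudioClip:
    """Resample to the pipeline's canonical rate (48 kHz by default)."""
    return resample(clip, rate_hz)
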