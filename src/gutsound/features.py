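"""Mel-spectrogram features on the detection frame grid.

A recording is cut into overlapping analysis frames (100 ms long, 25 ms hop,
i.e. 75% overlap), each frame is Hann-windowed and Fourier-transformed with
an FFT length equal to the frame (4800 samples at 48 kHz), and the power
spectrum is pooled onto a mel filterbank. The classifier consumes, per frame,
a small patch: ``height`` frequency bands aggregated from the mel axis by
``width`` consecutive frame columns centred on the target frame.

Bowel-sound energy concentrates in roughly 100-1000 Hz, so the default mel
range is 40-2000 Hz and the default band edges are 100/300/600/1000 Hz.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.fft
import scipy.signal

from .audio import AudioClip
from .errors import ConfigError, ValidationError

DEFAULT_FRAME_LENGTH_S = 0.100
DEFAULT_HOP_S = 0.025
DEFAULT_N_MELS = 40
DEFAULT_FMIN_HZ = 40.0
DEFAULT_FMAX_HZ = 2000.0
DEFAULT_DB_FLOOR = -80.0
DEFAULT_BAND_EDGES_HZ = (100.0, 300.0, 600.0, 1000.0)
DEFAULT_PATCH_WIDTH = 11


@dataclass(frozen=True)
class FrameGrid:
    """The shared frame timeline of features, labels and predictions.

    Frame ``i`` spans ``[origin_s + i*hop_s, origin_s + i*hop_s + frame_length_s)``
    and lies fully inside the clip.
    """

    n_frames: int
    frame_length_s: float = DEFAULT_FRAME_LENGTH_S
    hop_s: float = DEFAULT_HOP_S
    origin_s: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames: must be >= 1")
        if self.frame_length_s <= 0 or self.hop_s <= 0:
            raise ValidationError("frame_length_s/hop_s: must be positive")

    def frame_start_s(self, i) -> np.ndarray:
        return self.origin_s + np.asarray(i) * self.hop_s

    def starts_s(self) -> np.ndarray:
        return self.origin_s + np.arange(self.n_frames) * self.hop_s

    @property
    def span_end_s(self) -> float:
        """End time of the last frame."""
        return self.origin_s + (self.n_frames - 1) * self.hop_s + self.frame_length_s


def frame_signal(
    clip: AudioClip,
    frame_length_s: float = DEFAULT_FRAME_LENGTH_S,
    hop_s: float = DEFAULT_HOP_S,
) -> FrameGrid:
    """Lay the analysis frame grid over a clip.

    Counts are computed in integer samples so that a 60 s clip at the
    default 100 ms / 25 ms geometry yields exactly
    ``(2_880_000 - 4800) // 1200 + 1 = 2397`` frames.
    """
    frame_n = int(round(frame_length_s * clip.sample_rate_hz))
    hop_n = int(round(hop_s * clip.sample_rate_hz))
    if frame_n < 1 or hop_n < 1:
        raise ValidationError("frame/hop shorter than one sample")
    if len(clip.samples) < frame_n:
        raise ValidationError(
            f"clip of {clip.duration_s:.3f} s is shorter than one "
            f"{frame_length_s:.3f} s frame"
        )
    n_frames = (len(clip.samples) - frame_n) // hop_n + 1
    return FrameGrid(n_frames=n_frames, frame_length_s=frame_length_s, hop_s=hop_s)


def hz_to_mel(f_hz) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f_hz, dtype=np.float64) / 700.0)


def mel_to_hz(m) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft: int, sample_rate_hz: int, fmin_hz: float, fmax_hz: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Triangular mel filterbank with unit peak per row.

    Returns ``(weights [n_mels, n_fft//2+1], center_hz [n_mels])``.
    """
    if not 0 <= fmin_hz < fmax_hz <= sample_rate_hz / 2:
        raise ConfigError("mel range must satisfy 0 <= fmin < fmax <= Nyquist")
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate_hz)
    mel_pts = np.linspace(hz_to_mel(fmin_hz), hz_to_mel(fmax_hz), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    weights = np.zeros((n_mels, len(fft_freqs)))
    for i in range(n_mels):
        lo, center, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(center - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - center, 1e-12)
        weights[i] = np.clip(np.minimum(up, down), 0.0, None)
    return weights, hz_pts[1:-1]


@dataclass(frozen=True)
class MelSpectrogram:
    """dB-scaled mel power spectrogram on a :class:`FrameGrid`.

    ``values[m, t]`` is the mel power of band ``m`` in frame ``t``, in
    absolute dB (``10*log10(power)``), floored at ``db_floor`` dB below the
    per-file maximum. All-silent input maps to ``db_floor`` everywhere.
    """

    values: np.ndarray  # [n_mels, n_frames]
    grid: FrameGrid
    center_hz: np.ndarray  # [n_mels]
    sample_rate_hz: int
    n_fft: int
    n_mels: int = DEFAULT_N_MELS
    fmin_hz: float = DEFAULT_FMIN_HZ
    fmax_hz: float = DEFAULT_FMAX_HZ
    db_floor: float = DEFAULT_DB_FLOOR

    def __post_init__(self) -> None:
        if self.values.shape != (self.n_mels, self.grid.n_frames):
            raise ValidationError("values: shape must be [n_mels, n_frames]")
        if not np.isfinite(self.values).all():
            raise ValidationError("values: spectrogram contains non-finite entries")


def mel_spectrogram(
    clip: AudioClip,
    frame_length_s: float = DEFAULT_FRAME_LENGTH_S,
    hop_s: float = DEFAULT_HOP_S,
    n_fft: Optional[int] = None,
    n_mels: int = DEFAULT_N_MELS,
    fmin_hz: float = DEFAULT_FMIN_HZ,
    fmax_hz: float = DEFAULT_FMAX_HZ,
    db_floor: float = DEFAULT_DB_FLOOR,
) -> MelSpectrogram:
    """Hann-windowed STFT -> mel power -> dB, one column per grid frame.

    ``n_fft`` must equal the frame length in samples (4800 at the defaults);
    a mismatch is a configuration error rather than a silent zero-pad.
    """
    grid = frame_signal(clip, frame_length_s, hop_s)
    frame_n = int(round(frame_length_s * clip.sample_rate_hz))
    hop_n = int(round(hop_s * clip.sample_rate_hz))
    if n_fft is None:
        n_fft = frame_n
    if n_fft != frame_n:
        raise ConfigError(
            f"n_fft={n_fft} does not match the {frame_length_s*1e3:.0f} ms frame "
            f"({frame_n} samples at {clip.sample_rate_hz} Hz)"
        )

    x = np.ascontiguousarray(clip.samples, dtype=np.float64)
    frames = np.lib.stride_tricks.sliding_window_view(x, frame_n)[::hop_n][: grid.n_frames]
    window = scipy.signal.windows.hann(frame_n, sym=False)
    spec = scipy.fft.rfft(frames * window, n=n_fft, axis=1)
    power = spec.real**2 + spec.imag**2  # [n_frames, n_fft//2+1]

    fb, center_hz = mel_filterbank(n_mels, n_fft, clip.sample_rate_hz, fmin_hz, fmax_hz)
    mel_power = power @ fb.T  # [n_frames, n_mels]

    peak = float(mel_power.max())
    if peak <= 0.0:
        values = np.full((n_mels, grid.n_frames), db_floor)
    else:
        floor_abs = 10.0 * np.log10(peak) + db_floor
        with np.errstate(divide="ignore"):
            db = 10.0 * np.log10(mel_power)
        values = np.maximum(db, floor_abs).T
    return MelSpectrogram(
        values=values,
        grid=grid,
        center_hz=center_hz,
        sample_rate_hz=clip.sample_rate_hz,
        n_fft=n_fft,
        n_mels=n_mels,
        fmin_hz=fmin_hz,
        fmax_hz=fmax_hz,
        db_floor=db_floor,
    )


@dataclass(frozen=True)
class MelFrameTensor:
    """Per-frame classifier input patches.

    ``patches[t]`` is a ``height x width`` patch: frequency bands (rows) by
    time context columns centred on frame ``t``, standardized per patch to
    zero mean / unit variance (constant patches map to all zeros).
    """

    patches: np.ndarray  # [n_frames, height, width]
    band_edges_hz: Tuple[float, ...]
    grid: FrameGrid
    patch_mean: np.ndarray  # [n_frames] pre-standardization mean
    patch_std: np.ndarray  # [n_frames] pre-standardization std

    def __post_init__(self) -> None:
        if not np.isfinite(self.patches).all():
            raise ValidationError("patches: non-finite values")
        if self.patches.shape[0] != self.grid.n_frames:
            raise ValidationError("patches: first axis must match grid.n_frames")

    @property
    def height(self) -> int:
        return self.patches.shape[1]

    @property
    def width(self) -> int:
        return self.patches.shape[2]


def band_aggregate(spec: MelSpectrogram, band_edges_hz: Sequence[float]) -> np.ndarray:
    """Average mel rows into frequency bands; returns [n_bands, n_frames].

    Band ``b`` pools the mel bins whose centre frequency falls in
    ``[edge_b, edge_{b+1})``; an empty band is a configuration error.
    """
    edges = np.asarray(band_edges_hz, dtype=np.float64)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ConfigError("band_edges_hz must be ascending with >= 2 edges")
    if edges[0] < spec.fmin_hz - 1e-9 or edges[-1] > spec.fmax_hz + 1e-9:
        raise ConfigError(
            f"band edges must lie within the mel range "
            f"[{spec.fmin_hz:g}, {spec.fmax_hz:g}] Hz"
        )
    bands = []
    for b in range(len(edges) - 1):
        mask = (spec.center_hz >= edges[b]) & (spec.center_hz < edges[b + 1])
        if not mask.any():
            raise ConfigError(
                f"band [{edges[b]:g}, {edges[b+1]:g}) Hz contains no mel bins; "
                "increase n_mels or widen the band"
            )
        bands.append(spec.values[mask].mean(axis=0))
    return np.stack(bands)


def make_patches(
    spec: MelSpectrogram,
    height: int = len(DEFAULT_BAND_EDGES_HZ) - 1,
    width: int = DEFAULT_PATCH_WIDTH,
    band_edges_hz: Sequence[float] = DEFAULT_BAND_EDGES_HZ,
) -> MelFrameTensor:
    """Build the ``height x width`` classifier patches, one per frame.

    Edge frames are padded by replicating the first/last column so every
    frame gets a full-width patch.
    """
    if width % 2 != 1 or width < 1:
        raise ConfigError("width must be an odd positive integer (centred context)")
    if height != len(band_edges_hz) - 1:
        raise ConfigError("height must equal len(band_edges_hz) - 1")
    banded = band_aggregate(spec, band_edges_hz)  # [height, n_frames]
    half = width // 2
    padded = np.pad(banded, ((0, 0), (half, half)), mode="edge")
    # [height, n_frames, width] views of consecutive columns
    windows = np.lib.stride_tricks.sliding_window_view(padded, width, axis=1)
    patches = np.ascontiguousarray(windows.transpose(1, 0, 2))  # [n_frames, h, w]

    mean = patches.mean(axis=(1, 2))
    std = patches.std(axis=(1, 2))
    safe = np.where(std > 1e-12, std, 1.0)
    standardized = (patches - mean[:, None, None]) / safe[:, None, None]
    standardized[std <= 1e-12] = 0.0
    return MelFrameTensor(
        patches=standardized,
        band_edges_hz=tuple(float(e) for e in band_edges_hz),
        grid=spec.grid,
        patch_mean=mean,
        patch_std=std,
    )


def featurize(clip: AudioClip, **kwargs) -> MelFrameTensor:
    """Convenience: clip -> mel spectrogram -> patches with defaults."""
    patch_kwargs = {
        k: kwargs.pop(k) for k in ("height", "width", "band_edges_hz") if k in kwargs
    }
    return make_patches(mel_spectrogram(clip, **kwargs), **patch_kwargs)
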