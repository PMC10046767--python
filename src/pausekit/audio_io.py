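"""Audio reading, normalization, and framing.

Every downstream stage consumes an :class:`AudioSignal`: a mono float
waveform in [-1, 1] at the pipeline's canonical 44,100 Hz rate.  WAV
files of any PCM depth or sample rate are accepted; :func:`preprocess`
performs the channel downmix and band-limited resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

TARGET_RATE = 44_100
DEFAULT_FRAME_DURATION = 0.03

__all__ = [
    "AudioSignal",
    "CorpusManifest",
    "read_wav",
    "write_wav",
    "preprocess",
    "frame_audio",
    "read_manifest",
    "write_manifest",
]


class AudioDecodeError(ValueError):
    """Raised when an audio file cannot be decoded into samples."""


@dataclass
class AudioSignal:
    """A waveform with its sample rate.

    ``samples`` may be 1-D (mono) or 2-D ``(n_samples, n_channels)``
    before preprocessing; after :func:`preprocess` it is always 1-D
    float64 at 44,100 Hz.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise AudioDecodeError("audio signal has no samples")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.shape[0] / self.sample_rate


@dataclass
class CorpusManifest:
    """Maps recordings to subjects and (optionally) binary diagnosis labels.

    ``records`` is a DataFrame with columns ``subject_id, audio_path, label``;
    label is 0 (control), 1 (AD) or NaN for unlabeled recordings.
    """

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"subject_id", "audio_path", "label"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        ids = self.records["subject_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate subject_ids in manifest: {dupes}")
        labels = self.records["label"].dropna()
        if not labels.isin([0, 1]).all():
            raise ValueError("manifest labels must be 0 or 1 when present")


def _pcm_to_float(data: np.ndarray) -> np.ndarray:
    """Scale integer PCM to [-1, 1] float; floats pass through."""
    if np.issubdtype(data.dtype, np.floating):
        return data.astype(np.float64)
    info = np.iinfo(data.dtype)
    if info.min < 0:  # signed PCM (16/24-in-32/32 bit)
        return data.astype(np.float64) / -float(info.min)
    # 8-bit WAV is unsigned, midpoint 128
    return (data.astype(np.float64) - 128.0) / 128.0


def read_wav(path: str | Path) -> AudioSignal:
    """Read a WAV file into float samples in [-1, 1], preserving channels."""
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # pragma: no cover - message path
        raise AudioDecodeError(f"cannot read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise AudioDecodeError(f"WAV file {path!r} contains no samples")
    return AudioSignal(_pcm_to_float(data), int(rate))


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write as 16-bit PCM mono WAV (the pipeline's on-disk format)."""
    x = np.clip(signal.samples, -1.0, 1.0)
    if x.ndim != 1:
        x = x.mean(axis=1)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(path), signal.sample_rate, pcm)


def preprocess(raw: AudioSignal) -> AudioSignal:
    """Normalize a recording to mono 44,100 Hz.

    Stereo (or any multichannel) audio is downmixed by the arithmetic
    mean of channels; rate conversion uses a polyphase band-limited
    resampler.  Already-conformant audio is returned unchanged
    (idempotent, bit-for-bit).
    """
    x = raw.samples
    if x.ndim == 2:
        x = x.mean(axis=1)
    if raw.sample_rate != TARGET_RATE:
        g = math.gcd(raw.sample_rate, TARGET_RATE)
        x = resample_poly(x, TARGET_RATE // g, raw.sample_rate // g)
    if x.size == 0:
        raise AudioDecodeError("audio is empty after preprocessing")
    return AudioSignal(x, TARGET_RATE)


def frame_audio(signal: AudioSignal, frame_duration: float = DEFAULT_FRAME_DURATION) -> np.ndarray:
    """Cut a signal into non-overlapping frames.

    Returns an array of shape ``(n_frames, frame_len)`` where
    ``frame_len = floor(frame_duration * sample_rate)``.  The trailing
    remainder shorter than one frame is dropped, so
    ``n_frames = floor(duration / frame_duration)`` and the frames
    concatenate back to an exact prefix of the signal.
    """
    if frame_duration <= 0:
        raise ValueError(f"frame_duration must be positive, got {frame_duration}")
    if signal.samples.ndim != 1:
        raise ValueError("frame_audio requires mono audio; call preprocess first")
    frame_len = int(frame_duration * signal.sample_rate)
    n_frames = signal.samples.shape[0] // frame_len
    if n_frames == 0:
        raise ValueError(
            f"signal of {signal.duration:.4f} s is shorter than one "
            f"{frame_duration} s frame"
        )
    return signal.samples[: n_frames * frame_len].reshape(n_frames, frame_len)


def read_manifest(path: str | Path) -> CorpusManifest:
    df = pd.read_csv(path, dtype={"subject_id": str, "audio_path": str})
    if "label" not in df.columns:
        df["label"] = np.nan
    return CorpusManifest(df[["subject_id", "audio_path", "label"]])


def write_manifest(path: str | Path, manifest: CorpusManifest) -> None:
    out = manifest.records.copy()
    out["label"] = out["label"].astype("Int64")
    out.to_csv(path, index=False)
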