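"""Functional acoustic feature sets per 4 s segment.

Two standard paralinguistic sets are exposed: ComParE 2013 (6373
features) and eGeMAPS (88 features).  When the openSMILE toolkit is
installed its reference configurations are used directly.  In
environments without openSMILE a *surrogate* backend produces vectors
of the same published cardinality from deterministic spectral low-level
descriptors and statistical functionals.  Surrogate vectors are NOT
openSMILE features -- they are a synthetic stand-in that preserves the
set sizes and carries real spectral information so the comparison and
ensemble streams remain exercisable offline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.fft import dct
from scipy.stats import kurtosis, skew
from sklearn.preprocessing import StandardScaler

from .audio_io import AudioSignal

__all__ = [
    "FeatureSet",
    "FeatureVector",
    "FeatureExtractionError",
    "extract_features",
    "scale_features",
]


class FeatureSet(str, Enum):
    COMPARE_2013 = "compare"
    EGEMAPS = "egemaps"


#: Published sizes of the functional feature sets.
FEATURE_SET_SIZES = {FeatureSet.COMPARE_2013: 6373, FeatureSet.EGEMAPS: 88}

_N_BASE = 88  # 11 low-level descriptors x 8 functionals
_PROJECTION_SEED = 20130477  # fixed: the surrogate expansion is part of the format


class FeatureExtractionError(RuntimeError):
    pass


class OpenSmileUnavailableError(ImportError):
    pass


@dataclass
class FeatureVector:
    """One functional feature vector for one audio segment."""

    values: np.ndarray
    feature_set: FeatureSet
    subject_id: str = ""
    segment_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = FEATURE_SET_SIZES[FeatureSet(self.feature_set)]
        if self.values.shape != (expected,):
            raise ValueError(
                f"{self.feature_set} vector must have length {expected}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite after imputation")


# ---------------------------------------------------------------------------
# surrogate backend

def _mel_filterbank(n_mels: int, n_fft: int, sr: float) -> np.ndarray:
    """Triangular mel filters over rfft bins (standard HTK-style construction)."""

    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(sr / 2), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.fft.rfftfreq(n_fft, 1.0 / sr)
    fb = np.zeros((n_mels, bins.size))
    for i in range(n_mels):
        lo, mid, hi = hz_pts[i : i + 3]
        up = (bins - lo) / max(mid - lo, 1e-9)
        down = (hi - bins) / max(hi - mid, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _surrogate_llds(x: np.ndarray, sr: float) -> np.ndarray:
    """Frame-level descriptors, shape (n_frames, 11).

    Columns: log energy, zero-crossing rate, spectral centroid,
    bandwidth, 85% rolloff, flux, flatness, and 4 cepstral coefficients
    from a 26-band mel filterbank.
    """
    frame_len = int(0.025 * sr)
    hop = int(0.010 * sr)
    n = 1 + max(0, (x.size - frame_len)) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n)[:, None]
    frames = x[idx] * np.hanning(frame_len)

    spec = np.abs(np.fft.rfft(frames, axis=1))
    power = spec**2
    freqs = np.fft.rfftfreq(frame_len, 1.0 / sr)
    tot = power.sum(axis=1) + 1e-12

    log_e = 10.0 * np.log10(tot)
    zcr = np.mean(np.abs(np.diff(np.signbit(frames), axis=1)), axis=1)
    centroid = (power * freqs).sum(axis=1) / tot
    bandwidth = np.sqrt((power * (freqs[None, :] - centroid[:, None]) ** 2).sum(axis=1) / tot)
    cum = np.cumsum(power, axis=1)
    rolloff = freqs[np.argmax(cum >= 0.85 * cum[:, -1:], axis=1)]
    flux = np.r_[0.0, np.sqrt(((np.diff(spec, axis=0)) ** 2).sum(axis=1))]
    flatness = np.exp(np.mean(np.log(power + 1e-12), axis=1)) / (power.mean(axis=1) + 1e-12)

    fb = _mel_filterbank(26, frame_len, sr)
    logmel = np.log(power @ fb.T + 1e-12)
    ceps = dct(logmel, type=2, axis=1, norm="ortho")[:, 1:5]

    return np.column_stack([log_e, zcr, centroid, bandwidth, rolloff, flux, flatness, ceps])


def _functionals(llds: np.ndarray) -> np.ndarray:
    """Eight statistics per descriptor: mean, std, skew, kurtosis, min, max, median, slope."""
    t = np.arange(llds.shape[0])
    tc = t - t.mean()
    denom = (tc**2).sum() or 1.0
    slope = (tc[:, None] * (llds - llds.mean(axis=0))).sum(axis=0) / denom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skew/kurtosis warn on constant columns
        stats = [
            llds.mean(axis=0),
            llds.std(axis=0),
            skew(llds, axis=0),
            kurtosis(llds, axis=0),
            llds.min(axis=0),
            llds.max(axis=0),
            np.median(llds, axis=0),
            slope,
        ]
    return np.concatenate(stats)


_projection_cache: dict[int, np.ndarray] = {}


def _expansion_matrix(n_out: int) -> np.ndarray:
    if n_out not in _projection_cache:
        rng = np.random.default_rng(_PROJECTION_SEED)
        _projection_cache[n_out] = rng.standard_normal((n_out, _N_BASE)) / np.sqrt(_N_BASE)
    return _projection_cache[n_out]


def _extract_surrogate(audio: AudioSignal, feature_set: FeatureSet) -> np.ndarray:
    base = _functionals(_surrogate_llds(audio.samples, audio.sample_rate))
    if feature_set is FeatureSet.EGEMAPS:
        vec = base
    else:
        extra = _expansion_matrix(FEATURE_SET_SIZES[feature_set] - _N_BASE) @ base
        vec = np.concatenate([base, extra])
    return vec


# ---------------------------------------------------------------------------
# openSMILE backend

_SMILE_NAMES = {FeatureSet.COMPARE_2013: "ComParE_2016", FeatureSet.EGEMAPS: "eGeMAPSv02"}


def _extract_opensmile(audio: AudioSignal, feature_set: FeatureSet) -> np.ndarray:
    try:
        import opensmile
    except ImportError as exc:
        raise OpenSmileUnavailableError(
            "the openSMILE toolkit is not installed; run `pip install opensmile` "
            "or use backend='surrogate'"
        ) from exc
    smile = opensmile.Smile(
        feature_set=getattr(opensmile.FeatureSet, _SMILE_NAMES[feature_set]),
        feature_level=opensmile.FeatureLevel.Functionals,
    )
    df = smile.process_signal(audio.samples, audio.sample_rate)
    return df.to_numpy().ravel()


def extract_features(
    segment_audio: AudioSignal,
    feature_set: FeatureSet | str,
    subject_id: str = "",
    segment_index: int = 0,
    backend: str = "auto",
) -> FeatureVector:
    """Extract one functional feature vector from a segment of audio.

    ``backend`` is ``"opensmile"``, ``"surrogate"`` or ``"auto"`` (use
    openSMILE when importable, fall back to the surrogate otherwise).
    Non-finite outputs are imputed to 0 with a warning.
    """
    feature_set = FeatureSet(feature_set)
    if segment_audio.duration < 0.1:
        raise FeatureExtractionError(
            f"segment of {segment_audio.duration:.3f} s is too short (minimum 0.1 s)"
        )
    if backend == "auto":
        try:
            import opensmile  # noqa: F401

            backend = "opensmile"
        except ImportError:
            backend = "surrogate"
    if backend == "opensmile":
        values = _extract_opensmile(segment_audio, feature_set)
    elif backend == "surrogate":
        values = _extract_surrogate(segment_audio, feature_set)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    bad = ~np.isfinite(values)
    if bad.any():
        warnings.warn(f"imputed {bad.sum()} non-finite feature values to 0", stacklevel=2)
        values = np.where(bad, 0.0, values)
    return FeatureVector(values, feature_set, subject_id, segment_index)


def scale_features(
    train: np.ndarray, apply_to: np.ndarray | None = None
) -> tuple[np.ndarray, StandardScaler]:
    """Z-score features using statistics of the training rows only.

    Constant training features map to 0 everywhere.  Returns the scaled
    ``apply_to`` matrix (defaults to ``train``) and the fitted scaler.
    """
    train = np.asarray(train, dtype=np.float64)
    if train.size == 0:
        raise ValueError("train matrix must be nonempty")
    scaler = StandardScaler().fit(train)
    target = train if apply_to is None else np.asarray(apply_to, dtype=np.float64)
    return scaler.transform(target), scaler
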