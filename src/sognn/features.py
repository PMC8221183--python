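"""Band-wise differential-entropy / power features from multichannel EEG.

The pipeline mirrors the SEED-style preprocessing convention: non-overlapped
1-s Hanning windows, a 512-point FFT, band powers summed over the five
classical bands (delta 1-3 Hz, theta 4-7 Hz, alpha 8-13 Hz, beta 14-30 Hz,
gamma 31-50 Hz), differential entropy as the Gaussian log-variance form,
zero-padding of variable-length trials to a common frame count, and
per-subject standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "EEGRecording",
    "BandFeatureTensor",
    "stft_band_power",
    "differential_entropy",
    "extract_features",
    "pad_features",
    "normalize_per_subject",
    "subject_statistics",
    "apply_statistics",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with inclusive bounds in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not (0 < self.lo <= self.hi):
            raise ValueError(f"band {self.name}: need 0 < lo <= hi, got [{self.lo}, {self.hi}]")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 3.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 14.0, 30.0),
    BandDefinition("gamma", 31.0, 50.0),
)


@dataclass
class EEGRecording:
    """Raw multichannel EEG trial: ``signal`` is channels x samples (uV)."""

    signal: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = ""
    trial_id: str = ""
    label: int = -1

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.shape[0] < 1:
            raise ValueError("need at least one channel")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.signal.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class BandFeatureTensor:
    """Electrodes x bands x frames feature array with trial metadata.

    ``valid_T`` is the frame count before zero padding; frames at or beyond
    ``valid_T`` are exactly zero.
    """

    values: np.ndarray
    feature_kind: str = "de"
    frame_seconds: float = 1.0
    subject_id: str = ""
    trial_id: str = ""
    label: int = -1
    valid_T: int = field(default=-1)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be electrodes x bands x frames")
        if self.valid_T < 0:
            self.valid_T = self.values.shape[2]
        if self.valid_T > self.values.shape[2]:
            raise ValueError("valid_T exceeds frame count")

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]


def stft_band_power(
    rec: EEGRecording,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    nfft: int = 512,
    window_seconds: float = 1.0,
) -> np.ndarray:
    """Per-band spectral power in non-overlapping Hanning windows.

    Each window of ``window_seconds`` is tapered, zero-padded to ``nfft``
    points and periodogram power is summed over the FFT bins whose frequency
    f satisfies lo <= f <= hi, normalized by the window energy sum(w^2).
    Returns channels x bands x frames, all entries >= 0.
    """
    win_len = int(round(rec.fs * window_seconds))
    if rec.n_samples < win_len:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{win_len}-sample window"
        )
    if nfft < win_len:
        raise ValueError(f"nfft={nfft} smaller than window of {win_len} samples")
    nyquist = rec.fs / 2.0
    for b in bands:
        if b.hi > nyquist:
            raise ValueError(f"band {b.name} ([{b.lo},{b.hi}] Hz) exceeds Nyquist {nyquist} Hz")

    n_frames = rec.n_samples // win_len
    window = np.hanning(win_len)
    norm = float(np.sum(window**2))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rec.fs)

    frames = rec.signal[:, : n_frames * win_len].reshape(rec.n_channels, n_frames, win_len)
    spec = np.fft.rfft(frames * window, n=nfft, axis=-1)
    psd = np.abs(spec) ** 2 / norm  # channels x frames x bins

    out = np.empty((rec.n_channels, len(bands), n_frames))
    for bi, b in enumerate(bands):
        members = (freqs >= b.lo) & (freqs <= b.hi)
        if not members.any():
            raise ValueError(f"band {b.name} contains no FFT bins at nfft={nfft}, fs={rec.fs}")
        out[:, bi, :] = psd[:, :, members].sum(axis=-1)
    return out


def differential_entropy(band_power: np.ndarray, epsilon: float = 1e-12) -> np.ndarray:
    """Gaussian differential entropy 0.5*ln(2*pi*e*(P + epsilon)).

    Band power acts as the variance estimate; natural log throughout, so a
    4x power increase raises every entry by ln 4.
    """
    band_power = np.asarray(band_power, dtype=np.float64)
    if np.any(band_power < 0):
        raise ValueError("band power must be nonnegative")
    return 0.5 * np.log(2.0 * np.pi * np.e * (band_power + epsilon))


def extract_features(
    rec: EEGRecording,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    feature_kind: str = "de",
    nfft: int = 512,
    window_seconds: float = 1.0,
    epsilon: float = 1e-12,
) -> BandFeatureTensor:
    """Full extraction: STFT band power, then DE (or raw PSD band power)."""
    power = stft_band_power(rec, bands, nfft=nfft, window_seconds=window_seconds)
    if feature_kind == "de":
        values = differential_entropy(power, epsilon=epsilon)
    elif feature_kind == "psd":
        values = power
    else:
        raise ValueError(f"unknown feature kind {feature_kind!r}")
    return BandFeatureTensor(
        values=values,
        feature_kind=feature_kind,
        frame_seconds=window_seconds,
        subject_id=rec.subject_id,
        trial_id=rec.trial_id,
        label=rec.label,
        valid_T=values.shape[2],
    )


def pad_features(feat: BandFeatureTensor, target_T: int) -> BandFeatureTensor:
    """Append zero frames so the tensor has exactly ``target_T`` frames."""
    if feat.valid_T > target_T:
        raise ValueError(
            f"trial {feat.trial_id!r} has {feat.valid_T} frames > target {target_T}; "
            "refusing to truncate"
        )
    if feat.n_frames == target_T:
        return feat
    n, b, t = feat.values.shape
    values = np.zeros((n, b, target_T))
    values[:, :, :t] = feat.values
    return replace(feat, values=values)


def subject_statistics(
    samples: list[BandFeatureTensor],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-subject mean/std over valid frames, one value per electrode-band."""
    by_subject: dict[str, list[BandFeatureTensor]] = {}
    for s in samples:
        by_subject.setdefault(s.subject_id, []).append(s)
    stats = {}
    for sid, group in by_subject.items():
        pooled = np.concatenate([s.values[:, :, : s.valid_T] for s in group], axis=2)
        mean = pooled.mean(axis=2)
        std = pooled.std(axis=2)
        bad = np.argwhere(std == 0)
        if bad.size:
            e, b = bad[0]
            raise ValueError(
                f"zero variance for subject {sid!r}, electrode {e}, band {b}: "
                "cannot standardize"
            )
        stats[sid] = (mean, std)
    return stats


def apply_statistics(
    samples: list[BandFeatureTensor],
    stats: dict[str, tuple[np.ndarray, np.ndarray]],
) -> list[BandFeatureTensor]:
    """Standardize each sample with the given per-subject statistics.

    Padded frames are excluded and re-zeroed so they never leak into the
    valid data or the statistics of later stages.
    """
    out = []
    for s in samples:
        mean, std = stats[s.subject_id]
        values = np.zeros_like(s.values)
        values[:, :, : s.valid_T] = (
            s.values[:, :, : s.valid_T] - mean[:, :, None]
        ) / std[:, :, None]
        out.append(replace(s, values=values))
    return out


def normalize_per_subject(samples: list[BandFeatureTensor]) -> list[BandFeatureTensor]:
    """Standardize every subject independently (each to mean 0, std 1).

    This is the dataset-wide convention: the held-out subject of a LOSO fold
    is normalized with its own statistics too.  For a leakage-free variant
    compute statistics on training subjects only via ``subject_statistics``
    and apply them with ``apply_statistics``.
    """
    return apply_statistics(samples, subject_statistics(samples))
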