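"""Band coherence features from multichannel EEG.

Pipeline per subject: zero-phase band-pass (0.15-30 Hz), segmentation
into 650 ms windows with 50% overlap, Hann-tapered Welch auto/cross
spectra, magnitude-squared coherence

    msc(f) = |Pxy(f)|^2 / (Pxx(f) Pyy(f)),

band averaging over delta/theta/alpha, and a Fisher-Z variance
stabilization z = atanh(sqrt(msc)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .montage import DEFAULT_BANDS, DEFAULT_PAIRS, BandDefinition, feature_name
from .synthetic import EEGRecording

__all__ = [
    "SpectralEstimate",
    "CoherenceSpectrum",
    "FeatureConfig",
    "CoherenceFeatureMatrix",
    "bandpass",
    "segment",
    "spectral_estimates",
    "magnitude_squared_coherence",
    "band_coherence",
    "fisher_z",
    "build_feature_matrix",
]


@dataclass
class SpectralEstimate:
    """Welch-averaged one-sided auto/cross power spectral densities."""

    freqs: np.ndarray
    Pxx: np.ndarray
    Pyy: np.ndarray
    Pxy: np.ndarray  # complex
    n_segments: int


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    msc: np.ndarray


@dataclass
class FeatureConfig:
    """Settings for feature extraction.

    ``z_convention``: "sqrt" applies atanh(sqrt(msc)) (the convention for
    magnitude-squared coherence); "direct" applies atanh(msc).
    """

    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    bp_lo: float = 0.15
    bp_hi: float = 30.0
    win_ms: float = 650.0
    overlap: float = 0.5
    z_convention: str = "sqrt"


@dataclass
class CoherenceFeatureMatrix:
    """Subjects x (pair, band) Fisher-Z band coherences."""

    values: np.ndarray
    feature_names: list[str]
    labels: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.feature_names)):
            raise ValueError("values shape does not match names/labels")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CoherenceFeatureMatrix":
        feats = [c for c in df.columns if c not in ("subject_id", "label")]
        return cls(
            df[feats].to_numpy(float),
            feats,
            df["label"].astype(str).tolist(),
            df["subject_id"].astype(str).tolist(),
        )


def bandpass(rec: EEGRecording, lo: float = 0.15, hi: float = 30.0) -> EEGRecording:
    """Zero-phase Butterworth band-pass applied per channel."""
    nyq = rec.fs / 2
    if not 0 <= lo < hi:
        raise ValueError("need 0 <= lo < hi")
    if hi >= nyq:
        raise ValueError(f"hi={hi} must be below the Nyquist frequency {nyq}")
    if lo == 0:
        sos = signal.butter(4, hi, btype="lowpass", fs=rec.fs, output="sos")
    else:
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(out, rec.fs, rec.channels, rec.subject_id, rec.label)


def segment(
    x: np.ndarray, fs: float, win_ms: float = 650.0, overlap: float = 0.5
) -> np.ndarray:
    """Split a 1-D signal into full-length overlapping windows.

    Window length = floor(win_ms * fs / 1000) samples; hop = floor of
    (1 - overlap) of that; the trailing remainder is discarded.
    """
    x = np.asarray(x, float)
    win = int(np.floor(win_ms * fs / 1000.0))
    hop = int(np.floor(win * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("overlap too large: empty hop")
    if x.size < win:
        raise ValueError(f"signal ({x.size}) shorter than one window ({win})")
    return np.lib.stride_tricks.sliding_window_view(x, win)[::hop].copy()


def _windowed_fft(windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-detrend, Hann-taper and rFFT each window; returns (F, taper)."""
    w = signal.get_window("hann", windows.shape[1])
    d = windows - windows.mean(axis=1, keepdims=True)
    return np.fft.rfft(d * w, axis=1), w


def _cross_density(Fx: np.ndarray, Fy: np.ndarray, w: np.ndarray, fs: float,
                   nper: int) -> np.ndarray:
    scale = 1.0 / (fs * (w**2).sum())
    P = (np.conj(Fx) * Fy).mean(axis=0) * scale
    # one-sided density: double all bins except DC (and Nyquist if present)
    P = P * 2.0
    P[..., 0] /= 2.0
    if nper % 2 == 0:
        P[..., -1] /= 2.0
    return P


def spectral_estimates(
    x_windows: np.ndarray, y_windows: np.ndarray, fs: float
) -> SpectralEstimate:
    """Welch auto/cross spectra from pre-segmented signals."""
    if x_windows.shape != y_windows.shape:
        raise ValueError("x and y must have identical segmentation")
    L, nper = x_windows.shape
    Fx, w = _windowed_fft(x_windows)
    Fy, _ = _windowed_fft(y_windows)
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    Pxx = _cross_density(Fx, Fx, w, fs, nper).real
    Pyy = _cross_density(Fy, Fy, w, fs, nper).real
    Pxy = _cross_density(Fx, Fy, w, fs, nper)
    return SpectralEstimate(freqs, Pxx, Pyy, Pxy, L)


def magnitude_squared_coherence(est: SpectralEstimate) -> CoherenceSpectrum:
    """msc(f) = |Pxy|^2 / (Pxx Pyy), clipped to [0, 1].

    Requires at least two averaged segments: the single-segment estimate
    is identically 1 and carries no information.
    """
    if est.n_segments < 2:
        raise ValueError("MSC needs >= 2 averaged segments (1-segment MSC is 1)")
    denom = est.Pxx * est.Pyy
    msc = np.zeros_like(est.Pxx)
    ok = denom > 0
    msc[ok] = np.abs(est.Pxy[ok]) ** 2 / denom[ok]
    return CoherenceSpectrum(est.freqs, np.clip(msc, 0.0, 1.0))


def band_coherence(cs: CoherenceSpectrum, band: BandDefinition) -> float:
    """Arithmetic mean of MSC over bins with lo <= f <= hi."""
    sel = (cs.freqs >= band.lo) & (cs.freqs <= band.hi)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band {band.name}")
    return float(cs.msc[sel].mean())


def fisher_z(c: float, convention: str = "sqrt", clamp: bool = False) -> float:
    """Fisher-Z transform of a coherence value in [0, 1)."""
    if c < 0:
        raise ValueError("coherence must be non-negative")
    if c >= 1:
        if not clamp:
            raise ValueError("coherence must be < 1 (set clamp=True to saturate)")
        c = 1.0 - 1e-12
    if convention == "sqrt":
        return float(np.arctanh(np.sqrt(c)))
    if convention == "direct":
        return float(np.arctanh(c))
    raise ValueError(f"unknown Fisher-Z convention {convention!r}")


def _subject_features(rec: EEGRecording, cfg: FeatureConfig) -> np.ndarray:
    filtered = bandpass(rec, cfg.bp_lo, cfg.bp_hi)
    needed = sorted({ch for pair in cfg.pairs for ch in pair})
    missing = [ch for ch in needed if ch not in rec.channels]
    if missing:
        raise ValueError(f"recording {rec.subject_id} missing electrodes {missing}")
    windows = {
        ch: segment(filtered.channel(ch), rec.fs, cfg.win_ms, cfg.overlap)
        for ch in needed
    }
    row = np.empty(len(cfg.pairs) * len(cfg.bands))
    j = 0
    for pair in cfg.pairs:
        est = spectral_estimates(windows[pair[0]], windows[pair[1]], rec.fs)
        cs = magnitude_squared_coherence(est)
        for band in cfg.bands:
            row[j] = fisher_z(band_coherence(cs, band), cfg.z_convention, clamp=True)
            j += 1
    return row


def build_feature_matrix(
    cohort: list[EEGRecording], config: FeatureConfig | None = None
) -> CoherenceFeatureMatrix:
    """Fisher-Z band coherence features for a cohort.

    Features are ordered pair-major then band, matching the montage
    ordering (left intra, right intra, inter) x (delta, theta, alpha).
    """
    cfg = config or FeatureConfig()
    names = [feature_name(p, b) for p in cfg.pairs for b in cfg.bands]
    values = np.vstack([_subject_features(r, cfg) for r in cohort])
    return CoherenceFeatureMatrix(
        values, names, [r.label for r in cohort], [r.subject_id for r in cohort]
    )
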