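"""Synthetic resting-state EEG cohorts with class-dependent coherence.

Generative model
----------------
Each recording is a sum, over the analysis bands, of band-limited white
noise that is independent per channel, plus band-limited *shared* sources:

* an optional per-band background source injected into every channel
  (sets a floor coherence common to both classes), and
* one source per planted effect, injected with unit gain into both
  electrodes of its pair.

Band limiting uses an ideal (FFT brickwall) filter so that source and
noise have identical spectral shape and adjacent bands do not leak into
each other: inside a band the spectral-density ratio is a constant equal
to the variance ratio, and the band magnitude-squared coherence (MSC)
of a pair has the closed form implemented in
:func:`analytic_pair_coherence`. Source variances are solved from that
closed form so that the expected band MSC equals the class target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import BAND_BY_NAME, CHANNELS_1020, DEFAULT_PAIRS, BandDefinition

__all__ = [
    "EEGRecording",
    "CohortEffect",
    "CohortSpec",
    "analytic_pair_coherence",
    "synthesize_recording",
    "generate_cohort",
]


@dataclass
class EEGRecording:
    """One subject's multichannel EEG (channels x samples)."""

    data: np.ndarray
    fs: float
    channels: tuple[str, ...]
    subject_id: str
    label: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel count does not match data rows")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError as exc:
            raise KeyError(f"channel {name!r} not in recording") from exc


@dataclass(frozen=True)
class CohortEffect:
    """A planted coherence effect: one electrode pair, one band, one MSC
    target per class (keyed by class label)."""

    pair: tuple[str, str]
    band: str
    targets: dict[str, float]

    def target_for(self, label: str) -> float:
        return self.targets[label]


def _default_effects(classes: tuple[str, str]) -> tuple[CohortEffect, ...]:
    """Five planted pair-band effects, MSC 0.6 vs 0.2 between classes.

    Within each band the planted pairs share no electrode, so each
    effect's shared source leaks into no other planted feature.
    """
    a, b = classes
    t = {a: 0.6, b: 0.2}
    return (
        CohortEffect(("F3", "C3"), "alpha", dict(t)),
        CohortEffect(("P4", "T6"), "alpha", dict(t)),
        CohortEffect(("C3", "C4"), "theta", dict(t)),
        CohortEffect(("P3", "T5"), "theta", dict(t)),
        CohortEffect(("F3", "F4"), "delta", dict(t)),
    )


@dataclass
class CohortSpec:
    """Recipe for a two-class synthetic cohort.

    Defaults emulate a clinical-scale recording campaign: 46 + 55
    subjects, 19-channel 10/20 montage, 250 Hz, 3 minutes eyes-closed
    rest, five planted pair-band coherence effects (MSC 0.6 vs 0.2).
    """

    classes: tuple[str, str] = ("BD", "MDD")
    n_per_class: tuple[int, int] = (46, 55)
    fs: float = 250.0
    duration_s: float = 180.0
    effect_map: tuple[CohortEffect, ...] | None = None
    background_coherence: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    channels: tuple[str, ...] = CHANNELS_1020
    bands: tuple[BandDefinition, ...] = field(
        default_factory=lambda: tuple(BAND_BY_NAME.values()))

    def __post_init__(self) -> None:
        if self.effect_map is None:
            self.effect_map = _default_effects(self.classes)
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("each class needs at least one subject")
        if not 0 <= self.background_coherence < 1:
            raise ValueError("background_coherence must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        n_samp = self.duration_s * self.fs
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("duration_s * fs must be an integer sample count")
        band_names = {b.name for b in self.bands}
        montage_pairs = set(DEFAULT_PAIRS)
        for eff in self.effect_map:
            if eff.band not in band_names:
                raise ValueError(f"unknown band {eff.band!r}")
            if eff.pair not in montage_pairs:
                raise ValueError(f"pair {eff.pair} not in the montage pair list")
            for lab, c in eff.targets.items():
                if lab not in self.classes:
                    raise ValueError(f"effect target for unknown class {lab!r}")
                if not 0 <= c < 1:
                    raise ValueError("target coherence must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def analytic_pair_coherence(
    source_var: float,
    gain_x: float,
    gain_y: float,
    noise_var_x: float,
    noise_var_y: float,
) -> float:
    """Exact MSC of two channels sharing one white source plus
    independent white noise:

        msc = (gx*gy*s)^2 / ((gx^2 s + nx)(gy^2 s + ny))

    Constant across frequency when source and noise share the same
    spectral shape, hence equal to the band-averaged MSC.
    """
    if source_var < 0 or noise_var_x < 0 or noise_var_y < 0:
        raise ValueError("variances must be non-negative")
    px = gain_x**2 * source_var + noise_var_x
    py = gain_y**2 * source_var + noise_var_y
    if px == 0 or py == 0:
        raise ValueError("zero total variance on a channel: MSC undefined")
    return (gain_x * gain_y * source_var) ** 2 / (px * py)


def _shared_variance_for_target(c: float, noise_var: float) -> float:
    """Shared-source variance giving band MSC ``c`` against independent
    noise of variance ``noise_var`` (unit gains): from the closed form,
    msc = (s/(s+n))^2  =>  s = n*sqrt(c)/(1-sqrt(c))."""
    r = np.sqrt(c)
    return noise_var * r / (1.0 - r)


def _brickwall(x: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Ideal zero-phase band-limit along the last axis: zero every FFT
    bin outside [lo, hi]. Keeps the source/noise density ratio exact at
    every retained frequency."""
    n = x.shape[-1]
    F = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    F[..., (f < band.lo) | (f > band.hi)] = 0.0
    return np.fft.irfft(F, n=n, axis=-1)


def synthesize_recording(
    spec: CohortSpec, label: str, seed: int, subject_id: str = "S000"
) -> EEGRecording:
    """Generate one subject. Deterministic given ``seed``."""
    if label not in spec.classes:
        raise ValueError(f"label {label!r} not one of {spec.classes}")
    rng = np.random.default_rng(seed)
    n_ch, n = len(spec.channels), spec.n_samples
    idx = {ch: i for i, ch in enumerate(spec.channels)}
    noise_var = spec.noise_sd**2
    bg_var = (
        _shared_variance_for_target(spec.background_coherence, noise_var)
        if spec.background_coherence > 0 else 0.0
    )
    data = np.zeros((n_ch, n))
    for band in spec.bands:
        raw = rng.normal(0.0, spec.noise_sd, size=(n_ch, n))
        if bg_var > 0:
            raw += np.sqrt(bg_var) * rng.normal(size=n)
        for eff in spec.effect_map:
            if eff.band != band.name:
                continue
            c = eff.target_for(label)
            shared = _shared_variance_for_target(c, noise_var)
            src_var = shared - bg_var
            if src_var < 0:
                raise ValueError(
                    f"effect target {c} below background coherence for {eff.pair}")
            if src_var > 0:
                src = np.sqrt(src_var) * rng.normal(size=n)
                data_rows = (idx[eff.pair[0]], idx[eff.pair[1]])
                raw[data_rows[0]] += src
                raw[data_rows[1]] += src
        data += _brickwall(raw, band, spec.fs)
    return EEGRecording(data, spec.fs, tuple(spec.channels), subject_id, label)


def generate_cohort(spec: CohortSpec) -> list[EEGRecording]:
    """Generate the full cohort; bit-identical for equal (spec, seed)."""
    master = np.random.default_rng(spec.seed)
    total = sum(spec.n_per_class)
    seeds = master.integers(0, 2**31, size=total)
    recs: list[EEGRecording] = []
    k = 0
    for label, n_sub in zip(spec.classes, spec.n_per_class):
        for _ in range(n_sub):
            recs.append(
                synthesize_recording(spec, label, int(seeds[k]), f"S{k + 1:03d}"))
            k += 1
    return recs
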