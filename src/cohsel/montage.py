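"""10/20 montage, electrode-pair list and frequency bands used throughout.

The coherence montage evaluates intrahemispheric synchronization on six
left- and six right-hemisphere pairs and interhemispheric synchronization
on four homologous pairs (temporal pair taken as T7-T8).
"""

from __future__ import annotations

from dataclasses import dataclass

#: 19-electrode 10/20 set. T7/T8 are the modern central-temporal names;
#: T5/T6 (posterior-temporal, modern P7/P8) are kept under their classic
#: names because the pair list below refers to them.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

LEFT_INTRA_PAIRS: tuple[tuple[str, str], ...] = (
    ("F3", "C3"), ("F3", "P3"), ("F3", "T5"),
    ("C3", "P3"), ("C3", "T5"), ("P3", "T5"),
)
RIGHT_INTRA_PAIRS: tuple[tuple[str, str], ...] = (
    ("F4", "C4"), ("F4", "P4"), ("F4", "T6"),
    ("C4", "P4"), ("C4", "T6"), ("P4", "T6"),
)
INTER_PAIRS: tuple[tuple[str, str], ...] = (
    ("F3", "F4"), ("C3", "C4"), ("P3", "P4"), ("T7", "T8"),
)

#: 16 coherence pairs, ordering fixed: left intra, right intra, inter.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    LEFT_INTRA_PAIRS + RIGHT_INTRA_PAIRS + INTER_PAIRS
)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"band {self.name}: need 0 < lo < hi, got {self.lo}, {self.hi}")


#: Conventional clinical bands; configurable wherever bands are consumed.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
)

BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}


def pair_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}-{pair[1]}"


def feature_name(pair: tuple[str, str], band: BandDefinition | str) -> str:
    bname = band if isinstance(band, str) else band.name
    return f"{pair_name(pair)}_{bname}"
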