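"""Source-level arithmetic for band-limited underwater sounds.

A spectral source level (dB re 1 uPa Hz^-1/2 at 1 m) integrated over a
frequency band gives the effective RMS sound pressure level of the source.
Only a flat spectral density over the band is supported: the band integral is
then level + 10 log10(bandwidth).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["SpectralSourceLevel", "band_integrated_spl"]


@dataclass(frozen=True)
class SpectralSourceLevel:
    """A flat spectral source level over a frequency band.

    ``level`` is in dB re 1 uPa Hz^-1/2 at 1 m; the band is [band_low,
    band_high] in Hz with 0 < band_low < band_high.
    """

    level: float
    band_low: float
    band_high: float

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError(
                f"need 0 < band_low < band_high, got [{self.band_low}, {self.band_high}]"
            )


def band_integrated_spl(s: SpectralSourceLevel) -> float:
    """Effective source RMS sound pressure level, dB re 1 uPa at 1 m.

    Assumes the spectral density is flat across the band, so the integrated
    mean-square pressure is density x bandwidth:
    level + 10 log10(band_high - band_low).
    """
    return s.level + 10.0 * math.log10(s.band_high - s.band_low)
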