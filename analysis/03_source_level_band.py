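#!/usr/bin/env python
"""Band-integrated source level of a recorded deep-water fish call.

A call localized to the upper continental slope was reported with a spectral
source level of 131 dB re 1 uPa Hz^-1/2 over the 800-1000 Hz band. Assuming
a flat spectral density, integrating over the band gives the effective RMS
source sound pressure level, which this script computes and compares with in
situ source levels of shallow-water soniferous fishes (128-170 dB re 1 uPa).

Writes results/band_level.csv.
"""
from pathlib import Path

import pandas as pd

from deepbubble import SpectralSourceLevel, band_integrated_spl

OUT = Path(__file__).resolve().parents[1] / "results" / "band_level.csv"


def main() -> None:
    s = SpectralSourceLevel(level=131.0, band_low=800.0, band_high=1000.0)
    spl = band_integrated_spl(s)
    OUT.parent.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {
                "spectral_level_dB_re_1uPa_rtHz": s.level,
                "band_low_Hz": s.band_low,
                "band_high_Hz": s.band_high,
                "band_integrated_spl_dB_re_1uPa": spl,
            }
        ]
    ).to_csv(OUT, index=False, lineterminator="\n")
    print(f"wrote {OUT}")
    print(
        f"\n{s.level:.0f} dB re 1 uPa Hz^-1/2 over {s.band_low:.0f}-"
        f"{s.band_high:.0f} Hz -> {spl:.1f} dB re 1 uPa effective RMS source level."
    )
    print(
        "that is 11-16 dB below typical shallow-water sciaenid source levels "
        "(165-170 dB re 1 uPa), consistent with the computed radiated-power "
        "loss of a driven bladder at several hundred metres depth."
    )


if __name__ == "__main__":
    main()
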