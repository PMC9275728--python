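#!/usr/bin/env python
"""Depth dependence of bubble resonance and radiated power.

Runs the constant-temperature (1.5 degC) salinity-35 depth profile from the
surface to 3500 m and tracks, for a 0.10 m bubble: the undamped and far-field
resonance frequencies, the far-field-to-Minnaert frequency ratio, and the
radiated-power reduction relative to the surface.

Writes results/depth_curves.csv (tidy: depth, quantity, gas, R0, value).
"""
from pathlib import Path

import numpy as np
import pandas as pd

from deepbubble import (
    cold_depth_profile,
    frequency_vs_depth,
    minnaert_ratio_vs_depth,
    power_reduction_db,
)
from deepbubble.depth_analysis import CANONICAL_RADIUS_M

OUT = Path(__file__).resolve().parents[1] / "results" / "depth_curves.csv"
STEP_M = 50.0  # grid step; node depths 0/1000/2000/3500 are exact fixtures


def main() -> None:
    profile = cold_depth_profile()
    depths = np.arange(0.0, 3500.0 + 0.5 * STEP_M, STEP_M)
    frames = []
    for gas in ("N2", "O2"):
        f_und, f_sig = frequency_vs_depth(profile, gas, CANONICAL_RADIUS_M, depths)
        ratio = minnaert_ratio_vs_depth(profile, gas, CANONICAL_RADIUS_M, depths)
        power = power_reduction_db(profile, gas, CANONICAL_RADIUS_M, depths)
        for curve in (f_und, f_sig, ratio, power):
            frames.append(
                pd.DataFrame(
                    {
                        "depth_m": curve.depths_m,
                        "quantity": curve.quantity,
                        "gas": curve.gas,
                        "R0_m": curve.R0,
                        "value": curve.values,
                    }
                )
            )
    tidy = pd.concat(frames, ignore_index=True)
    OUT.parent.mkdir(exist_ok=True)
    tidy.to_csv(OUT, index=False, lineterminator="\n")
    print(f"wrote {len(tidy)} rows to {OUT}")

    n2 = tidy[tidy.gas == "N2"]
    at = lambda q, d: float(
        n2[(n2.quantity == q) & (n2.depth_m == d)].value.iloc[0]
    )
    print(
        f"\nfar-field resonance of a 0.10 m nitrogen bubble: "
        f"{at('f_sigma_Hz', 0.0):.1f} Hz at the surface -> "
        f"{at('f_sigma_Hz', 3500.0):.1f} Hz at 3500 m."
    )
    print(
        f"Minnaert ratio f_sigma/f_M: {at('f_sigma_over_f_M', 0.0):.4f} at the "
        f"surface (Minnaert is a good surface approximation), "
        f"{at('f_sigma_over_f_M', 3500.0):.4f} at 3500 m (~2% above Minnaert)."
    )
    for d in (1000.0, 2000.0, 3500.0):
        db = at("power_reduction_dB", d)
        print(
            f"radiated-power reduction at {d:.0f} m: {db:.1f} dB "
            f"({10 ** (-db / 10):.0f}x below the surface peak)"
        )
    print(
        "\na deep-water fish must drive its bladder hundreds of times harder "
        "to radiate the sound power a surface fish gets at resonance."
    )


if __name__ == "__main__":
    main()
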