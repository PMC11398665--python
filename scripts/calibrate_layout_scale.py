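"""Calibrate the layout size constants hard-coded in strtomo.layout.

Recomputes:
  * SIZE_SCALE_C — the multiplier of the base lattice constant
    (arena/8) that brings the mean effective subunit diameter of default
    N=10 layouts to 7.0 arena pixels.  The mean diameter is strictly
    proportional to the constant, so the update is a single rescaling of
    the currently compiled value.
  * COSINE_RADIUS_PER_SIGMA — the radius of the positive cosine lobe per
    fitted (moment-matched) Gaussian sigma.

Run:  python scripts/calibrate_layout_scale.py [--n 1000] [--seed 0]
"""

import argparse

import numpy as np

from strtomo.layout import (
    SIZE_SCALE_C,
    cosine_radius_per_sigma,
    effective_diameter,
    generate_layout,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=1000, help="number of layouts")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    diams = [
        effective_diameter(su)
        for _ in range(args.n)
        for su in generate_layout(10, rng).subunits
    ]
    mean = float(np.mean(diams))
    print(f"current SIZE_SCALE_C      = {SIZE_SCALE_C}")
    print(f"mean effective diameter   = {mean:.5f} px (target 7.0)")
    print(f"calibrated SIZE_SCALE_C   = {SIZE_SCALE_C * 7.0 / mean:.5f}")
    print(f"COSINE_RADIUS_PER_SIGMA   = {cosine_radius_per_sigma():.7f}")


if __name__ == "__main__":
    main()
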