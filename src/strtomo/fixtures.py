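"""Seeded reference assets: canned layouts and their rate sinograms.

These are the small deterministic scenes used in examples and tests: a
schematic four-subunit layout (isotropic Gaussians of sigma = arena/10
at 3/8 and 5/8 of the arena), a single elongated subunit (the
anisotropy demonstration), and a default random ten-subunit mosaic.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .io import save_layout_json, save_sinogram_csv, save_sinogram_npz
from .layout import GaussianSubunit, SubunitLayout, generate_layout
from .model import GanglionModel
from .stimuli import RickerStripeSpec
from .tomography import TomographyPlan, acquire_sinogram

__all__ = [
    "schematic_four_subunit_layout",
    "single_ellipse_layout",
    "make_fixtures",
]


def schematic_four_subunit_layout(arena_size: float = 40.0) -> SubunitLayout:
    """Four isotropic subunits at x, y = 3/8 and 5/8 of the arena."""
    sigma = arena_size / 10.0
    pos = (0.375 * arena_size, 0.625 * arena_size)
    subs = [
        GaussianSubunit(x, y, sigma, sigma, 0.0, weight=0.25)
        for x in pos
        for y in pos
    ]
    return SubunitLayout(subs, arena_size=arena_size)


def single_ellipse_layout(arena_size: float = 40.0) -> SubunitLayout:
    """One strongly elongated subunit centered on the arena."""
    half = arena_size / 2.0
    return SubunitLayout(
        [GaussianSubunit(half, half, 4.0, 1.5, math.pi / 2.0, weight=1.0)],
        arena_size=arena_size,
    )


def make_fixtures(seed: int, outdir) -> dict[str, Path]:
    """Write the canned layouts and matching rate sinograms.

    The schematic sinogram uses surround factor s = 1 (the introductory
    setting); the others use the default Ricker parameters.  Everything
    regenerates identically from the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan = TomographyPlan(response_mode="rate")
    scenes = {
        "schematic4": (schematic_four_subunit_layout(), RickerStripeSpec(w=5.0, s=1.0)),
        "single_ellipse": (single_ellipse_layout(), RickerStripeSpec()),
        "default10": (
            generate_layout(10, np.random.default_rng(seed)),
            RickerStripeSpec(),
        ),
    }
    written: dict[str, Path] = {}
    for name, (layout, stripe) in scenes.items():
        lpath = outdir / f"{name}_layout.json"
        save_layout_json(layout, lpath, metadata={"seed": seed, "fixture": name})
        sino = acquire_sinogram(GanglionModel([layout]), plan, stripe)
        save_sinogram_csv(sino, outdir / f"{name}_sinogram.csv")
        save_sinogram_npz(sino, outdir / f"{name}_sinogram.npz")
        written[name] = lpath
    return written
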