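"""Stimulus rendering: Ricker stripes, Marr-wavelet spots, full-field steps.

All stimuli are Weber-contrast images on the square arena grid, values in
[-1, +1] with 0 = mean gray.  Profiles are evaluated at pixel centers
(pixel (row, col) has center (col + 0.5, row + 0.5) in arena
coordinates), which keeps rotations and sub-pixel offsets exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RickerStripeSpec",
    "MarrSpotSpec",
    "ricker_profile",
    "render_ricker_stripe",
    "render_marr_spot",
    "full_field",
    "render_stripe_bank",
]


@dataclass(frozen=True)
class RickerStripeSpec:
    """A stripe whose cross-section is a (modified) 1D Ricker wavelet.

    w is the zero-crossing separation (width of the central band), s the
    surround factor multiplying the suppressive sidebands (s > 1 gives a
    net-darkening stimulus), angle the stripe orientation in degrees,
    offset the signed perpendicular shift of the stripe axis from the
    arena center.  stripe_spacing, if set, renders an infinite periodic
    array of parallel stripes with that center-to-center period.
    """

    w: float = 5.0
    s: float = 2.5
    angle: float = 0.0
    offset: float = 0.0
    polarity: int = 1
    stripe_spacing: float | None = None

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("stripe width w must be > 0")
        if self.s < 0:
            raise ValueError("surround factor s must be >= 0")
        if not (0.0 <= self.angle < 180.0):
            raise ValueError("angle must lie in [0, 180)")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if self.stripe_spacing is not None and self.stripe_spacing <= self.w:
            raise ValueError("stripe_spacing must exceed the stripe width")


@dataclass(frozen=True)
class MarrSpotSpec:
    """2D Marr-wavelet spot: excitatory center, suppressive annulus."""

    center: tuple[float, float]
    d: float = 25.0
    truncate_negative: bool = False

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("size parameter d must be > 0")


def ricker_profile(x, w: float, s: float, polarity: int = 1):
    """Modified 1D Ricker wavelet, clipped to the contrast range.

    L(x) = s0(x) * (1 - 4 x^2 / w^2) * exp(-2 x^2 / w^2), with s0 = s on
    the sidebands (|x| >= w/2) and 1 on the central band.  Values are
    clipped to [-1, +1]; polarity -1 negates before clipping.
    """
    if w <= 0:
        raise ValueError("w must be > 0")
    if s < 0:
        raise ValueError("s must be >= 0")
    x = np.asarray(x, dtype=float)
    base = (1.0 - 4.0 * x**2 / w**2) * np.exp(-2.0 * x**2 / w**2)
    s0 = np.where(np.abs(x) >= w / 2.0, s, 1.0)
    return np.clip(polarity * s0 * base, -1.0, 1.0)


def _perpendicular_offsets(arena_size: float, angle_deg: float):
    n = int(round(arena_size))
    coords = np.arange(n) + 0.5
    xx, yy = np.meshgrid(coords, coords)
    half = arena_size / 2.0
    a = math.radians(angle_deg)
    # stripe axis direction (cos a, sin a); normal (-sin a, cos a)
    return -(xx - half) * math.sin(a) + (yy - half) * math.cos(a)


def render_ricker_stripe(
    spec: RickerStripeSpec, arena_size: float = 40.0
) -> np.ndarray:
    """Render a (single or periodic multi-) Ricker stripe on the arena."""
    u = _perpendicular_offsets(arena_size, spec.angle) - spec.offset
    if spec.stripe_spacing is not None:
        p = spec.stripe_spacing
        u = (u + p / 2.0) % p - p / 2.0  # fold to [-p/2, p/2)
    return ricker_profile(u, spec.w, spec.s, spec.polarity)


def render_marr_spot(spec: MarrSpotSpec, arena_size: float = 40.0) -> np.ndarray:
    """Render a 2D Marr wavelet L(r) = (1 - 2 r^2/d^2) exp(-2 r^2/d^2)."""
    n = int(round(arena_size))
    coords = np.arange(n) + 0.5
    xx, yy = np.meshgrid(coords, coords)
    r2 = (xx - spec.center[0]) ** 2 + (yy - spec.center[1]) ** 2
    vals = (1.0 - 2.0 * r2 / spec.d**2) * np.exp(-2.0 * r2 / spec.d**2)
    if spec.truncate_negative:
        vals = np.maximum(vals, 0.0)
    return vals


def full_field(contrast: float, arena_size: float = 40.0) -> np.ndarray:
    """Spatially uniform contrast step."""
    if not -1.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [-1, 1]")
    n = int(round(arena_size))
    return np.full((n, n), float(contrast))


def render_stripe_bank(
    angles_deg, positions, stripe: RickerStripeSpec, arena_size: float = 40.0
) -> np.ndarray:
    """All (angle, position) stripe frames, flattened to (n_a * n_p, n_px).

    Frame order is angle-major, matching sinogram layout.  Rendering is
    vectorised over positions per angle: a position shift only shifts the
    perpendicular coordinate fed to the 1D profile.
    """
    n = int(round(arena_size))
    positions = np.asarray(positions, dtype=float)
    frames = np.empty((len(angles_deg), len(positions), n * n))
    for i, ang in enumerate(angles_deg):
        u = _perpendicular_offsets(arena_size, float(ang)).ravel()
        du = u[None, :] - positions[:, None]
        if stripe.stripe_spacing is not None:
            p = stripe.stripe_spacing
            du = (du + p / 2.0) % p - p / 2.0
        frames[i] = ricker_profile(du, stripe.w, stripe.s, stripe.polarity)
    return frames.reshape(len(angles_deg) * len(positions), n * n)
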