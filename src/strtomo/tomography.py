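"""Tomographic acquisition and filtered back-projection.

Responses to Ricker stripes at all combinations of angle and
perpendicular position form a sinogram (one row per angle).  Sinograms
from spiking responses are Gaussian-smoothed across positions and
angles, then reconstructed with filtered back-projection (FBP, ramp
filter).  Position offsets are signed perpendicular distances from the
arena center; the reconstruction grid is centered on the arena with
pixel pitch equal to the position step, so hotspot coordinates come out
directly in arena pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .model import GanglionModel
from .stimuli import RickerStripeSpec, render_stripe_bank

__all__ = [
    "TomographyPlan",
    "Sinogram",
    "SmoothingParams",
    "Reconstruction",
    "acquire_sinogram",
    "smooth_sinogram",
    "fbp_reconstruct",
    "recenter_sinogram",
]


def default_angles() -> np.ndarray:
    return np.arange(0.0, 180.0, 5.0)


@dataclass
class TomographyPlan:
    """Measurement schedule: which angles and positions to probe."""

    angles: np.ndarray = field(default_factory=default_angles)
    n_positions: int = 60
    position_step: float = 2.0 / 3.0
    repeats: int = 1
    response_mode: str = "rate"  # "rate" | "spikes"

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if np.any((self.angles < 0) | (self.angles >= 180)):
            raise ValueError("angles must lie in [0, 180)")
        if self.n_positions < 2:
            raise ValueError("need at least 2 stripe positions")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.response_mode not in ("rate", "spikes"):
            raise ValueError(f"unknown response_mode {self.response_mode!r}")

    @property
    def positions(self) -> np.ndarray:
        """Symmetric offsets (i - (n-1)/2) * step around the arena center."""
        i = np.arange(self.n_positions, dtype=float)
        return (i - (self.n_positions - 1) / 2.0) * self.position_step

    @property
    def n_presentations(self) -> int:
        return len(self.angles) * self.n_positions * self.repeats


@dataclass
class Sinogram:
    """Angle x position response matrix (spikes per stimulus)."""

    responses: np.ndarray
    angles: np.ndarray
    positions: np.ndarray
    cyclic: bool = False

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.responses.shape != (len(self.angles), len(self.positions)):
            raise ValueError("sinogram shape does not match angles/positions")

    @property
    def position_step(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass(frozen=True)
class SmoothingParams:
    """Gaussian sinogram smoothing: sigma_pos in % of the arena size,
    sigma_ang in degrees."""

    sigma_pos: float = 2.5
    sigma_ang: float = 5.0

    def __post_init__(self) -> None:
        if self.sigma_pos < 0 or self.sigma_ang < 0:
            raise ValueError("smoothing sigmas must be >= 0")


@dataclass
class Reconstruction:
    """Square FBP output; coordinates in arena pixels via pixel_pitch."""

    values: np.ndarray
    pixel_pitch: float
    center: tuple[float, float] = (20.0, 20.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("reconstruction must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reconstruction contains non-finite values")

    @property
    def extent(self) -> float:
        return self.values.shape[0] * self.pixel_pitch

    def pixel_coordinates(self):
        """Arena (x, y) coordinates of every reconstruction pixel."""
        n = self.values.shape[0]
        off = (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch
        x = self.center[0] + off
        y = self.center[1] + off
        return np.meshgrid(x, y)


def acquire_sinogram(
    model: GanglionModel,
    plan: TomographyPlan,
    stripe: RickerStripeSpec,
    rng=None,
    stimulus_bank: np.ndarray | None = None,
) -> Sinogram:
    """Measure a sinogram from a model.

    Entry (a, p) is the model's response to the stripe rendered at angle
    a with perpendicular offset p: the deterministic rate, or the mean of
    `repeats` Poisson spike-count draws.  A precomputed stimulus bank
    (from stimuli.render_stripe_bank with the plan's angles/positions)
    may be passed to amortise rendering across layouts.
    """
    if plan.response_mode == "spikes" and rng is None:
        raise ValueError("spiking acquisition needs a random generator")
    if stimulus_bank is None:
        stimulus_bank = render_stripe_bank(
            plan.angles, plan.positions, stripe, model.arena_size
        )
    rates = model.rates(stimulus_bank).reshape(len(plan.angles), plan.n_positions)
    if plan.response_mode == "spikes":
        rng = np.random.default_rng(rng)
        counts = rng.poisson(rates, size=(plan.repeats,) + rates.shape)
        rates = counts.mean(axis=0).astype(float)
    return Sinogram(
        rates, plan.angles.copy(), plan.positions.copy(),
        cyclic=stripe.stripe_spacing is not None,
    )


def _flip_positions(rows: np.ndarray, cyclic: bool) -> np.ndarray:
    """Map position p -> -p within each row (the 180-degree wrap rule)."""
    flipped = rows[..., ::-1]
    if cyclic:
        # positions j*step in [0, period): -p is (n-j) mod n
        flipped = np.roll(flipped, 1, axis=-1)
    return flipped


def smooth_sinogram(
    sino: Sinogram, params: SmoothingParams, arena_size: float = 40.0
) -> Sinogram:
    """Separable Gaussian smoothing across positions and angles.

    Position-axis sigma is sigma_pos % of the arena converted to column
    units; angle-axis sigma is sigma_ang / angle step.  Boundaries:
    positions reflect (or wrap for cyclic sinograms); the angle axis
    wraps with the sinogram's natural 180-degree symmetry, pairing angle
    a + 180 with position -p (row reversal at the seam).
    """
    resp = sino.responses
    step = sino.position_step
    sig_pos = params.sigma_pos / 100.0 * arena_size / step
    if sig_pos > 0:
        mode = "wrap" if sino.cyclic else "reflect"
        resp = ndimage.gaussian_filter1d(resp, sig_pos, axis=1, mode=mode)
    angle_step = float(sino.angles[1] - sino.angles[0]) if len(sino.angles) > 1 else None
    sig_ang = params.sigma_ang / angle_step if angle_step else 0.0
    if sig_ang > 0:
        n = resp.shape[0]
        pad = min(n, int(math.ceil(4.0 * sig_ang)) + 1)
        ext = np.concatenate(
            [
                _flip_positions(resp[n - pad:], sino.cyclic),
                resp,
                _flip_positions(resp[:pad], sino.cyclic),
            ],
            axis=0,
        )
        ext = ndimage.gaussian_filter1d(ext, sig_ang, axis=0, mode="nearest")
        resp = ext[pad:pad + n]
    return replace(sino, responses=resp)


def _ramp_filter(n_fft: int) -> np.ndarray:
    """Discrete ramp (Ram-Lak) filter in the frequency domain.

    Built from the band-limited real-space kernel (h[0] = 1/4,
    h[odd k] = -1/(pi k)^2) to avoid suppressing the DC component the
    way a naive |f| filter does.
    """
    k = np.concatenate([np.arange(n_fft // 2 + 1), np.arange(n_fft // 2 - 1, 0, -1)])
    h = np.zeros(n_fft)
    h[0] = 0.25
    odd = k % 2 == 1
    h[odd] = -1.0 / (math.pi * k[odd]) ** 2
    return 2.0 * np.real(np.fft.fft(h))


def fbp_reconstruct(sino: Sinogram, arena_size: float = 40.0) -> Reconstruction:
    """Filtered back-projection with a pure ramp filter.

    Each row is ramp-filtered in the frequency domain (zero-padded to
    the next power of two >= twice the row length), back-projected with
    linear interpolation onto an n_positions x n_positions grid centered
    on the arena, and scaled by pi / (2 * n_angles).
    """
    n_ang, n_pos = sino.responses.shape
    if n_ang < 2:
        raise ValueError("FBP needs at least 2 projection angles")
    n_fft = 1 << max(6, int(math.ceil(math.log2(2 * n_pos))))
    filt = _ramp_filter(n_fft)
    padded = np.zeros((n_ang, n_fft))
    padded[:, :n_pos] = sino.responses
    filtered = np.real(np.fft.ifft(np.fft.fft(padded, axis=1) * filt, axis=1))
    filtered = filtered[:, :n_pos]

    step = sino.position_step
    off = (np.arange(n_pos) - (n_pos - 1) / 2.0) * step
    xx, yy = np.meshgrid(off, off)
    recon = np.zeros((n_pos, n_pos))
    ang = np.radians(sino.angles)
    if sino.cyclic:
        # rows are assumed recentred: column n // 2 is offset zero
        pos = (np.arange(n_pos) - n_pos // 2) * step
    else:
        pos = sino.positions
    for i in range(n_ang):
        t = -xx * math.sin(ang[i]) + yy * math.cos(ang[i])
        recon += np.interp(t.ravel(), pos, filtered[i], left=0.0, right=0.0).reshape(
            n_pos, n_pos
        )
    recon *= math.pi / (2.0 * n_ang)
    half = arena_size / 2.0
    return Reconstruction(recon, pixel_pitch=step, center=(half, half))


def recenter_sinogram(sino: Sinogram, rf_center, arena_size: float = 40.0) -> Sinogram:
    """Cyclically re-zero each row of a periodic-stimulus sinogram.

    For each angle, the column whose stripe position is closest (in the
    cyclic metric) to the perpendicular projection of the receptive-field
    center is rolled to the central column (index n // 2).  Row value
    multisets are preserved.
    """
    if not sino.cyclic:
        raise ValueError("recentering applies to cyclic sinograms only")
    n = len(sino.positions)
    step = sino.position_step
    period = n * step
    half = arena_size / 2.0
    dx, dy = rf_center[0] - half, rf_center[1] - half
    out = np.empty_like(sino.responses)
    central = n // 2
    for i, ang in enumerate(np.radians(sino.angles)):
        u = -dx * math.sin(ang) + dy * math.cos(ang)
        dist = (sino.positions - u + period / 2.0) % period - period / 2.0
        j = int(np.argmin(np.abs(dist)))
        out[i] = np.roll(sino.responses[i], central - j)
    return replace(sino, responses=out)
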