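"""Hotspot detection, subunit matching, F-scores and benchmark sweeps.

A reconstruction is scored against its ground-truth layout by detecting
hotspots (retained local maxima), matching them to subunit ellipses, and
computing F = 2 TP / (2 TP + FP + FN).  Errors are categorised as
undetected (no hotspot within the subunit's 1.5-sigma ellipse),
mislocalized (a hotspot within 1.5 but not 0.75 sigma), or spurious;
each mislocalization pairs one false-positive hotspot with one
false-negative subunit and is counted once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .layout import (
    SubunitLayout,
    build_photoreceptor_stage,
    gaussian_subunit_weights,
    generate_layout,
    superimpose_layouts,
)
from .model import GanglionModel
from .stimuli import RickerStripeSpec, render_stripe_bank
from .tomography import (
    Reconstruction,
    Sinogram,
    SmoothingParams,
    TomographyPlan,
    acquire_sinogram,
    fbp_reconstruct,
    smooth_sinogram,
)

__all__ = [
    "Hotspot",
    "HotspotSet",
    "MatchReport",
    "StrParams",
    "detect_hotspots",
    "match_hotspots",
    "f_score",
    "scale_parameters",
    "required_positions",
    "run_benchmark",
    "BenchmarkResult",
    "measurement_time",
    "time_to_threshold",
    "nearest_neighbor_distance",
    "build_variant_model",
    "VARIANTS",
]


@dataclass(frozen=True)
class Hotspot:
    x: float
    y: float
    value: float


@dataclass
class HotspotSet:
    hotspots: list[Hotspot]

    def __len__(self) -> int:
        return len(self.hotspots)

    def __iter__(self):
        return iter(self.hotspots)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([[h.x, h.y] for h in self.hotspots]).reshape(-1, 2)


@dataclass(frozen=True)
class MatchReport:
    tp: int
    fp: int
    fn: int
    errors_undetected: int
    errors_spurious: int
    errors_mislocalized: int

    @property
    def f_score(self) -> float:
        return f_score(self.tp, self.fp, self.fn)

    @property
    def n_errors(self) -> int:
        return self.errors_undetected + self.errors_spurious + self.errors_mislocalized


@dataclass(frozen=True)
class StrParams:
    """The tuned stimulation/analysis quadruple."""

    w: float = 5.0  # stripe width, px
    s: float = 2.5  # surround factor
    sigma_pos: float = 2.5  # position smoothing, % of arena
    sigma_ang: float = 5.0  # angle smoothing, degrees

    def __post_init__(self) -> None:
        if min(self.w, self.s, self.sigma_pos, self.sigma_ang) < 0 or self.w <= 0:
            raise ValueError("STR parameters must be positive")


def f_score(tp: int, fp: int, fn: int) -> float:
    """Harmonic mean of precision and sensitivity."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    denom = 2 * tp + fp + fn
    if denom == 0:
        import warnings

        warnings.warn("F-score of an empty match is defined as 0")
        return 0.0
    return 2.0 * tp / denom


def detect_hotspots(
    recon: Reconstruction, threshold_frac: float = 0.3, circle_frac: float = 0.9
) -> HotspotSet:
    """Local maxima of the reconstruction that qualify as hotspots.

    A local maximum is a pixel at least as large as its eight neighbours
    (out-of-image neighbours cannot block); 8-connected plateau
    components are merged into a single hotspot at their centroid.
    Maxima below `threshold_frac` of the global maximum, or outside the
    circle of diameter `circle_frac` times the reconstruction extent,
    are discarded.
    """
    vals = recon.values
    gmax = vals.max()
    if gmax <= 0:
        return HotspotSet([])
    local_max = vals >= ndimage.maximum_filter(vals, size=3, mode="constant", cval=-np.inf)
    candidates = local_max & (vals >= threshold_frac * gmax)
    labels, n_comp = ndimage.label(candidates, structure=np.ones((3, 3)))
    if n_comp == 0:
        return HotspotSet([])
    n = vals.shape[0]
    centroids = ndimage.center_of_mass(candidates, labels, range(1, n_comp + 1))
    peak_vals = ndimage.maximum(vals, labels, range(1, n_comp + 1))
    radius = circle_frac * recon.extent / 2.0
    grid_center = (n - 1) / 2.0
    out = []
    for (row, col), v in zip(centroids, peak_vals):
        dr = (row - grid_center) * recon.pixel_pitch
        dc = (col - grid_center) * recon.pixel_pitch
        if math.hypot(dr, dc) > radius:
            continue
        out.append(
            Hotspot(
                x=recon.center[0] + dc,
                y=recon.center[1] + dr,
                value=float(v),
            )
        )
    return HotspotSet(out)


def match_hotspots(hotspots: HotspotSet, truth: SubunitLayout) -> MatchReport:
    """Match detected hotspots to ground-truth subunit ellipses.

    A subunit counts as detected (TP) if a hotspot lies inside its
    0.75-sigma ellipse; with several candidates the highest-valued
    hotspot is the match and the rest are false positives.  A hotspot
    inside overlapping ellipses is assigned to the subunit with the
    smallest normalised (Mahalanobis) radius.
    """
    if not truth.subunits:
        raise ValueError("truth layout must contain at least one subunit")
    n_sub = len(truth.subunits)
    n_hot = len(hotspots)
    if n_hot == 0:
        return MatchReport(0, 0, n_sub, errors_undetected=n_sub,
                           errors_spurious=0, errors_mislocalized=0)
    rho = np.array(
        [
            [su.normalized_radius(h.x, h.y) for h in hotspots]
            for su in truth.subunits
        ]
    )  # (n_sub, n_hot)
    values = np.array([h.value for h in hotspots])

    # stage 1: assign each hotspot inside some 0.75-sigma ellipse to the
    # nearest such subunit; per subunit the highest-valued candidate matches
    best_sub = np.argmin(rho, axis=0)
    inside_075 = rho[best_sub, np.arange(n_hot)] <= 0.75
    matched_sub = np.full(n_sub, -1)  # hotspot index matched to each subunit
    hot_state = np.zeros(n_hot, dtype=int)  # 0 free, 1 tp
    for s in range(n_sub):
        cand = np.where(inside_075 & (best_sub == s))[0]
        if len(cand):
            pick = cand[np.argmax(values[cand])]
            matched_sub[s] = pick
            hot_state[pick] = 1

    tp = int((matched_sub >= 0).sum())
    fn_mask = matched_sub < 0
    fp_idx = np.where(hot_state == 0)[0]
    fp = len(fp_idx)

    # error categories
    undetected = 0
    mislocalized = 0
    consumed = np.zeros(n_hot, dtype=bool)
    for s in np.where(fn_mask)[0]:
        within = np.where(rho[s] <= 1.5)[0]
        if len(within) == 0:
            undetected += 1
            continue
        mislocalized += 1
        free = [h for h in within if hot_state[h] == 0 and not consumed[h]]
        if free:
            consumed[free[int(np.argmax(values[free]))]] = True
    spurious = int(fp - consumed.sum())
    return MatchReport(
        tp=tp, fp=fp, fn=int(fn_mask.sum()),
        errors_undetected=undetected,
        errors_spurious=spurious,
        errors_mislocalized=mislocalized,
    )


# ---------------------------------------------------------------------------
# parameter scaling


def _round_to(x: float, q: float) -> float:
    """Nearest multiple of q, ties away from zero."""
    return math.copysign(math.floor(abs(x) / q + 0.5) * q, x)


def scale_parameters(n_subunits: int) -> StrParams:
    """Scale the N=10 optimum to other subunit counts.

    Spatial parameters scale with the subunit diameter, i.e. with
    sqrt(10/N) (area-preserving layout rule); w is rounded to 0.2 px and
    sigma_pos to 0.1 %; s and sigma_ang are scale-free and stay fixed.
    """
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    scale = math.sqrt(10.0 / n_subunits)
    return StrParams(
        w=_round_to(5.0 * scale, 0.2),
        s=2.5,
        sigma_pos=_round_to(2.5 * scale, 0.1),
        sigma_ang=5.0,
    )


def required_positions(
    n_subunits: int, positions_per_subunit: float = 7.0, arena_size: float = 40.0
) -> int:
    """Total stripe positions needed for a given effective resolution.

    The effective subunit diameter is 7 px at N=10 and scales with
    sqrt(10/N); the rule requires `positions_per_subunit` stripe
    positions inside one subunit diameter across the arena.
    """
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    diameter = 7.0 * math.sqrt(10.0 / n_subunits)
    return int(round(arena_size * positions_per_subunit / diameter))


def measurement_time(plan: TomographyPlan, seconds_per_presentation: float = 0.6) -> float:
    """Total stimulation time, including per-flash recovery (0.6 s each)."""
    return plan.n_presentations * seconds_per_presentation


def nearest_neighbor_distance(hotspots: HotspotSet) -> float:
    """Mean distance of each hotspot to its nearest neighbour (px)."""
    if len(hotspots) < 2:
        raise ValueError("need at least two hotspots")
    xy = hotspots.coordinates
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


# ---------------------------------------------------------------------------
# benchmarks

VARIANTS = (
    "default",
    "cosine",
    "threshold-quadratic",
    "overlap-1.6",
    "gaussian-weights",
    "baseline-3",
    "photoreceptor",
    "dual-identical",
)


def build_variant_model(
    variant: str, n_subunits: int, rng, arena_size: float = 40.0, rotation_rng=None
):
    """Build (model, truth layout) for one model variant.

    `rotation_rng`, if given, drives the random rotations of the
    dual-layout variant independently of layout generation.
    """
    return _make_variant(variant, n_subunits, rng, arena_size, rotation_rng)


def _make_variant(variant: str, n_subunits: int, rng, arena_size: float,
                  rotation_rng=None):
    kw = dict(arena_size=arena_size)
    if variant == "default":
        layout = generate_layout(n_subunits, rng, **kw)
        return GanglionModel([layout]), layout
    if variant == "cosine":
        layout = generate_layout(n_subunits, rng, profile_kind="cosine", **kw)
        return GanglionModel([layout]), layout
    if variant == "threshold-quadratic":
        layout = generate_layout(n_subunits, rng, **kw)
        return GanglionModel([layout], subunit_nonlinearity="threshold-quadratic"), layout
    if variant == "overlap-1.6":
        layout = generate_layout(n_subunits, rng, overlap_factor=1.6, **kw)
        return GanglionModel([layout]), layout
    if variant == "gaussian-weights":
        layout = gaussian_subunit_weights(generate_layout(n_subunits, rng, **kw))
        return GanglionModel([layout]), layout
    if variant == "baseline-3":
        layout = generate_layout(n_subunits, rng, **kw)
        return GanglionModel([layout], baseline_rate=3.0), layout
    if variant == "photoreceptor":
        layout = generate_layout(n_subunits, rng, **kw)
        for _ in range(20):
            # a sparse mosaic can leave a subunit unconnected; redraw it
            try:
                stage = build_photoreceptor_stage(layout, rng)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not build a connected photoreceptor mosaic")
        return GanglionModel([layout], photoreceptor_stage=stage), layout
    if variant == "dual-identical":
        a = generate_layout(n_subunits, rng, **kw)
        b = generate_layout(n_subunits, rng, **kw)
        a2, b2 = superimpose_layouts(a, b, rotation_rng if rotation_rng is not None else rng)
        return GanglionModel([a2, b2]), a2
    raise ValueError(f"unknown model variant {variant!r}")


@dataclass
class BenchmarkResult:
    mean_f: float
    sem_f: float
    error_fractions: dict  # pooled over layouts: undetected/spurious/mislocalized
    reports: list
    f_scores: np.ndarray

    def as_summary(self) -> dict:
        return {
            "mean_f": self.mean_f,
            "sem_f": self.sem_f,
            "n_layouts": len(self.f_scores),
            "error_fractions": self.error_fractions,
        }


def run_benchmark(
    n_layouts: int,
    n_subunits: int,
    params: StrParams,
    plan: TomographyPlan | None = None,
    variant: str = "default",
    rng=None,
    arena_size: float = 40.0,
    threshold_frac: float = 0.3,
    circle_frac: float = 0.9,
) -> BenchmarkResult:
    """Full STR pipeline over freshly generated layouts.

    Per layout: generate -> acquire (Poisson spikes unless the plan says
    rate) -> smooth -> FBP -> detect -> match.  Returns the mean and SEM
    of the F-score plus error-category fractions pooled over layouts.
    """
    if n_layouts < 1:
        raise ValueError("n_layouts must be >= 1")
    rng = np.random.default_rng(rng)
    if plan is None:
        plan = TomographyPlan(response_mode="spikes")
    stripe = RickerStripeSpec(w=params.w, s=params.s)
    smoothing = SmoothingParams(params.sigma_pos, params.sigma_ang)
    bank = render_stripe_bank(plan.angles, plan.positions, stripe, arena_size)
    reports = []
    for _ in range(n_layouts):
        model, truth = _make_variant(variant, n_subunits, rng, arena_size)
        sino = acquire_sinogram(model, plan, stripe, rng=rng, stimulus_bank=bank)
        if plan.response_mode == "spikes":
            sino = smooth_sinogram(sino, smoothing, arena_size)
        recon = fbp_reconstruct(sino, arena_size)
        hotspots = detect_hotspots(recon, threshold_frac, circle_frac)
        reports.append(match_hotspots(hotspots, truth))
    fs = np.array([r.f_score for r in reports])
    totals = {
        "undetected": sum(r.errors_undetected for r in reports),
        "spurious": sum(r.errors_spurious for r in reports),
        "mislocalized": sum(r.errors_mislocalized for r in reports),
    }
    n_err = sum(totals.values())
    fractions = {k: (v / n_err if n_err else 0.0) for k, v in totals.items()}
    sem = float(fs.std(ddof=1) / math.sqrt(len(fs))) if len(fs) > 1 else 0.0
    return BenchmarkResult(float(fs.mean()), sem, fractions, reports, fs)


def time_to_threshold(
    n_subunits: int,
    f_threshold: float = 0.8,
    rng=None,
    n_layouts: int = 50,
    angle_counts=(6, 9, 12, 18, 24, 36, 48, 72),
    arena_size: float = 40.0,
    seconds_per_presentation: float = 0.6,
) -> float:
    """Measurement time needed to reach a target mean F-score.

    Positions are fixed by the effective-resolution rule
    (required_positions) with the position step covering the arena, the
    stimulation parameters by scale_parameters, and the number of
    equally spaced angles is swept upward; returns the measurement time
    of the first angle count whose benchmark mean F reaches the
    threshold.  Raises RuntimeError if the cap is exceeded.
    """
    if n_subunits < 2:
        raise ValueError("n_subunits must be >= 2")
    rng = np.random.default_rng(rng)
    n_pos = required_positions(n_subunits, arena_size=arena_size)
    params = scale_parameters(n_subunits)
    for n_ang in angle_counts:
        plan = TomographyPlan(
            angles=np.arange(n_ang) * (180.0 / n_ang),
            n_positions=n_pos,
            position_step=arena_size / n_pos,
            response_mode="spikes",
        )
        if f_threshold <= 0:
            return measurement_time(plan, seconds_per_presentation)
        res = run_benchmark(
            n_layouts, n_subunits, params, plan=plan, rng=rng, arena_size=arena_size
        )
        if res.mean_f >= f_threshold:
            return measurement_time(plan, seconds_per_presentation)
    raise RuntimeError(
        f"F-threshold {f_threshold} not reached within {angle_counts[-1]} angles"
    )
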