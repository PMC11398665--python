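"""Ground-truth subunit layouts.

Subunit mosaics are generated as Voronoi diagrams of perturbed hexagonal
lattices; 2D Gaussians are fitted to the Voronoi cells by moment matching
and serve as the linear filters of the model's subunits (the biological
correlate being bipolar cells). The layout scale follows an
area-preserving rule so that the receptive field of a model covers a
roughly constant region of the arena regardless of the number of
subunits N: all linear dimensions scale with sqrt(10 / N), anchored so
that the mean effective subunit diameter at N = 10 is 7 arena pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import Voronoi

__all__ = [
    "GaussianSubunit",
    "SubunitLayout",
    "PhotoreceptorStage",
    "generate_layout",
    "fit_gaussian_to_cell",
    "effective_diameter",
    "gaussian_subunit_weights",
    "build_photoreceptor_stage",
    "superimpose_layouts",
    "subunit_filter",
    "layout_filter_matrix",
    "layout_rf_map",
    "fit_rf_gaussian",
    "effective_rf_diameter",
    "SIZE_SCALE_C",
    "COSINE_RADIUS_PER_SIGMA",
]

# Lattice nearest-neighbour distance is arena_size / 8 before the global
# size rule is applied.  SIZE_SCALE_C anchors the absolute scale: it is
# calibrated once (scripts/calibrate_layout_scale.py) so that the mean
# effective subunit diameter of default N=10 layouts is 7.0 px on the
# 40-px arena.
SIZE_SCALE_C = 1.29741

# Radius of the positive cosine lobe, in units of the standard deviation
# of the Gaussian fitted to the lobe by least squares with free
# amplitude (see cosine_radius_per_sigma below); cached value.
COSINE_RADIUS_PER_SIGMA = 2.1365640

DEFAULT_ARENA = 40.0


@dataclass(frozen=True)
class GaussianSubunit:
    """One elliptical subunit filter.

    The induced spatial filter is normalised to unit volume before the
    subunit weight is applied, so a full-field unit-contrast stimulus
    always drives the linear stage to ``polarity``.
    """

    cx: float
    cy: float
    sigma_major: float
    sigma_minor: float
    orientation: float  # radians, in [0, pi)
    weight: float = 1.0
    polarity: int = 1

    def __post_init__(self) -> None:
        if not (self.sigma_major >= self.sigma_minor > 0):
            raise ValueError(
                "need sigma_major >= sigma_minor > 0, got "
                f"({self.sigma_major}, {self.sigma_minor})"
            )
        if self.weight < 0:
            raise ValueError("subunit weight must be >= 0")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")

    @property
    def center(self) -> tuple[float, float]:
        return (self.cx, self.cy)

    def covariance(self) -> np.ndarray:
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        rot = np.array([[c, -s], [s, c]])
        diag = np.diag([self.sigma_major**2, self.sigma_minor**2])
        return rot @ diag @ rot.T

    def normalized_radius(self, x, y):
        """Mahalanobis-like radius: 1.0 on the 1-sigma ellipse."""
        dx = np.asarray(x, dtype=float) - self.cx
        dy = np.asarray(y, dtype=float) - self.cy
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return np.sqrt((u / self.sigma_major) ** 2 + (v / self.sigma_minor) ** 2)


@dataclass
class SubunitLayout:
    """An ordered mosaic of subunits on a square arena."""

    subunits: list[GaussianSubunit]
    arena_size: float = DEFAULT_ARENA
    profile_kind: str = "gaussian"  # "gaussian" | "cosine"

    def __post_init__(self) -> None:
        if self.profile_kind not in ("gaussian", "cosine"):
            raise ValueError(f"unknown profile_kind {self.profile_kind!r}")

    def __len__(self) -> int:
        return len(self.subunits)

    @property
    def weights(self) -> np.ndarray:
        return np.array([su.weight for su in self.subunits])

    @property
    def centers(self) -> np.ndarray:
        return np.array([[su.cx, su.cy] for su in self.subunits])

    def weight_total(self) -> float:
        return float(self.weights.sum())


@dataclass
class PhotoreceptorStage:
    """Photoreceptor mosaic feeding the subunits of one layout.

    ``connection_weights[s, p]`` weights photoreceptor p into subunit s;
    rows are normalised to unit sum.
    """

    photoreceptors: list[GaussianSubunit]
    connection_weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.connection_weights, dtype=float)
        if w.shape[1] != len(self.photoreceptors):
            raise ValueError("weight table does not match photoreceptor count")
        rowsums = w.sum(axis=1)
        if np.any(rowsums <= 0):
            raise ValueError("a subunit has no connected photoreceptors")
        self.connection_weights = w / rowsums[:, None]


# ---------------------------------------------------------------------------
# polygon moments and Gaussian fits


def _polygon_moments(vertices: np.ndarray):
    """Area, centroid and central second moments of a simple polygon.

    Green's-theorem identities over the boundary; orientation-agnostic.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if area == 0.0:
        raise ValueError("degenerate (zero-area) polygon")
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    # second moments about the origin
    mxx = (cross * (x**2 + x * xn + xn**2)).sum() / 12.0
    myy = (cross * (y**2 + y * yn + yn**2)).sum() / 12.0
    mxy = (cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)).sum() / 24.0
    if area < 0:
        area, mxx, myy, mxy = -area, -mxx, -myy, -mxy
    cov = np.array(
        [
            [mxx / area - cx**2, mxy / area - cx * cy],
            [mxy / area - cx * cy, myy / area - cy**2],
        ]
    )
    return area, (cx, cy), cov


def fit_gaussian_to_cell(vertices: np.ndarray) -> GaussianSubunit:
    """Moment-matched Gaussian of a bounded polygon (e.g. a Voronoi cell).

    Center = polygon centroid; sigmas and orientation from the
    eigendecomposition of the polygon's central second area moments.
    """
    _, (cx, cy), cov = _polygon_moments(vertices)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        raise ValueError("degenerate polygon covariance")
    s_min, s_maj = math.sqrt(evals[0]), math.sqrt(evals[1])
    major = evecs[:, 1]
    orientation = math.atan2(major[1], major[0]) % math.pi
    return GaussianSubunit(cx, cy, s_maj, s_min, orientation)


def effective_diameter(subunit: GaussianSubunit) -> float:
    """Diameter of the circle matching the area of the 1.5-sigma ellipse."""
    return 3.0 * math.sqrt(subunit.sigma_major * subunit.sigma_minor)


# ---------------------------------------------------------------------------
# mosaic generation


def _hex_lattice(lattice_const: float, radius: float) -> np.ndarray:
    """Hexagonal lattice points within `radius` of the origin."""
    a = lattice_const
    n = int(math.ceil(radius / a)) + 2
    pts = []
    for j in range(-n, n + 1):
        for i in range(-n, n + 1):
            x = a * (i + 0.5 * j)
            y = a * (math.sqrt(3) / 2.0) * j
            if x * x + y * y <= radius * radius:
                pts.append((x, y))
    return np.array(pts)


def _bounded_cells(vor: Voronoi):
    """(point index, vertex array) for every bounded Voronoi cell."""
    out = []
    for ip, ireg in enumerate(vor.point_region):
        region = vor.regions[ireg]
        if not region or -1 in region:
            continue
        out.append((ip, vor.vertices[region]))
    return out


def _mosaic_cells(rng, lattice_const, perturbation_frac, select_radius):
    """Perturbed-hex Voronoi cells with centroids within select_radius."""
    lattice = _hex_lattice(lattice_const, select_radius + 3.0 * lattice_const)
    pts = lattice + rng.normal(
        scale=perturbation_frac * lattice_const, size=lattice.shape
    )
    vor = Voronoi(pts)
    cells = []
    for ip, verts in _bounded_cells(vor):
        _, (cx, cy), _ = _polygon_moments(verts)
        if cx * cx + cy * cy <= select_radius**2:
            cells.append(((cx, cy), verts))
    return cells


def generate_layout(
    n_subunits: int,
    rng,
    overlap_factor: float = 1.35,
    perturbation_frac: float = 0.21,
    arena_size: float = DEFAULT_ARENA,
    weight_total: float = 1.0,
    profile_kind: str = "gaussian",
    max_retries: int = 50,
) -> SubunitLayout:
    """Generate a random subunit layout centered on the arena.

    A hexagonal lattice (nearest-neighbour distance arena_size/8, scaled
    by the global size rule SIZE_SCALE_C * sqrt(10/N)) is perturbed by
    independent Gaussian shifts of `perturbation_frac` of the lattice
    constant, Voronoi-tessellated, and the N cells whose centroids lie
    closest to the lattice center are fitted with Gaussians whose sigmas
    are multiplied by `overlap_factor`.  Equal weights, normalised to
    `weight_total`; the layout is recentred so its (weighted) center of
    mass sits at the arena center.
    """
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    rng = np.random.default_rng(rng)
    a = (arena_size / 8.0) * SIZE_SCALE_C * math.sqrt(10.0 / n_subunits)
    select_radius = a * (0.65 * math.sqrt(n_subunits) + 1.5)
    for _ in range(max_retries):
        cells = _mosaic_cells(rng, a, perturbation_frac, select_radius)
        if len(cells) < n_subunits:
            continue  # degenerate tessellation; retry with fresh perturbation
        cells.sort(key=lambda c: c[0][0] ** 2 + c[0][1] ** 2)
        chosen = cells[:n_subunits]
        try:
            fits = [fit_gaussian_to_cell(verts) for _, verts in chosen]
        except ValueError:
            continue
        break
    else:
        raise RuntimeError("could not generate a valid mosaic")

    center = np.mean([[f.cx, f.cy] for f in fits], axis=0)
    half = arena_size / 2.0
    subunits = [
        GaussianSubunit(
            cx=f.cx - center[0] + half,
            cy=f.cy - center[1] + half,
            sigma_major=f.sigma_major * overlap_factor,
            sigma_minor=f.sigma_minor * overlap_factor,
            orientation=f.orientation,
            weight=weight_total / n_subunits,
        )
        for f in fits
    ]
    return SubunitLayout(subunits, arena_size=arena_size, profile_kind=profile_kind)


# ---------------------------------------------------------------------------
# filters on the pixel grid


def _pixel_grid(arena_size: float):
    n = int(round(arena_size))
    coords = np.arange(n) + 0.5
    xx, yy = np.meshgrid(coords, coords)  # xx varies along columns
    return xx, yy


def cosine_radius_per_sigma() -> float:
    """Lobe radius R per fitted sigma for a radial cosine profile.

    The profile is cos(pi * r / (2R)) on r <= R, zero beyond.  R is
    expressed in units of the sigma of the radial Gaussian that best
    fits the lobe in the least-squares sense with a free amplitude —
    the sizing that makes cosine subunits interchangeable with Gaussian
    subunits of the same fitted sigma.  (Moment matching of the lobe as
    a density would give the noticeably larger R = 2.499 sigma, because
    a Gaussian matching the lobe's variance underweights its compact
    core.)
    """
    from scipy.integrate import quad
    from scipy.optimize import minimize_scalar

    def sse(sig):
        fg = quad(
            lambda r: math.cos(math.pi * r / 2) * math.exp(-r * r / (2 * sig**2)) * r,
            0, 1,
        )[0]
        gg = quad(lambda r: math.exp(-r * r / sig**2) * r, 0, 5)[0]
        ff = quad(lambda r: math.cos(math.pi * r / 2) ** 2 * r, 0, 1)[0]
        return ff - fg * fg / gg

    res = minimize_scalar(sse, bounds=(0.1, 1.0), method="bounded")
    return 1.0 / res.x


def subunit_filter(
    subunit: GaussianSubunit,
    arena_size: float = DEFAULT_ARENA,
    profile_kind: str = "gaussian",
) -> np.ndarray:
    """Discrete spatial filter of one subunit, normalised to unit volume.

    The profile (Gaussian density, or positive cosine lobe sized so that
    its moment-matched Gaussian has the subunit's sigmas) is evaluated at
    pixel centers and the discrete sum renormalised to 1, which keeps
    full-field anchoring exact.  Polarity is *not* applied here.
    """
    xx, yy = _pixel_grid(arena_size)
    rho = subunit.normalized_radius(xx, yy)
    if profile_kind == "gaussian":
        vals = np.exp(-0.5 * rho**2)
    elif profile_kind == "cosine":
        rho_scaled = rho / COSINE_RADIUS_PER_SIGMA
        vals = np.where(rho_scaled <= 1.0, np.cos(np.pi / 2.0 * rho_scaled), 0.0)
    else:
        raise ValueError(f"unknown profile_kind {profile_kind!r}")
    total = vals.sum()
    if total <= 0:
        raise ValueError("subunit filter has no support on the arena grid")
    return vals / total


def layout_filter_matrix(layout: SubunitLayout) -> np.ndarray:
    """(n_subunits, n_pixels) stack of unit-volume filters."""
    return np.stack(
        [
            subunit_filter(su, layout.arena_size, layout.profile_kind).ravel()
            for su in layout.subunits
        ]
    )


def layout_rf_map(layout: SubunitLayout) -> np.ndarray:
    """Linear receptive field: polarity- and weight-summed filters."""
    filters = layout_filter_matrix(layout)
    w = layout.weights * np.array([su.polarity for su in layout.subunits])
    n = int(round(layout.arena_size))
    return (w @ filters).reshape(n, n)


def fit_rf_gaussian(rf_map: np.ndarray, arena_size: float | None = None,
                    method: str = "moments"):
    """Single-Gaussian fit to a receptive-field map.

    Returns (cx, cy, sigma_major, sigma_minor, orientation, amplitude).
    The default moment-matching fit (centroid + second image moments of
    |rf_map|) is closed-form and consistent with the Gaussian fits used
    for the Voronoi cells; ``method="lsq"`` refines it by least squares
    with a free amplitude (which, on the flat-topped maps that subunit
    mosaics produce, yields systematically wider sigmas).
    """
    img = np.asarray(rf_map, dtype=float)
    n = img.shape[0]
    if arena_size is None:
        arena_size = float(n)
    xx, yy = _pixel_grid(arena_size)
    absimg = np.abs(img)
    total = absimg.sum()
    if total <= 0:
        raise ValueError("cannot fit a Gaussian to an all-zero map")
    cx0 = (absimg * xx).sum() / total
    cy0 = (absimg * yy).sum() / total
    vxx = (absimg * (xx - cx0) ** 2).sum() / total
    vyy = (absimg * (yy - cy0) ** 2).sum() / total
    vxy = (absimg * (xx - cx0) * (yy - cy0)).sum() / total
    evals, evecs = np.linalg.eigh(np.array([[vxx, vxy], [vxy, vyy]]))
    s1, s2 = math.sqrt(max(evals[0], 1e-6)), math.sqrt(max(evals[1], 1e-6))
    th0 = math.atan2(evecs[1, 1], evecs[0, 1]) % math.pi
    amp0 = float(img.ravel()[np.argmax(absimg)])
    if method == "moments":
        return cx0, cy0, s2, s1, th0, amp0
    if method != "lsq":
        raise ValueError(f"unknown fit method {method!r}")

    x, y = xx.ravel(), yy.ravel()
    z = img.ravel()

    def model(p):
        amp, cx, cy, ls1, ls2, th = p
        smaj, smin = math.exp(ls1), math.exp(ls2)
        c, s = math.cos(th), math.sin(th)
        u = c * (x - cx) + s * (y - cy)
        v = -s * (x - cx) + c * (y - cy)
        return amp * np.exp(-0.5 * ((u / smaj) ** 2 + (v / smin) ** 2))

    p0 = np.array([amp0, cx0, cy0, math.log(s2), math.log(s1), th0])
    res = least_squares(lambda p: model(p) - z, p0, method="lm", max_nfev=400)
    amp, cx, cy, ls1, ls2, th = res.x
    smaj, smin = math.exp(ls1), math.exp(ls2)
    if smin > smaj:
        smaj, smin = smin, smaj
        th += math.pi / 2.0
    return cx, cy, smaj, smin, th % math.pi, amp


def effective_rf_diameter(layout: SubunitLayout) -> float:
    """Effective diameter (1.5-sigma based) of the fitted receptive field."""
    _, _, smaj, smin, _, _ = fit_rf_gaussian(layout_rf_map(layout), layout.arena_size)
    return 3.0 * math.sqrt(smaj * smin)


# ---------------------------------------------------------------------------
# layout variants


def gaussian_subunit_weights(
    layout: SubunitLayout, sigma_frac: float = 0.12
) -> SubunitLayout:
    """Reweight subunits by a large central Gaussian.

    weight_k is proportional to the value, at subunit k's center, of a 2D
    Gaussian centered on the arena with sigma = sigma_frac * arena_size;
    weights are renormalised to the layout's previous total.
    """
    if not layout.subunits:
        raise ValueError("empty layout")
    sigma = sigma_frac * layout.arena_size
    half = layout.arena_size / 2.0
    centers = layout.centers
    d2 = ((centers - half) ** 2).sum(axis=1)
    raw = np.exp(-0.5 * d2 / sigma**2)
    w = raw / raw.sum() * layout.weight_total()
    subs = [replace(su, weight=float(wk)) for su, wk in zip(layout.subunits, w)]
    return SubunitLayout(subs, layout.arena_size, layout.profile_kind)


def build_photoreceptor_stage(layout: SubunitLayout, rng) -> PhotoreceptorStage:
    """Photoreceptor mosaic (half the subunit diameter) feeding a layout.

    The mosaic is produced by the same perturbed-hex Voronoi procedure at
    half the subunit lattice constant (targeting ~4x as many
    photoreceptors as subunits before trimming), covering the region of
    the layout.  Photoreceptors whose centers fall outside every subunit
    1.5-sigma ellipse are discarded; each survivor connects to every
    subunit whose 1.5-sigma ellipse covers its center, weighted by the
    subunit's Gaussian value there, normalised per subunit.
    """
    if layout.profile_kind != "gaussian":
        raise ValueError("photoreceptor stage requires gaussian subunits")
    rng = np.random.default_rng(rng)
    n = len(layout.subunits)
    a_sub = (layout.arena_size / 8.0) * SIZE_SCALE_C * math.sqrt(10.0 / n)
    a_ph = a_sub / 2.0
    centers = layout.centers
    half = layout.arena_size / 2.0
    reach = max(
        math.hypot(su.cx - half, su.cy - half) + 1.5 * su.sigma_major
        for su in layout.subunits
    )
    cells = _mosaic_cells(rng, a_ph, 0.21, reach + 2.0 * a_ph)
    photoreceptors = []
    for (cx, cy), verts in cells:
        fit = fit_gaussian_to_cell(verts)
        photoreceptors.append(
            GaussianSubunit(
                cx=fit.cx + half,
                cy=fit.cy + half,
                sigma_major=fit.sigma_major * 1.35,
                sigma_minor=fit.sigma_minor * 1.35,
                orientation=fit.orientation,
            )
        )
    # connection weights; trim photoreceptors outside every 1.5-sigma ellipse
    w = np.zeros((n, len(photoreceptors)))
    for s, su in enumerate(layout.subunits):
        rho = np.array(
            [su.normalized_radius(ph.cx, ph.cy) for ph in photoreceptors]
        )
        w[s] = np.where(rho <= 1.5, np.exp(-0.5 * rho**2), 0.0)
    keep = w.sum(axis=0) > 0
    w = w[:, keep]
    photoreceptors = [ph for ph, k in zip(photoreceptors, keep) if k]
    if np.any(w.sum(axis=1) <= 0):
        raise ValueError("a subunit has no connected photoreceptors")
    return PhotoreceptorStage(photoreceptors, w)


def _transform_layout(layout: SubunitLayout, angle: float, weight_total: float):
    """Recenter on the fitted RF, rotate about the arena center, reweight."""
    cx, cy, _, _, _, _ = fit_rf_gaussian(layout_rf_map(layout), layout.arena_size)
    half = layout.arena_size / 2.0
    c, s = math.cos(angle), math.sin(angle)
    w_old = layout.weight_total()
    subs = []
    for su in layout.subunits:
        x, y = su.cx - cx, su.cy - cy  # recentred offsets from the RF center
        subs.append(
            replace(
                su,
                cx=half + c * x - s * y,
                cy=half + s * x + c * y,
                orientation=(su.orientation + angle) % math.pi,
                weight=su.weight / w_old * weight_total,
            )
        )
    return SubunitLayout(subs, layout.arena_size, layout.profile_kind)


def superimpose_layouts(
    a: SubunitLayout, b: SubunitLayout, rng, weight_total: float = 0.5
) -> list[SubunitLayout]:
    """Prepare two independent layouts for a dual-mosaic model.

    Each layout is shifted so the Gaussian fit of its own receptive field
    is arena-centered, rotated by an independent uniform random angle
    about the arena center, and its weight total set to `weight_total`
    (0.5 by default, so the pair contributes equally).
    """
    rng = np.random.default_rng(rng)
    angles = rng.uniform(0.0, 2.0 * math.pi, size=2)
    return [
        _transform_layout(a, float(angles[0]), weight_total),
        _transform_layout(b, float(angles[1]), weight_total),
    ]
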