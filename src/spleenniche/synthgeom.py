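"""Synthetic spleen cross-section generator with known ground truth.

The generator emulates the anatomy quantified in confocal sections of the
murine spleen: an elliptical cross-section lined by a thin myofibroblastic
capsule, trabecular projections, white-pulp (WP) discs ringed by marginal
zones, and sparse blood/lymphatic vessels in the red pulp (RP).  Cells are
planted on the continuous (μm) domain under a configurable
distance-to-capsule law with a distance-dependent Ki-67 (proliferation)
state, so every downstream distance, profile and verdict can be checked
against a stored ground truth.  A proteomics abundance simulator plants
differential proteins for the same purpose.

Geometry is defined continuously in μm and rasterized last; analytic checks
(areas, distance laws) use the continuous definition so discretization
error stays separate from logic error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

__all__ = [
    "GeometryParams",
    "PlacementSpec",
    "IntensitySpec",
    "TissueGeometry",
    "IntensityImage",
    "AbundanceMatrix",
    "DistanceLaw",
    "UniformArea",
    "TruncExponential",
    "Piecewise",
    "make_tissue",
    "plant_cells",
    "render_channel",
    "scenario",
    "simulate_abundance",
    "SCENARIOS",
    "MARKER_COLUMNS",
]

MARKER_COLUMNS = ["Lin", "CD41", "CD48", "cKit", "CD150", "Sca1", "Ki67"]

# marker templates for the two imaged populations: pHSC = 3-(Lin-CD41-CD48-)
# c-kit+CD150+ (Sca-1+ in flow), HSPC = 3- c-kit+
PHSC_MARKERS = {
    "Lin": False, "CD41": False, "CD48": False,
    "cKit": True, "CD150": True, "Sca1": True,
}
HSPC_MARKERS = {
    "Lin": False, "CD41": False, "CD48": False,
    "cKit": True, "CD150": False, "Sca1": True,
}


class ParameterError(ValueError):
    """Invalid generator parameters."""


class ResolutionError(ParameterError):
    """Grid too coarse for the requested geometry."""


class PlacementError(RuntimeError):
    """Rejection sampling failed to place an object in the allowed region."""


class DesignError(ValueError):
    """Degenerate experimental design for the abundance simulator."""


# --------------------------------------------------------------------------
# distance laws
# --------------------------------------------------------------------------

class DistanceLaw:
    """Law of a planted cell's distance to the capsule's inner edge (μm)."""

    def sample(self, n: int, zone_max: float, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def mean(self, zone_max: float) -> float:
        raise NotImplementedError


@dataclass(frozen=True)
class UniformArea(DistanceLaw):
    """Positions uniform over the allowed region (the random-dot law).

    The induced distance law is the annulus-area law of the geometry, so
    there is no target distance to draw; :func:`plant_cells` samples
    positions directly.
    """

    def sample(self, n, zone_max, rng):  # pragma: no cover - not used directly
        raise TypeError("UniformArea has no target-distance sampler; "
                        "positions are drawn uniformly over the region")


@dataclass(frozen=True)
class TruncExponential(DistanceLaw):
    """Exponential(scale) shifted by ``shift`` and truncated to [shift, zone_max]."""

    scale: float
    shift: float = 0.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ParameterError("TruncExponential scale must be positive")
        if self.shift < 0:
            raise ParameterError("TruncExponential shift must be >= 0")

    def sample(self, n, zone_max, rng):
        span = zone_max - self.shift
        if span <= 0:
            raise ParameterError("zone_max must exceed the law's shift")
        u = rng.random(n)
        # inverse CDF of Exp(scale) truncated to [0, span]
        tail = -np.expm1(-span / self.scale)
        return self.shift - self.scale * np.log1p(-u * tail)

    def mean(self, zone_max):
        span = zone_max - self.shift
        s = self.scale
        tail = -math.expm1(-span / s)
        return self.shift + s - span * math.exp(-span / s) / tail

    def log_pdf(self, d: np.ndarray, zone_max: float) -> np.ndarray:
        span = zone_max - self.shift
        tail = -math.expm1(-span / self.scale)
        x = np.asarray(d, float) - self.shift
        out = np.full_like(x, -np.inf)
        ok = (x >= 0) & (x <= span)
        out[ok] = -x[ok] / self.scale - math.log(self.scale * tail)
        return out


@dataclass(frozen=True)
class Piecewise(DistanceLaw):
    """Piecewise-uniform law over distance bins [edges[i], edges[i+1])."""

    edges: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        edges = np.asarray(self.edges, float)
        w = np.asarray(self.weights, float)
        if len(edges) != len(w) + 1 or np.any(np.diff(edges) <= 0):
            raise ParameterError("Piecewise needs strictly increasing edges, "
                                 "one more edge than weights")
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ParameterError("Piecewise weights must be >= 0 and sum to 1")

    def sample(self, n, zone_max, rng):
        edges = np.asarray(self.edges, float)
        if edges[-1] > zone_max + 1e-9:
            raise ParameterError("Piecewise support exceeds zone_max")
        bins = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        lo, hi = edges[bins], edges[bins + 1]
        return lo + rng.random(n) * (hi - lo)

    def mean(self, zone_max):
        edges = np.asarray(self.edges, float)
        mids = 0.5 * (edges[:-1] + edges[1:])
        return float(np.dot(mids, self.weights))


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryParams:
    """Continuous description of one synthetic spleen cross-section.

    Lengths are μm.  ``a``/``b`` are the outer semi-axes; ``capsule_width``
    is the α-SMA⁺ myofibroblast band just inside the outline.  Densities
    are target area fractions of the region the structure occupies.
    """

    shape: Literal["disk", "ellipse"] = "ellipse"
    a: float = 1500.0
    b: float = 1000.0
    capsule_width: float = 20.0
    n_trabeculae: int = 6
    trabecula_length: float = 300.0
    trabecula_width: float = 30.0
    n_wp_discs: int = 8
    wp_radius_range: tuple[float, float] = (80.0, 150.0)
    marginal_ring_width: float = 25.0
    vessel_density_rp: float = 0.08
    vessel_density_wp: float = 0.02
    lymph_density_rp: float = 0.01
    pixel_size: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.shape not in ("disk", "ellipse"):
            raise ParameterError(f"unknown shape {self.shape!r}")
        if self.shape == "disk" and self.a != self.b:
            raise ParameterError("disk requires a == b")
        if not (self.a >= self.b > self.capsule_width):
            raise ParameterError("require a >= b > capsule_width")
        if self.capsule_width < self.pixel_size:
            raise ResolutionError(
                f"capsule_width {self.capsule_width} μm is below one pixel "
                f"({self.pixel_size} μm); refine the grid")
        for name in ("vessel_density_rp", "vessel_density_wp", "lymph_density_rp"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ParameterError(f"{name} must be in [0, 1)")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")

    @property
    def analytic_area_mm2(self) -> float:
        """Area of the outer outline in mm²."""
        return math.pi * self.a * self.b / 1e6


@dataclass(frozen=True)
class PlacementSpec:
    """How to plant a synthetic cell population."""

    n_cells: int = 667
    distance_law: DistanceLaw = field(default_factory=lambda: TruncExponential(60.0))
    zone_max: float = 200.0
    ki67_intercept: float = -0.20
    ki67_slope: float = 0.009   # per μm; positive => proliferative cells sit deeper
    cell_radius: float = 3.0
    marker_profile: dict = field(default_factory=lambda: dict(PHSC_MARKERS))
    restrict_to: Literal["whole_cs", "red_pulp"] = "red_pulp"
    sex: str = "F"
    treatment: str = "steady"

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if self.zone_max <= 0:
            raise ParameterError("zone_max must be positive")
        if self.restrict_to not in ("whole_cs", "red_pulp"):
            raise ParameterError(f"unknown restrict_to {self.restrict_to!r}")


@dataclass(frozen=True)
class IntensitySpec:
    """Synthetic immunofluorescence channel (SDF-1α-like by default)."""

    channel_name: str = "SDF1a"
    base_level: float = 5.0
    capsule_level: float = 100.0
    stromal_cell_level: float = 60.0
    stromal_cell_fraction: float = 0.10
    noise_sd: float = 5.0
    scale_factor: float = 1.0

    def validate(self) -> None:
        if min(self.base_level, self.capsule_level, self.stromal_cell_level) < 0:
            raise ParameterError("intensity levels must be >= 0")
        if not (0 <= self.stromal_cell_fraction < 1):
            raise ParameterError("stromal_cell_fraction must be in [0, 1)")
        if self.noise_sd < 0 or self.scale_factor < 0:
            raise ParameterError("noise_sd and scale_factor must be >= 0")


# --------------------------------------------------------------------------
# continuous shape helpers
# --------------------------------------------------------------------------

def _point_ellipse_distance(x, y, a: float, b: float) -> np.ndarray:
    """Exact unsigned distance from points to the ellipse x²/a² + y²/b² = 1.

    Vectorized bisection on the orthogonal-projection parameter t of the
    nearest boundary point (e0²p0/(t+e0²), e1²p1/(t+e1²)); requires
    a > b > 0.  Points on the axes take the analytic closed forms.
    """
    p0 = np.abs(np.asarray(x, float))
    p1 = np.abs(np.asarray(y, float))
    shape = np.broadcast(p0, p1).shape
    p0b = np.broadcast_to(p0, shape).ravel()
    p1b = np.broadcast_to(p1, shape).ravel()
    e0s, e1s = a * a, b * b
    d = np.empty(p0b.shape)

    off_axis = p1b > 1e-9 * b
    q0, q1 = p0b[off_axis], p1b[off_axis]
    t0 = -e1s + b * q1
    t1 = -e1s + np.hypot(a * q0, b * q1)
    for _ in range(90):
        t = 0.5 * (t0 + t1)
        f = (a * q0 / (t + e0s)) ** 2 + (b * q1 / (t + e1s)) ** 2 - 1.0
        pos = f > 0
        t0 = np.where(pos, t, t0)
        t1 = np.where(pos, t1, t)
    t = 0.5 * (t0 + t1)
    cx = e0s * q0 / (t + e0s)
    cy = e1s * q1 / (t + e1s)
    d[off_axis] = np.hypot(cx - q0, cy - q1)

    # p1 == 0: nearest point on the major axis side, or off-axis for
    # interior points inside the evolute cusp
    ax = ~off_axis
    q0 = p0b[ax]
    crit = (e0s - e1s) / a
    near = q0 < crit
    xc = np.where(near, e0s * q0 / (e0s - e1s), a)
    yc2 = np.where(near, e1s * (1.0 - (xc / a) ** 2), 0.0)
    d[ax] = np.sqrt((xc - q0) ** 2 + np.maximum(yc2, 0.0))
    return d.reshape(shape)


@dataclass
class _Outline:
    """Continuous outer outline with an exact inside/boundary-distance test."""

    kind: str
    a: float
    b: float
    cx: float
    cy: float

    def inside(self, x, y):
        dx = (np.asarray(x, float) - self.cx) / self.a
        dy = (np.asarray(y, float) - self.cy) / self.b
        return dx * dx + dy * dy <= 1.0

    def boundary_distance(self, x, y):
        """Signed distance to the outline: positive inside, negative outside."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if self.kind == "disk" or self.a == self.b:
            r = np.hypot(x - self.cx, y - self.cy)
            return self.a - r
        d = _point_ellipse_distance(x - self.cx, y - self.cy, self.a, self.b)
        sign = np.where(self.inside(x, y), 1.0, -1.0)
        return (sign * d).reshape(np.shape(x))


@dataclass
class TissueGeometry:
    """Registered binary structure masks on a common grid.

    Masks (rows = y, cols = x, pixel centers at integer multiples of
    ``pixel_size`` starting at 0): ``cross_section``, ``capsule``,
    ``trabeculae``, ``wp``, ``marginal_zone``, ``blood_vessels``,
    ``lymph_vessels``.  The capsule, trabeculae and WP masks are pairwise
    disjoint (capsule takes precedence); vessels may overlap any
    compartment they irrigate.
    """

    masks: dict[str, np.ndarray]
    pixel_size: float
    center: tuple[float, float]
    params: GeometryParams | None = None
    # continuous internals, present only on freshly generated tissue
    _outline: _Outline | None = None
    _trabeculae_geom: object | None = None
    _wp_discs: list | None = None

    STRUCTURES = ("cross_section", "capsule", "trabeculae", "wp",
                  "marginal_zone", "blood_vessels", "lymph_vessels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks["cross_section"].shape

    @property
    def red_pulp(self) -> np.ndarray:
        """RP exclusive of WP (incl. marginal ring), capsule, trabeculae, vessels."""
        m = self.masks
        return (m["cross_section"] & ~m["wp"] & ~m["marginal_zone"]
                & ~m["capsule"] & ~m["trabeculae"]
                & ~m["blood_vessels"] & ~m["lymph_vessels"])

    def region_mask(self, name: str) -> np.ndarray:
        """Resolve a named region to a boolean raster.

        Beyond the stored structures: ``white_pulp`` = WP disc + marginal
        ring; ``core`` = cross-section minus capsule; ``red_pulp`` = the
        strict RP (vessels excluded); ``rp_domain`` = RP territory with its
        vessels included (the normalizing area for vascular density).
        """
        m = self.masks
        if name in m:
            return m[name]
        if name == "white_pulp":
            return m["wp"] | m["marginal_zone"]
        if name == "core":
            return m["cross_section"] & ~m["capsule"]
        if name == "red_pulp":
            return self.red_pulp
        if name == "rp_domain":
            return (m["cross_section"] & ~m["wp"] & ~m["marginal_zone"]
                    & ~m["capsule"] & ~m["trabeculae"])
        raise KeyError(f"unknown region {name!r}")

    def area_mm2(self, name: str) -> float:
        npx = int(self.region_mask(name).sum())
        return npx * self.pixel_size ** 2 / 1e6

    def capsule_distance(self, x, y):
        """Continuous distance to the capsule's inner edge (requires the
        continuous outline, i.e. a freshly generated tissue)."""
        if self._outline is None:
            raise RuntimeError("continuous outline unavailable on loaded tissue")
        w = self.params.capsule_width if self.params else 0.0
        return self._outline.boundary_distance(x, y) - w


@dataclass
class IntensityImage:
    """Single-channel synthetic fluorescence raster plus its SRC mask."""

    values: np.ndarray
    channel_name: str
    pixel_size: float
    src_mask: np.ndarray
    spec: IntensitySpec | None = None


# --------------------------------------------------------------------------
# tissue construction
# --------------------------------------------------------------------------

def _grid(params: GeometryParams):
    margin = 2 * params.pixel_size
    width = 2 * (params.a + margin)
    height = 2 * (params.b + margin)
    nx = int(math.ceil(width / params.pixel_size)) + 1
    ny = int(math.ceil(height / params.pixel_size)) + 1
    cx = (nx - 1) / 2 * params.pixel_size
    cy = (ny - 1) / 2 * params.pixel_size
    xs = np.arange(nx) * params.pixel_size
    ys = np.arange(ny) * params.pixel_size
    return xs, ys, cx, cy


def _paint_disks(mask: np.ndarray, centers, radii, pixel_size: float) -> None:
    """Set mask pixels whose centers fall inside any of the given disks."""
    ny, nx = mask.shape
    for (cx, cy), r in zip(centers, radii):
        j0 = max(0, int((cx - r) / pixel_size) - 1)
        j1 = min(nx, int((cx + r) / pixel_size) + 2)
        i0 = max(0, int((cy - r) / pixel_size) - 1)
        i1 = min(ny, int((cy + r) / pixel_size) + 2)
        if j0 >= j1 or i0 >= i1:
            continue
        xs = np.arange(j0, j1) * pixel_size
        ys = np.arange(i0, i1) * pixel_size
        dx = xs[None, :] - cx
        dy = ys[:, None] - cy
        mask[i0:i1, j0:j1] |= dx * dx + dy * dy <= r * r


def _place_vessels(rng, domain_ok, domain_mask, radius_range, target_fraction,
                   bbox, pixel_size, max_iter=20000):
    """Add random disks until they cover ``target_fraction`` of ``domain_mask``.

    ``domain_ok(x, y)`` is the continuous acceptance test for disk centers;
    coverage is tracked on the raster, so the stopping rule sees exactly
    what the measurement layer will see.
    """
    vessel = np.zeros_like(domain_mask)
    total = int(domain_mask.sum())
    if target_fraction <= 0 or total == 0:
        return vessel
    (x0, x1), (y0, y1) = bbox
    covered = 0
    for _ in range(max_iter):
        if covered / total >= target_fraction:
            break
        x = x0 + rng.random() * (x1 - x0)
        y = y0 + rng.random() * (y1 - y0)
        if not bool(np.asarray(domain_ok(x, y)).item()):
            continue
        r = rng.uniform(*radius_range)
        _paint_disks(vessel, [(x, y)], [r], pixel_size)
        covered = int((vessel & domain_mask).sum())
    return vessel


def make_tissue(params: GeometryParams) -> TissueGeometry:
    """Rasterize a synthetic spleen cross-section from continuous parameters.

    Deterministic for a fixed ``params.seed``.  The returned masks satisfy
    the set identities documented on :class:`TissueGeometry`; the
    rasterized cross-section area is within 2% of the analytic shape area
    at the default 5 μm pixel size.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size
    xs, ys, cx, cy = _grid(params)
    X, Y = np.meshgrid(xs, ys)

    outline = _Outline(params.shape, params.a, params.b, cx, cy)
    bd = outline.boundary_distance(X, Y)
    cross_section = bd >= 0
    capsule = cross_section & (bd <= params.capsule_width)

    # trabeculae: rectangles projecting inward from the capsule along the
    # local normal, like the α-SMA+ trabecular network
    trab_polys = []
    for _ in range(params.n_trabeculae):
        theta = rng.uniform(0, 2 * math.pi)
        length = params.trabecula_length * rng.uniform(0.7, 1.3)
        width = params.trabecula_width * rng.uniform(0.7, 1.3)
        # boundary point and inward normal of the ellipse at parameter theta
        bx = cx + params.a * math.cos(theta)
        by = cy + params.b * math.sin(theta)
        nxv = math.cos(theta) / params.a
        nyv = math.sin(theta) / params.b
        norm = math.hypot(nxv, nyv)
        n_vec = np.array([-nxv / norm, -nyv / norm])   # inward normal
        t_vec = np.array([-n_vec[1], n_vec[0]])        # tangent
        p0 = np.array([bx, by])
        half = width / 2
        poly = Polygon([
            p0 + t_vec * half,
            p0 - t_vec * half,
            p0 - t_vec * half + n_vec * length,
            p0 + t_vec * half + n_vec * length,
        ])
        trab_polys.append(poly)
    trab_geom = shapely.union_all(trab_polys) if trab_polys else None
    if trab_polys:
        trabeculae = shapely.contains_xy(trab_geom, X.ravel(), Y.ravel())
        trabeculae = trabeculae.reshape(X.shape) & cross_section & ~capsule
    else:
        trabeculae = np.zeros_like(cross_section)

    # white-pulp discs with marginal rings, fully inside the core
    wp_discs: list[tuple[float, float, float]] = []
    ring = params.marginal_ring_width
    attempts = 0
    while len(wp_discs) < params.n_wp_discs and attempts < 20000:
        attempts += 1
        r = rng.uniform(*params.wp_radius_range)
        x = cx + rng.uniform(-params.a, params.a)
        y = cy + rng.uniform(-params.b, params.b)
        need = params.capsule_width + r + ring + 2 * px
        if outline.boundary_distance(x, y) < need:
            continue
        if trab_geom is not None and shapely.distance(
                shapely.points(x, y), trab_geom) < r + ring:
            continue
        if any(math.hypot(x - ox, y - oy) < r + orad + 2 * ring + 2 * px
               for ox, oy, orad in wp_discs):
            continue
        wp_discs.append((x, y, r))
    if len(wp_discs) < params.n_wp_discs:
        raise PlacementError(
            f"could only place {len(wp_discs)}/{params.n_wp_discs} WP discs; "
            "geometry too crowded")
    wp = np.zeros_like(cross_section)
    wp_with_ring = np.zeros_like(cross_section)
    _paint_disks(wp, [(x, y) for x, y, _ in wp_discs],
                 [r for _, _, r in wp_discs], px)
    _paint_disks(wp_with_ring, [(x, y) for x, y, _ in wp_discs],
                 [r + ring for _, _, r in wp_discs], px)
    marginal = wp_with_ring & ~wp

    def in_rp_domain(x, y):
        """Continuous test: inside the core, outside trabeculae and WP+ring."""
        ok = outline.boundary_distance(x, y) > params.capsule_width
        if trab_geom is not None:
            ok = ok & ~shapely.contains_xy(trab_geom, x, y)
        for ox, oy, orad in wp_discs:
            ok = ok & (np.hypot(np.asarray(x) - ox, np.asarray(y) - oy)
                       > orad + ring)
        return ok

    def in_vascular_bed(x, y):
        """Vessel centers: anywhere in the tissue except WP+ring — the
        vascular bed reaches the capsule (subcapsular sinuses, penetrating
        trabecular vessels), so vessel proximity is independent of a
        cell's capsule distance."""
        ok = outline.boundary_distance(x, y) > 0
        for ox, oy, orad in wp_discs:
            ok = ok & (np.hypot(np.asarray(x) - ox, np.asarray(y) - oy)
                       > orad + ring)
        return ok

    rp_domain = (cross_section & ~capsule & ~trabeculae & ~wp & ~marginal)
    bbox = ((cx - params.a, cx + params.a), (cy - params.b, cy + params.b))
    blood = _place_vessels(rng, in_vascular_bed, rp_domain, (6.0, 15.0),
                           params.vessel_density_rp, bbox, px)

    def in_wp(x, y):
        return any(math.hypot(x - ox, y - oy) <= orad for ox, oy, orad in wp_discs)

    wp_vessels = _place_vessels(rng, in_wp, wp, (4.0, 8.0),
                                params.vessel_density_wp, bbox, px)
    blood = blood | wp_vessels
    lymph = _place_vessels(rng, in_vascular_bed, rp_domain, (5.0, 10.0),
                           params.lymph_density_rp, bbox, px)

    masks = {
        "cross_section": cross_section,
        "capsule": capsule,
        "trabeculae": trabeculae,
        "wp": wp,
        "marginal_zone": marginal,
        "blood_vessels": blood & cross_section,
        "lymph_vessels": lymph & cross_section,
    }
    return TissueGeometry(masks=masks, pixel_size=px, center=(cx, cy),
                          params=params, _outline=outline,
                          _trabeculae_geom=trab_geom, _wp_discs=wp_discs)


# --------------------------------------------------------------------------
# cell placement
# --------------------------------------------------------------------------

def _region_ok(tissue: TissueGeometry, x, y, restrict_to: str):
    """Continuous membership test for cell centers."""
    d = tissue.capsule_distance(x, y)
    ok = d >= 0
    if restrict_to == "red_pulp":
        if tissue._trabeculae_geom is not None:
            ok = ok & ~shapely.contains_xy(tissue._trabeculae_geom, x, y)
        ring = tissue.params.marginal_ring_width
        for ox, oy, orad in tissue._wp_discs or []:
            ok = ok & (np.hypot(np.asarray(x) - ox, np.asarray(y) - oy)
                       > orad + ring)
    return ok, d


MAX_REJECTIONS = 10_000


def plant_cells(tissue: TissueGeometry, spec: PlacementSpec,
                seed: int, *, image_id: str = "img0",
                animal_id: str = "m0") -> pd.DataFrame:
    """Plant ``spec.n_cells`` synthetic cells and record their ground truth.

    Cells are placed by rejection sampling on the continuous domain: for a
    target distance drawn from ``spec.distance_law``, a uniform candidate
    position is accepted when its true capsule distance falls within one
    pixel of the target, which makes the planted distance law exact up to
    that tolerance band.  ``true_distance_um`` stores the continuous
    center-to-capsule distance; Ki-67 state is Bernoulli with a
    logit-linear dependence on that distance.
    """
    spec.validate()
    if tissue._outline is None:
        raise RuntimeError("plant_cells requires a freshly generated tissue")
    rng = np.random.default_rng(seed)
    params = tissue.params
    cx, cy = tissue.center
    tol = tissue.pixel_size
    zone_max = spec.zone_max

    # feasibility: the deepest reachable point
    max_depth = params.b - params.capsule_width
    if zone_max > max_depth + tol:
        zone_max = max_depth  # cap at the geometry's reach

    xs_lo, xs_hi = cx - params.a, cx + params.a
    ys_lo, ys_hi = cy - params.b, cy + params.b

    uniform = isinstance(spec.distance_law, UniformArea)
    targets = None if uniform else spec.distance_law.sample(
        spec.n_cells, zone_max, rng)

    pos = np.empty((spec.n_cells, 2))
    true_d = np.empty(spec.n_cells)
    if uniform:
        # vectorized: accept every admissible candidate until n are placed
        filled = 0
        drawn = 0
        while filled < spec.n_cells:
            m = max(4096, 2 * (spec.n_cells - filled))
            if drawn > MAX_REJECTIONS * spec.n_cells:
                raise PlacementError("uniform placement failed; empty region?")
            drawn += m
            xb = xs_lo + rng.random(m) * (xs_hi - xs_lo)
            yb = ys_lo + rng.random(m) * (ys_hi - ys_lo)
            ok, d = _region_ok(tissue, xb, yb, spec.restrict_to)
            ok &= d <= zone_max
            hits = np.flatnonzero(ok)[:spec.n_cells - filled]
            pos[filled:filled + hits.size, 0] = xb[hits]
            pos[filled:filled + hits.size, 1] = yb[hits]
            true_d[filled:filled + hits.size] = d[hits]
            filled += hits.size
        return _finish_cells(spec, pos, true_d, rng, image_id, animal_id)

    batch = 512
    for i in range(spec.n_cells):
        placed = False
        tries = 0
        while tries < MAX_REJECTIONS:
            xb = xs_lo + rng.random(batch) * (xs_hi - xs_lo)
            yb = ys_lo + rng.random(batch) * (ys_hi - ys_lo)
            ok, d = _region_ok(tissue, xb, yb, spec.restrict_to)
            ok = ok & (np.abs(d - targets[i]) <= tol)
            hits = np.flatnonzero(ok)
            tries += batch
            if hits.size:
                j = hits[0]
                pos[i] = (xb[j], yb[j])
                true_d[i] = d[j]
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"no admissible position found for cell {i} after "
                f"{MAX_REJECTIONS} rejections (zone_max={spec.zone_max}, "
                f"restrict_to={spec.restrict_to})")
    return _finish_cells(spec, pos, true_d, rng, image_id, animal_id)


def _finish_cells(spec: PlacementSpec, pos: np.ndarray, true_d: np.ndarray,
                  rng: np.random.Generator, image_id: str,
                  animal_id: str) -> pd.DataFrame:
    logit = spec.ki67_intercept + spec.ki67_slope * true_d
    p_ki67 = 1.0 / (1.0 + np.exp(-logit))
    ki67 = rng.random(spec.n_cells) < p_ki67

    cells = pd.DataFrame({
        "x_um": pos[:, 0],
        "y_um": pos[:, 1],
        "radius_um": spec.cell_radius,
    })
    for m in MARKER_COLUMNS:
        if m == "Ki67":
            cells[m] = ki67
        else:
            cells[m] = bool(spec.marker_profile.get(m, False))
    cells["sex"] = spec.sex
    cells["treatment"] = spec.treatment
    cells["animal_id"] = animal_id
    cells["image_id"] = image_id
    cells["true_distance_um"] = true_d
    return cells


# --------------------------------------------------------------------------
# intensity channel
# --------------------------------------------------------------------------

def render_channel(tissue: TissueGeometry, spec: IntensitySpec,
                   seed: int) -> IntensityImage:
    """Render a synthetic fluorescence channel.

    Capsule pixels carry ``capsule_level * scale_factor`` (the perturbation
    scale models the G-CSF-induced drop in capsular SDF-1α); a random
    ``stromal_cell_fraction`` of strict-RP pixels are designated stromal
    reticular cells (SRC) at ``stromal_cell_level``; everything else in the
    cross-section sits at ``base_level``.  Gaussian noise of ``noise_sd``
    is added on top.  Deterministic per seed.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    img = np.zeros(tissue.shape, float)
    cs = tissue.masks["cross_section"]
    img[cs] = spec.base_level
    img[tissue.masks["capsule"]] = spec.capsule_level * spec.scale_factor

    rp = tissue.red_pulp
    rp_idx = np.flatnonzero(rp.ravel())
    n_src = int(round(spec.stromal_cell_fraction * rp_idx.size))
    src = np.zeros(tissue.shape, bool)
    if n_src:
        chosen = rng.choice(rp_idx, size=n_src, replace=False)
        src.ravel()[chosen] = True
        img[src] = spec.stromal_cell_level
    if spec.noise_sd > 0:
        img[cs] += rng.normal(0.0, spec.noise_sd, int(cs.sum()))
    return IntensityImage(values=img, channel_name=spec.channel_name,
                          pixel_size=tissue.pixel_size, src_mask=src, spec=spec)


# --------------------------------------------------------------------------
# scenario presets
# --------------------------------------------------------------------------

def _steady_geometry(seed: int = 0) -> GeometryParams:
    return GeometryParams(seed=seed)


def scenario(name: str, *, seed: int = 0
             ) -> tuple[GeometryParams, PlacementSpec, IntensitySpec]:
    """Named study conditions.

    ``steady_female`` / ``steady_male``: homeostatic sections; the female
    law concentrates ~65% of cells within 0–60 μm of the capsule and the
    male law has a larger mean, matching the reported ordering.  ``gcsf``:
    mobilization — the distance-law mode shifts ~30 μm outward inside the
    unchanged 200 μm zone and capsular SDF-1α intensity is scaled to 0.4.
    ``gcsf_rev``: recovery after mobilization, back to the steady law with
    intensity restored.  ``fu5``: myeloablation — the occupied zone expands
    to ≈400 μm.
    """
    geom = _steady_geometry(seed)
    intensity = IntensitySpec()
    if name == "steady_female":
        place = PlacementSpec(n_cells=667, distance_law=TruncExponential(60.0),
                              zone_max=200.0, sex="F", treatment="steady")
    elif name == "steady_male":
        place = PlacementSpec(n_cells=320, distance_law=TruncExponential(120.0),
                              zone_max=200.0, sex="M", treatment="steady")
    elif name == "gcsf":
        place = PlacementSpec(n_cells=600,
                              distance_law=TruncExponential(60.0, shift=30.0),
                              zone_max=200.0, sex="F", treatment="gcsf")
        intensity = replace(intensity, scale_factor=0.4)
    elif name == "gcsf_rev":
        place = PlacementSpec(n_cells=600, distance_law=TruncExponential(60.0),
                              zone_max=200.0, sex="F", treatment="gcsf_rev")
    elif name == "fu5":
        # myeloablation randomizes positions through an expanded ≈400 μm zone
        place = PlacementSpec(n_cells=660, distance_law=UniformArea(),
                              zone_max=400.0, sex="F", treatment="fu5")
    else:
        raise KeyError(f"unknown scenario {name!r}")
    return geom, place, intensity


SCENARIOS = ("steady_female", "steady_male", "gcsf", "gcsf_rev", "fu5")


# --------------------------------------------------------------------------
# proteomics abundance simulator
# --------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Protein × sample intensity matrix with sample labels.

    ``values``: linear-scale intensities, NaN = not detected.  ``samples``:
    one row per column of ``values`` with cell_type / biorep / techrep.
    ``truth``: planted log2 fold changes (generator output only).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame | None = None

    def columns_for(self, cell_type: str) -> list[str]:
        return list(self.samples.index[self.samples["cell_type"] == cell_type])


def _dropout_threshold(log2x: np.ndarray, rate: float, slope: float) -> float:
    """Solve for the logistic dropout midpoint giving the target overall rate."""
    lo, hi = log2x.min() - 20, log2x.max() + 20
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        r = float(np.mean(1.0 / (1.0 + np.exp((log2x - mid) / slope))))
        if r < rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_abundance(n_proteins: int = 2431,
                       groups: dict[str, int] | None = None,
                       effects: pd.DataFrame | None = None,
                       missing_rate: float = 0.05,
                       seed: int = 0,
                       *,
                       n_tech: int = 3,
                       base_mean: float = 20.0,
                       base_sd: float = 2.0,
                       bio_sd: float = 0.5,
                       tech_sd: float = 0.2,
                       dropout_slope: float = 1.0) -> AbundanceMatrix:
    """Simulate a label-free proteomics matrix with planted effects.

    Intensities are log-normal: protein baselines (log2) are
    N(``base_mean``, ``base_sd``), biological replicates add
    N(0, ``bio_sd``), technical runs add N(0, ``tech_sd``); planted
    ``effects`` (rows = protein id, columns = group, values = log2 fold
    change vs baseline) shift group means.  Missingness is applied at
    ``missing_rate`` overall through a logistic intensity-dependent
    dropout, mimicking the left-censoring of label-free MS.
    """
    if groups is None:
        groups = {"CTM": 6, "STC": 6, "LSK": 6}
    if not (0 <= missing_rate < 1):
        raise ParameterError("missing_rate must be in [0, 1)")
    for g, n in groups.items():
        if n < 2:
            raise DesignError(f"group {g!r} has {n} sample(s); need >= 2")
    rng = np.random.default_rng(seed)

    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    eff = pd.DataFrame(0.0, index=proteins, columns=list(groups))
    if effects is not None:
        bad = effects.index.difference(eff.index)
        if len(bad):
            raise ParameterError(f"effects reference unknown proteins: {list(bad)[:5]}")
        bad = [c for c in effects.columns if c not in eff.columns]
        if bad:
            raise ParameterError(f"effects reference unknown groups: {bad}")
        eff.loc[effects.index, effects.columns] = effects.astype(float)

    base = rng.normal(base_mean, base_sd, n_proteins)
    cols, col_meta, data = [], [], []
    for g, n_bio in groups.items():
        for b in range(1, n_bio + 1):
            bio = base + eff[g].to_numpy() + rng.normal(0, bio_sd, n_proteins)
            for t in range(1, n_tech + 1):
                name = f"{g}_{b}_{t}"
                cols.append(name)
                col_meta.append((name, g, b, t))
                data.append(bio + rng.normal(0, tech_sd, n_proteins))
    log2x = np.column_stack(data)

    if missing_rate > 0:
        mid = _dropout_threshold(log2x, missing_rate, dropout_slope)
        p_miss = 1.0 / (1.0 + np.exp((log2x - mid) / dropout_slope))
        miss = rng.random(log2x.shape) < p_miss
    else:
        miss = np.zeros(log2x.shape, bool)

    values = pd.DataFrame(np.exp2(log2x), index=proteins, columns=cols)
    values = values.mask(miss)
    samples = pd.DataFrame(col_meta, columns=["sample", "cell_type",
                                              "biorep", "techrep"]
                           ).set_index("sample")
    truth = eff.rename_axis("protein")
    return AbundanceMatrix(values=values, samples=samples, truth=truth)
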