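"""Matched random-dot Monte-Carlo null and distance-profile inference.

The core question — do cells sit preferentially close to a structure? — is
decided exactly the way the imaging workflow does it: for each image,
random dots (RDs) matched in count and size to the observed cells
(diameter ≈ 6 μm) are placed uniformly over the cross-section, 100
iterations per image; per-dot surface distances to the reference structure
form the null distribution.  Cells versus RDs are compared by unpaired
two-tailed Student's t on per-observation distances, and by per-bin t
tests across image-level binned frequency profiles (10/30/100 μm
intervals).  A structure earns a ``preferential_proximity`` verdict when
the cell mean is below the RD mean with p under the configured α.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .spatial import DistanceMap, boundary_distance_map, cell_surface_distance
from .synthgeom import TissueGeometry

__all__ = [
    "RandomDotSet",
    "FrequencyProfile",
    "TestResult",
    "NicheReport",
    "ReportConfig",
    "generate_random_dots",
    "rd_distances",
    "bin_profile",
    "compare_distances",
    "compare_profiles",
    "localization_report",
    "fit_trunc_exponential",
    "child_seed",
]


class EmptyProfileError(ValueError):
    """No distances to bin."""


class SampleSizeError(ValueError):
    """Too few observations for a test."""


def child_seed(master_seed: int, image_id: str) -> int:
    """Per-image RNG seed by stable hashing, reproducible under parallelism."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(image_id.encode())) % (2**31)


# --------------------------------------------------------------------------
# random dots
# --------------------------------------------------------------------------

@dataclass
class RandomDotSet:
    """Iterated matched null point sets with per-dot distances."""

    dots: pd.DataFrame            # columns iteration, x_um, y_um
    n_per_iteration: int
    n_iterations: int
    dot_radius: float
    domain: str
    seed: int
    distances: dict[str, np.ndarray] = field(default_factory=dict)
    per_iteration_means: dict[str, np.ndarray] = field(default_factory=dict)


def generate_random_dots(tissue: TissueGeometry, domain: str = "core",
                         n: int = 667, iterations: int = 100,
                         dot_radius: float = 3.0, seed: int = 0) -> RandomDotSet:
    """Uniform random dots over a named domain, ``iterations`` matched sets.

    Dots are drawn uniformly over domain pixels with sub-pixel jitter, so
    the empirical law converges to the annulus-area law of the domain.
    Dots may overlap each other.  Deterministic per seed.
    """
    if n < 1 or iterations < 1:
        raise ValueError("n and iterations must be >= 1")
    mask = tissue.region_mask(domain)
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        raise ValueError(f"domain {domain!r} is empty")
    rng = np.random.default_rng(seed)
    px = tissue.pixel_size
    _, nx = mask.shape
    total = n * iterations
    flat = rng.choice(idx, size=total, replace=True)
    iy, ix = np.divmod(flat, nx)
    x = (ix + rng.uniform(-0.5, 0.5, total)) * px
    y = (iy + rng.uniform(-0.5, 0.5, total)) * px
    dots = pd.DataFrame({
        "iteration": np.repeat(np.arange(iterations), n),
        "x_um": x,
        "y_um": y,
    })
    return RandomDotSet(dots=dots, n_per_iteration=n, n_iterations=iterations,
                        dot_radius=dot_radius, domain=domain, seed=seed)


def rd_distances(rds: RandomDotSet, dmap: DistanceMap) -> np.ndarray:
    """Pooled per-dot surface distances to a reference, cached on the set.

    Distances are pooled across the iterations for the null distribution
    and profile; per-iteration means are kept for an envelope summary.
    """
    d_center = dmap.at(rds.dots["x_um"].to_numpy(), rds.dots["y_um"].to_numpy())
    d = np.maximum(0.0, d_center - rds.dot_radius)
    rds.distances[dmap.reference] = d
    rds.per_iteration_means[dmap.reference] = (
        d.reshape(rds.n_iterations, rds.n_per_iteration).mean(axis=1))
    return d


# --------------------------------------------------------------------------
# profiles
# --------------------------------------------------------------------------

@dataclass
class FrequencyProfile:
    """Percent of observations per uniform distance interval."""

    bin_edges: np.ndarray         # closed-bin edges; len = n_closed_bins + 1
    percent: np.ndarray           # per closed bin, plus open bin if present
    n: int
    open_ended: bool = False
    grouping: str | None = None

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def occupancy(self, lo: float, hi: float) -> float:
        """Exact marginal sum of whole bins covering [lo, hi)."""
        edges = self.bin_edges
        sel = (edges[:-1] >= lo - 1e-9) & (edges[1:] <= hi + 1e-9)
        return float(self.percent[:len(edges) - 1][sel].sum())


def bin_profile(distances, bin_width: float, max_edge: float | None = None,
                *, grouping: str | None = None) -> FrequencyProfile:
    """Bin distances into half-open uniform intervals [k·w, (k+1)·w).

    With an explicit ``max_edge``, counts at or beyond it land in a final
    open-ended bin and zero-count bins below it are retained; otherwise
    the edge grid extends just past the largest distance.
    """
    d = np.asarray(distances, float)
    if d.size == 0:
        raise EmptyProfileError("no distances to bin")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    if max_edge is None:
        top = (np.floor(d.max() / bin_width) + 1) * bin_width
        open_ended = False
    else:
        top = max_edge
        open_ended = True
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    if open_ended:
        counts = np.append(counts, int((d >= top).sum()))
    percent = 100.0 * counts / d.size
    return FrequencyProfile(bin_edges=edges, percent=percent, n=d.size,
                            open_ended=open_ended, grouping=grouping)


# --------------------------------------------------------------------------
# tests
# --------------------------------------------------------------------------

@dataclass
class TestResult:
    """Unpaired two-tailed Student's t summary."""

    statistic: float
    p: float
    df: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("statistic", "p", "df", "mean_a", "sem_a",
                 "mean_b", "sem_b", "n_a", "n_b")}


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def compare_distances(a, b) -> TestResult:
    """Equal-variance two-tailed Student's t on per-observation distances."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise SampleSizeError("each group needs at least 2 observations")
    with warnings.catch_warnings():
        # near-identical groups trip scipy's precision-loss warning; the
        # degenerate case is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero variance in both groups
        t = 0.0
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return TestResult(statistic=t, p=p, df=float(len(a) + len(b) - 2),
                      mean_a=float(a.mean()), sem_a=_sem(a),
                      mean_b=float(b.mean()), sem_b=_sem(b),
                      n_a=len(a), n_b=len(b))


def compare_profiles(profiles_a: list[FrequencyProfile],
                     profiles_b: list[FrequencyProfile],
                     *, holm: bool = False) -> pd.DataFrame:
    """Per-bin Student's t across image-level percentages.

    Bins empty in every profile of both groups are flagged ND (not
    detected) and excluded from testing.  An optional Holm correction
    across tested bins is off by default.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise SampleSizeError("need >= 2 profiles per group")
    ref = profiles_a[0]
    for p in profiles_a + profiles_b:
        if (len(p.percent) != len(ref.percent)
                or not np.allclose(p.bin_edges, ref.bin_edges)):
            raise ValueError("profiles have mismatching bin structure")
    A = np.vstack([p.percent for p in profiles_a])
    B = np.vstack([p.percent for p in profiles_b])
    rows = []
    for k in range(A.shape[1]):
        lo = ref.bin_edges[k] if k < len(ref.bin_edges) - 1 else ref.bin_edges[-1]
        hi = (ref.bin_edges[k + 1] if k < len(ref.bin_edges) - 1
              else float("inf"))
        nd = not (A[:, k].any() or B[:, k].any())
        if nd:
            rows.append(dict(bin_lo=lo, bin_hi=hi, nd=True, t=np.nan, p=np.nan,
                             mean_a=0.0, sem_a=0.0, mean_b=0.0, sem_b=0.0))
            continue
        r = compare_distances(A[:, k], B[:, k])
        rows.append(dict(bin_lo=lo, bin_hi=hi, nd=False, t=r.statistic, p=r.p,
                         mean_a=r.mean_a, sem_a=r.sem_a,
                         mean_b=r.mean_b, sem_b=r.sem_b))
    out = pd.DataFrame(rows)
    if holm:
        tested = out.index[~out["nd"]]
        pvals = out.loc[tested, "p"].to_numpy()
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, j in enumerate(order):
            running = max(running, (m - rank) * pvals[j])
            adj[j] = min(1.0, running)
        out.loc[tested, "p_holm"] = adj
    return out


# --------------------------------------------------------------------------
# localization report
# --------------------------------------------------------------------------

@dataclass
class ReportConfig:
    """Knobs of the localization analysis, defaulting to the imaging protocol."""

    references: tuple[str, ...] = ("capsule",)
    cell_class: str = "pHSC"
    bin_widths: tuple[float, ...] = (10.0, 30.0, 100.0)
    profile_max_edge: float = 300.0
    iterations: int = 100
    dot_radius: float = 3.0
    alpha: float = 0.05
    rd_domain: str = "core"      # whole cross-section, capsule excluded
    seed: int = 0


@dataclass
class NicheReport:
    """Per-structure verdicts, profiles, occupancies and stratified contrasts."""

    cell_class: str
    n_cells: int
    references: dict
    profiles: dict
    occupancy: dict
    strata: dict
    config: ReportConfig

    def to_dict(self) -> dict:
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in vars(self.config).items()}
        return {
            "cell_class": self.cell_class,
            "n_cells": self.n_cells,
            "references": self.references,
            "profiles": self.profiles,
            "occupancy": self.occupancy,
            "strata": self.strata,
            "config": cfg,
        }


def _profile_dict(p: FrequencyProfile) -> dict:
    return {"bin_edges": [float(e) for e in p.bin_edges],
            "percent": [float(v) for v in p.percent],
            "n": p.n, "open_ended": p.open_ended}


def localization_report(cells: pd.DataFrame, tissue: TissueGeometry,
                        config: ReportConfig | None = None) -> NicheReport:
    """Run the full localization analysis for one tissue's cell table.

    Selects the configured cell class, generates RDs matched per image to
    the class count, measures surface distances to every configured
    reference, and assembles mean comparisons, binned profiles with
    per-bin tests (when ≥2 images), occupancy fractions and
    Ki-67/sex/treatment stratified contrasts.
    """
    config = config or ReportConfig()
    if config.cell_class in cells.columns:
        sel = cells[cells[config.cell_class].astype(bool)].copy()
    else:
        raise KeyError(f"cell table has no class column {config.cell_class!r}; "
                       "run classify_cells first")
    if len(sel) == 0:
        raise ValueError(f"no cells of class {config.cell_class!r}")

    image_ids = (sel["image_id"].unique().tolist()
                 if "image_id" in sel.columns else ["img0"])
    dmaps = {ref: boundary_distance_map(tissue, ref)
             for ref in config.references}

    # measured distances per reference
    for ref in config.references:
        sel = cell_surface_distance(sel, dmaps[ref])

    # matched RDs per image
    rd_by_image: dict[str, RandomDotSet] = {}
    for img in image_ids:
        n_img = int((sel["image_id"] == img).sum()) if "image_id" in sel.columns \
            else len(sel)
        rds = generate_random_dots(tissue, config.rd_domain, n_img,
                                   config.iterations, config.dot_radius,
                                   seed=child_seed(config.seed, str(img)))
        for ref in config.references:
            rd_distances(rds, dmaps[ref])
        rd_by_image[img] = rds

    references: dict = {}
    profiles: dict = {}
    occupancy: dict = {}
    for ref in config.references:
        col = f"dist_{ref}_um"
        cell_d = sel[col].to_numpy()
        rd_d = np.concatenate([rd_by_image[i].distances[ref] for i in image_ids])
        test = compare_distances(cell_d, rd_d)
        verdict = bool(test.mean_a < test.mean_b and test.p < config.alpha)
        references[ref] = {
            "cell_mean_um": test.mean_a, "cell_sem_um": test.sem_a,
            "rd_mean_um": test.mean_b, "rd_sem_um": test.sem_b,
            "n_cells": test.n_a, "n_dots": test.n_b,
            "test": test.to_dict(),
            "preferential_proximity": verdict,
            "rd_iteration_mean_range": [
                float(np.min(np.concatenate(
                    [rd_by_image[i].per_iteration_means[ref] for i in image_ids]))),
                float(np.max(np.concatenate(
                    [rd_by_image[i].per_iteration_means[ref] for i in image_ids]))),
            ],
        }

        profiles[ref] = {}
        for w in config.bin_widths:
            p_cells = bin_profile(cell_d, w, config.profile_max_edge)
            p_rd = bin_profile(rd_d, w, config.profile_max_edge)
            entry = {"cells": _profile_dict(p_cells), "rd": _profile_dict(p_rd)}
            if len(image_ids) >= 2:
                pa = [bin_profile(sel.loc[sel["image_id"] == i, col], w,
                                  config.profile_max_edge, grouping=str(i))
                      for i in image_ids]
                pb = [bin_profile(rd_by_image[i].distances[ref], w,
                                  config.profile_max_edge, grouping=str(i))
                      for i in image_ids]
                entry["per_bin_tests"] = compare_profiles(pa, pb).to_dict("records")
            profiles[ref][f"{w:g}um"] = entry

        p10_cells = bin_profile(cell_d, 10.0, config.profile_max_edge)
        p10_rd = bin_profile(rd_d, 10.0, config.profile_max_edge)
        occupancy[ref] = {
            "cells_pct_0_60": p10_cells.occupancy(0, 60),
            "cells_pct_0_100": p10_cells.occupancy(0, 100),
            "cells_pct_100_200": p10_cells.occupancy(100, 200),
            "rd_pct_0_60": p10_rd.occupancy(0, 60),
            "rd_pct_0_100": p10_rd.occupancy(0, 100),
            "rd_pct_100_200": p10_rd.occupancy(100, 200),
        }

    # stratified contrasts on the first reference
    strata: dict = {}
    ref0 = config.references[0]
    col0 = f"dist_{ref0}_um"
    if "Ki67" in sel.columns and sel["Ki67"].nunique() == 2:
        neg = sel.loc[~sel["Ki67"].astype(bool), col0].to_numpy()
        pos = sel.loc[sel["Ki67"].astype(bool), col0].to_numpy()
        if len(neg) >= 2 and len(pos) >= 2:
            t = compare_distances(neg, pos)
            strata["ki67"] = {"quiescent_mean_um": t.mean_a,
                              "proliferative_mean_um": t.mean_b,
                              "pct_ki67_pos": 100.0 * len(pos) / len(sel),
                              "test": t.to_dict()}
    for colname, key in (("sex", "sex"), ("treatment", "treatment")):
        if colname in sel.columns and sel[colname].nunique() >= 2:
            levels = sorted(sel[colname].unique())
            pairs = {}
            for i_, a_ in enumerate(levels):
                for b_ in levels[i_ + 1:]:
                    da = sel.loc[sel[colname] == a_, col0].to_numpy()
                    db = sel.loc[sel[colname] == b_, col0].to_numpy()
                    if len(da) >= 2 and len(db) >= 2:
                        pairs[f"{a_}_vs_{b_}"] = compare_distances(da, db).to_dict()
            if pairs:
                strata[key] = pairs

    return NicheReport(cell_class=config.cell_class, n_cells=len(sel),
                       references=references, profiles=profiles,
                       occupancy=occupancy, strata=strata, config=config)


# --------------------------------------------------------------------------
# parameter recovery
# --------------------------------------------------------------------------

def fit_trunc_exponential(distances, zone_max: float,
                          shift: float = 0.0) -> float:
    """Maximum-likelihood scale of a truncated exponential distance law.

    Fits Exp(scale) truncated to [shift, zone_max] to measured distances;
    the one free parameter is found by bounded scalar minimization of the
    negative log-likelihood.
    """
    d = np.asarray(distances, float) - shift
    span = zone_max - shift
    d = np.clip(d, 0.0, span)
    if d.size == 0:
        raise SampleSizeError("no distances to fit")

    def nll(s):
        tail = -np.expm1(-span / s)
        return float(np.sum(d) / s + d.size * (np.log(s) + np.log(tail)))

    res = optimize.minimize_scalar(nll, bounds=(0.5, 10 * span), method="bounded")
    return float(res.x)
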