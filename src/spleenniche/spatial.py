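"""Measurement layer: distances, zones, areas, densities, intensities.

Mirrors the imaging workflow: an exact Euclidean distance transform of a
reference structure mask stands in for the pseudo-surface distance, cell
distances are surface-to-surface (centroid distance minus cell radius,
clipped at zero), the cross-section is partitioned into the ~200 μm
peripheral capsular zone and the inner core, and structure/cell densities
and per-region intensities are reported on the paper's scales (μm, mm²,
percent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthgeom import IntensityImage, TissueGeometry

__all__ = [
    "DistanceMap",
    "RegionPartition",
    "boundary_distance_map",
    "distance_map_from_mask",
    "cell_surface_distance",
    "classify_cells",
    "partition_regions",
    "structure_density",
    "cell_density",
    "region_intensity",
]


class ReferenceError(ValueError):
    """Empty or unusable reference structure."""


class SchemaError(KeyError):
    """Required column missing from a cell table."""


@dataclass
class DistanceMap:
    """Per-pixel Euclidean distance (μm) to the nearest reference pixel."""

    values: np.ndarray
    reference: str
    pixel_size: float

    def at(self, x_um, y_um, *, order: int = 1) -> np.ndarray:
        """Sample the map at continuous μm coordinates (bilinear by default).

        Pixel centers sit at integer multiples of ``pixel_size`` starting
        at (0, 0); coordinates outside the raster raise.
        """
        x = np.asarray(x_um, float) / self.pixel_size
        y = np.asarray(y_um, float) / self.pixel_size
        ny, nx = self.values.shape
        if np.any(x < 0) or np.any(y < 0) or np.any(x > nx - 1) or np.any(y > ny - 1):
            raise ValueError("coordinates fall outside the raster")
        return ndimage.map_coordinates(self.values, [np.atleast_1d(y),
                                                     np.atleast_1d(x)],
                                       order=order, mode="nearest")


def distance_map_from_mask(mask: np.ndarray, pixel_size: float,
                           reference: str = "mask") -> DistanceMap:
    """Exact EDT (not chamfer) of an arbitrary reference mask."""
    if not mask.any():
        raise ReferenceError(f"reference mask {reference!r} is empty")
    values = ndimage.distance_transform_edt(~mask, sampling=pixel_size)
    return DistanceMap(values=values, reference=reference, pixel_size=pixel_size)


def boundary_distance_map(tissue: TissueGeometry, reference: str) -> DistanceMap:
    """Distance map to a named structure of the tissue.

    ``reference`` may be any name resolvable by
    :meth:`TissueGeometry.region_mask` (``capsule``, ``blood_vessels``,
    ``lymph_vessels``, ...) or ``capsule+trabeculae`` for the combined
    α-SMA⁺ reference.
    """
    if reference == "capsule+trabeculae":
        mask = tissue.masks["capsule"] | tissue.masks["trabeculae"]
    else:
        mask = tissue.region_mask(reference)
    return distance_map_from_mask(mask, tissue.pixel_size, reference)


def cell_surface_distance(cells: pd.DataFrame, dmap: DistanceMap,
                          *, column: str | None = None) -> pd.DataFrame:
    """Add surface-to-surface distances to a cell table.

    distance = max(0, EDT at centroid − cell radius); cells overlapping
    the reference get 0.  Two columns are added: ``dist_<ref>_um`` (the
    surface distance) and ``dist_<ref>_center_um`` (the raw centroid
    distance, the quantity comparable to the planted ground truth).
    """
    for c in ("x_um", "y_um", "radius_um"):
        if c not in cells.columns:
            raise SchemaError(f"cell table lacks required column {c!r}")
    col = column or f"dist_{dmap.reference}_um"
    center = dmap.at(cells["x_um"].to_numpy(), cells["y_um"].to_numpy())
    out = cells.copy()
    out[col.replace("_um", "_center_um")] = center
    out[col] = np.maximum(0.0, center - cells["radius_um"].to_numpy())
    return out


# marker logic: 3- = Lin-CD41-CD48-
_IMAGING_REQUIRED = ["Lin", "CD41", "CD48", "cKit", "CD150"]
_FLOW_REQUIRED = _IMAGING_REQUIRED + ["Sca1"]


def classify_cells(cells: pd.DataFrame, scheme: str = "imaging") -> pd.DataFrame:
    """Set class flags from marker booleans.

    imaging: pHSC = 3⁻c-kit⁺CD150⁺, HSPC = 3⁻c-kit⁺ (pHSC ⊆ HSPC).
    flow: adds Sca-1 — LT_HSC = 3⁻Sca-1⁺c-kit⁺CD150⁺, ST_HSC = same but
    CD150⁻.  ``quiescent`` = Ki-67⁻ where a Ki67 column exists.
    """
    required = {"imaging": _IMAGING_REQUIRED, "flow": _FLOW_REQUIRED}.get(scheme)
    if required is None:
        raise ValueError(f"unknown scheme {scheme!r}")
    missing = [c for c in required if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table lacks marker column(s) {missing}")
    out = cells.copy()
    triple_neg = ~out["Lin"] & ~out["CD41"] & ~out["CD48"]
    out["HSPC"] = triple_neg & out["cKit"]
    out["pHSC"] = out["HSPC"] & out["CD150"]
    if scheme == "flow":
        lsk = out["HSPC"] & out["Sca1"]
        out["LT_HSC"] = lsk & out["CD150"]
        out["ST_HSC"] = lsk & ~out["CD150"]
    if "Ki67" in out.columns:
        out["quiescent"] = ~out["Ki67"]
    return out


@dataclass
class RegionPartition:
    """Capsular zone / inner core split plus compartment areas (mm²)."""

    regions: dict[str, np.ndarray]
    capsular_width: float
    pixel_size: float

    @property
    def areas(self) -> dict[str, float]:
        return {name: mask.sum() * self.pixel_size ** 2 / 1e6
                for name, mask in self.regions.items()}


def partition_regions(tissue: TissueGeometry, capsular_width: float = 200.0,
                      *, rp_definition: str = "strict") -> RegionPartition:
    """Split the cross-section into the peripheral capsular zone and core.

    The capsular zone is the band of cross-section pixels within
    ``capsular_width`` μm of the tissue outline (the ~200-μm-wide
    sub-capsular hematopoietic zone); the inner core is the rest, so the
    two tile the cross-section exactly.  ``rp_definition='strict'``
    excludes WP, capsule, trabeculae and vessels from the red pulp;
    ``'cs_minus_wp'`` keeps everything but WP (the boundary-marker-only
    definition).
    """
    if capsular_width <= 0:
        raise ValueError("capsular_width must be positive")
    cs = tissue.masks["cross_section"]
    # distance to the tissue outline = EDT of the outside
    d_out = ndimage.distance_transform_edt(cs, sampling=tissue.pixel_size)
    capsular_zone = cs & (d_out <= capsular_width)
    inner_core = cs & ~capsular_zone
    if rp_definition == "strict":
        red_pulp = tissue.red_pulp
    elif rp_definition == "cs_minus_wp":
        red_pulp = cs & ~tissue.region_mask("white_pulp")
    else:
        raise ValueError(f"unknown rp_definition {rp_definition!r}")
    regions = {
        "whole_cs": cs,
        "capsular_zone": capsular_zone,
        "inner_core": inner_core,
        "red_pulp": red_pulp,
        "white_pulp": tissue.region_mask("white_pulp"),
    }
    return RegionPartition(regions=regions, capsular_width=capsular_width,
                           pixel_size=tissue.pixel_size)


def structure_density(tissue: TissueGeometry, structure: str,
                      partition: RegionPartition, region: str) -> float:
    """Percent of a region's area occupied by a structure.

    ``region`` resolves against the partition first, then against the
    tissue's named regions (e.g. ``rp_domain`` to normalize vascular area
    to the full red-pulp territory).
    """
    smask = (tissue.masks[structure] if structure in tissue.masks
             else tissue.region_mask(structure))
    rmask = (partition.regions[region] if region in partition.regions
             else tissue.region_mask(region))
    denom = int(rmask.sum())
    if denom == 0:
        raise ZeroDivisionError(f"region {region!r} has zero area")
    return 100.0 * int((smask & rmask).sum()) / denom


def cell_density(n_cells: int, area_mm2: float,
                 n_nucleated: int | None = None) -> tuple[float, float | None]:
    """(cells/mm², cells per million nucleated cells)."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    per_mm2 = n_cells / area_mm2
    per_million = None
    if n_nucleated is not None:
        if n_nucleated <= 0:
            raise ValueError("n_nucleated must be positive")
        per_million = 1e6 * n_cells / n_nucleated
    return per_mm2, per_million


def region_intensity(image: IntensityImage, tissue: TissueGeometry,
                     src_mask: np.ndarray | None = None) -> dict[str, float]:
    """Mean channel intensity over the capsule and over SRC pixels.

    SRC = SDF-1α⁺ α-SMA⁻ red-pulp stromal pixels; defaults to the mask the
    renderer designated.  Reported per image so group tests can treat
    images as observations.
    """
    if image.values.shape != tissue.shape:
        raise ValueError("image and tissue rasters are not aligned")
    src = image.src_mask if src_mask is None else src_mask
    out: dict[str, float] = {}
    cap = tissue.masks["capsule"]
    if not cap.any():
        raise ReferenceError("capsule mask is empty")
    out["capsule"] = float(image.values[cap].mean())
    if src is not None and src.any():
        out["src"] = float(image.values[src].mean())
    return out
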