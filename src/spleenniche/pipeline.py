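"""Orchestration, configuration, I/O and report assembly.

One :class:`RunConfig` drives simulation → spatial measurement → null-model
inference (→ optionally the proteomics stage) and produces tidy artifacts:
per-structure mask TIFFs with a JSON sidecar, cells/distances CSV, profile
and test CSVs, ``report.json`` and a ``manifest.json`` with config hash and
per-file checksums.  Units everywhere: μm for distances, mm² for areas,
percent on the 0–100 scale.  Re-running with the same config and seed
reproduces byte-identical non-log outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__, proteo, synthgeom
from .nullmodel import ReportConfig, localization_report
from .spatial import (SchemaError, boundary_distance_map, cell_surface_distance,
                      classify_cells, partition_regions, region_intensity)
from .synthgeom import (MARKER_COLUMNS, AbundanceMatrix, TissueGeometry,
                        make_tissue, plant_cells, render_channel, scenario)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "read_inputs",
           "write_tissue", "read_tissue", "write_cells", "read_cells",
           "config_hash"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class UnitError(ValueError):
    """Missing physical pixel size."""


@dataclass
class RunConfig:
    """All knobs of one reproducible run (defaults = the imaging protocol)."""

    scenario: str | None = "steady_female"
    tissue_dir: str | None = None      # alternative to scenario: input paths
    cells_csv: str | None = None
    references: tuple[str, ...] = ("capsule", "blood_vessels")
    cell_class: str = "pHSC"
    bin_widths: tuple[float, ...] = (10.0, 30.0, 100.0)
    capsular_width: float = 200.0
    iterations: int = 100
    dot_radius: float = 3.0
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "results/run"
    n_images: int = 3
    rd_domain: str = "core"            # or "red_pulp"
    rp_definition: str = "strict"      # or "cs_minus_wp"
    moderated_t: bool = False
    imputation_scope: str = "global"   # or "protein"
    with_intensity: bool = True
    with_proteomics: bool = False

    def validate(self) -> None:
        if self.scenario is None and (self.tissue_dir is None
                                      or self.cells_csv is None):
            raise ConfigError("need either a scenario name or input paths")
        if any(w <= 0 for w in self.bin_widths):
            raise ConfigError("bin widths must be positive")
        if self.capsular_width <= 0 or self.dot_radius < 0:
            raise ConfigError("capsular_width must be > 0, dot_radius >= 0")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if self.rd_domain not in ("core", "red_pulp", "cross_section"):
            raise ConfigError(f"unknown rd_domain {self.rd_domain!r}")
        if self.rp_definition not in ("strict", "cs_minus_wp"):
            raise ConfigError(f"unknown rp_definition {self.rp_definition!r}")
        if self.imputation_scope not in ("global", "protein"):
            raise ConfigError(f"unknown imputation_scope {self.imputation_scope!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for k in ("references", "bin_widths"):
            if k in kwargs and isinstance(kwargs[k], list):
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


@dataclass
class RunManifest:
    """Provenance of one run: config hash, seeds, version, file checksums."""

    config_hash: str
    seed: int
    version: str
    checksums: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# --------------------------------------------------------------------------
# tissue / cell table I/O
# --------------------------------------------------------------------------

def write_tissue(tissue: TissueGeometry, out_dir: str | Path) -> None:
    """One uint8 0/1 TIFF per structure plus a JSON sidecar with units."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, mask in tissue.masks.items():
        tifffile.imwrite(out / f"{name}.tif", mask.astype(np.uint8))
    sidecar = {
        "pixel_size_um": tissue.pixel_size,
        "center_um": list(tissue.center),
        "seed": tissue.params.seed if tissue.params else None,
        "params": (dataclasses.asdict(tissue.params) if tissue.params else None),
    }
    if sidecar["params"] is not None:
        for k, v in sidecar["params"].items():
            if isinstance(v, tuple):
                sidecar["params"][k] = list(v)
    (out / "tissue.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_tissue(in_dir: str | Path) -> TissueGeometry:
    """Read masks + sidecar back; the continuous outline is not restored."""
    src = Path(in_dir)
    sidecar_path = src / "tissue.json"
    if not sidecar_path.exists():
        raise UnitError(f"no tissue.json sidecar in {src}; pixel size unknown")
    sidecar = json.loads(sidecar_path.read_text())
    masks = {}
    for name in TissueGeometry.STRUCTURES:
        path = src / f"{name}.tif"
        if not path.exists():
            raise FileNotFoundError(f"missing structure mask {path}")
        masks[name] = tifffile.imread(path).astype(bool)
    params = None
    if sidecar.get("params"):
        p = dict(sidecar["params"])
        for k in ("wp_radius_range",):
            if k in p and isinstance(p[k], list):
                p[k] = tuple(p[k])
        params = synthgeom.GeometryParams(**p)
    return TissueGeometry(masks=masks, pixel_size=float(sidecar["pixel_size_um"]),
                          center=tuple(sidecar["center_um"]), params=params)


_CELL_CSV_COLUMNS = (["x_um", "y_um", "radius_um"] + MARKER_COLUMNS
                     + ["sex", "treatment", "animal_id", "image_id",
                        "true_distance_um"])


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cells.to_csv(path, index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    cells = pd.read_csv(path)
    required = ["x_um", "y_um", "radius_um"] + [m for m in MARKER_COLUMNS
                                                if m != "Ki67"]
    missing = [c for c in required if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table {path} lacks required column(s) {missing}")
    known = set(_CELL_CSV_COLUMNS) | {c for c in cells.columns
                                      if c.startswith("dist_")}
    unknown = [c for c in cells.columns if c not in known]
    if unknown:
        log.warning("ignoring unknown cell-table column(s) %s", unknown)
    for m in MARKER_COLUMNS:
        if m in cells.columns:
            cells[m] = cells[m].astype(bool)
    return cells


def read_inputs(tissue_dir: str | Path, cells_csv: str | Path,
                matrix_csv: str | Path | None = None
                ) -> tuple[TissueGeometry, pd.DataFrame, AbundanceMatrix | None]:
    """Load typed objects from the on-disk formats, with schema checks."""
    tissue = read_tissue(tissue_dir)
    cells = read_cells(cells_csv)
    matrix = read_abundance(matrix_csv) if matrix_csv else None
    return tissue, cells, matrix


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.values.rename_axis("protein").to_csv(path)


def read_abundance(path: str | Path) -> AbundanceMatrix:
    """Matrix CSV with columns named ``celltype_biorep_techrep``."""
    vals = pd.read_csv(path, index_col=0)
    meta_rows = []
    for c in vals.columns:
        parts = c.rsplit("_", 2)
        if len(parts) != 3:
            raise SchemaError(f"column {c!r} is not celltype_biorep_techrep")
        meta_rows.append((c, parts[0], int(parts[1]), int(parts[2])))
    samples = pd.DataFrame(meta_rows, columns=["sample", "cell_type",
                                               "biorep", "techrep"]
                           ).set_index("sample")
    return AbundanceMatrix(values=vals, samples=samples)


# --------------------------------------------------------------------------
# orchestrated run
# --------------------------------------------------------------------------

def _simulate_inputs(config: RunConfig):
    geom, place, ispec = scenario(config.scenario, seed=config.seed)
    tissue = make_tissue(geom)
    tables = []
    for i in range(config.n_images):
        tables.append(plant_cells(tissue, place, seed=config.seed * 997 + i,
                                  image_id=f"img{i}", animal_id=f"m{i}"))
    cells = pd.concat(tables, ignore_index=True)
    image = (render_channel(tissue, ispec, seed=config.seed + 31)
             if config.with_intensity else None)
    return tissue, cells, image


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run simulation → measurement → inference and write all artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    image = None
    if config.scenario is not None:
        tissue, cells, image = _simulate_inputs(config)
        write_tissue(tissue, out / "tissue")
        write_cells(cells, out / "cells.csv")
    else:
        tissue, cells, _ = read_inputs(config.tissue_dir, config.cells_csv)

    cells = classify_cells(cells, scheme="imaging")
    log.info("cells: %d total, %d %s", len(cells),
             int(cells[config.cell_class].sum()), config.cell_class)

    references = list(config.references)
    extra_masks = {}
    if image is not None and image.src_mask.any():
        extra_masks["src"] = image.src_mask
        tissue.masks["src"] = image.src_mask  # make it addressable as a reference
        references.append("src")

    rep_cfg = ReportConfig(references=tuple(references),
                           cell_class=config.cell_class,
                           bin_widths=config.bin_widths,
                           iterations=config.iterations,
                           dot_radius=config.dot_radius,
                           alpha=config.alpha,
                           rd_domain=config.rd_domain,
                           seed=config.seed)
    report = localization_report(cells, tissue, rep_cfg)

    partition = partition_regions(tissue, config.capsular_width,
                                  rp_definition=config.rp_definition)
    areas = partition.areas

    report_dict = report.to_dict()
    report_dict["areas_mm2"] = {k: round(v, 6) for k, v in areas.items()}
    if image is not None:
        report_dict["intensity"] = region_intensity(image, tissue)
    report_dict["version"] = __version__

    # tidy exports
    dist_cols = [c for c in cells.columns]
    distanced = cells
    for ref in references:
        dmap = boundary_distance_map(tissue, ref)
        distanced = cell_surface_distance(distanced, dmap)
    distanced.to_csv(out / "distances.csv", index=False)

    prof_rows = []
    for ref, by_width in report.profiles.items():
        for width, entry in by_width.items():
            for who in ("cells", "rd"):
                p = entry[who]
                edges = p["bin_edges"]
                for k, pct in enumerate(p["percent"]):
                    lo = edges[k] if k < len(edges) - 1 else edges[-1]
                    hi = edges[k + 1] if k < len(edges) - 1 else float("inf")
                    prof_rows.append(dict(reference=ref, width=width, group=who,
                                          bin_lo=lo, bin_hi=hi, percent=pct))
    pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)

    test_rows = []
    for ref, entry in report.references.items():
        row = dict(reference=ref, **entry["test"])
        row["preferential_proximity"] = entry["preferential_proximity"]
        test_rows.append(row)
    pd.DataFrame(test_rows).to_csv(out / "tests.csv", index=False)

    if config.with_proteomics:
        matrix = synthgeom.simulate_abundance(seed=config.seed + 101)
        collapsed = proteo.collapse_technical(matrix)
        imputed = proteo.impute_lowest(collapsed, scope=config.imputation_scope)
        de = {}
        for a, b in (("CTM", "STC"), ("LSK", "STC"), ("LSK", "CTM")):
            de[f"{a}_vs_{b}"] = proteo.differential_abundance(
                imputed, a, b, moderated=config.moderated_t)
        venn = proteo.pairwise_sets(de)
        (out / "venn.json").write_text(
            json.dumps(venn["counts"], indent=2, sort_keys=True))
        for name, table in de.items():
            table.to_csv(out / f"de_{name}.csv")
        report_dict["proteomics"] = {"venn_counts": venn["counts"]}

    (out / "report.json").write_text(
        json.dumps(report_dict, indent=2, sort_keys=True))

    manifest = RunManifest(config_hash=config_hash(config), seed=config.seed,
                           version=__version__,
                           timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.checksums[str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True))
    return manifest
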