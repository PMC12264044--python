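# spleenniche

Spatial statistics for the splenic hematopoietic stem-cell (HSC) niche.

Rare primitive HSCs (pHSCs, Lin⁻CD41⁻CD48⁻c-kit⁺CD150⁺) in the mouse
spleen concentrate in a ~200-μm-wide band just inside the α-SMA⁺
myofibroblastic capsule. Deciding whether that clustering is real —
rather than an artifact of tissue shape — requires a null model: for each
imaged cross-section, random dots matched in count and size to the
observed cells (diameter ≈ 6 μm) are placed uniformly over the section,
100 iterations per image, and per-dot Euclidean distances to the candidate
structure form the reference distribution. This package implements that
whole workflow on synthetic spleen sections with known ground truth, so
every stage is verifiable end to end:

* **`spleenniche.synthgeom`** — synthetic section generator: elliptical
  cross-section with capsule band, trabeculae, white-pulp discs ringed by
  marginal zones, vessels; cells planted under a configurable
  distance-to-capsule law with distance-dependent Ki-67 state; an
  SDF-1α-like intensity channel; a label-free proteomics abundance
  simulator with planted differential proteins.
* **`spleenniche.spatial`** — exact Euclidean distance transforms,
  surface-to-surface cell distances (centroid EDT minus cell radius,
  clipped at 0), marker-based classification (pHSC ⊂ HSPC, LT/ST-HSC),
  capsular-zone/inner-core partition, area/density/intensity metrics.
* **`spleenniche.nullmodel`** — matched random-dot null, 10/30/100-μm
  binned frequency profiles, unpaired two-tailed Student's *t*
  comparisons, and the localization report with per-structure
  `preferential_proximity` verdicts (cell mean below RD mean at p < α).
* **`spleenniche.proteo`** — technical-replicate averaging,
  lowest-detected-value imputation, per-protein differential abundance on
  log2 intensities with Benjamini-Hochberg correction (enriched = fold
  change > 2 and adjusted p < 0.05), Venn counts, secretome subset,
  pathway classification, and ligand→receptor interaction scores with a
  label-permutation p-value.
* **`spleenniche.pipeline`** — one-config reproducible runs with
  checksummed artifacts, plus the `spleenniche` CLI
  (`simulate | analyze | proteo | all`).

## Worked example

```sh
python analysis/02_capsule_localization.py 0
```

generates three steady-state synthetic images (667 pHSCs each, planted
with a truncated-exponential distance law of scale 60 μm inside the
200-μm zone), measures capsule distances, and compares them with the
matched random-dot null. It prints:

```
pHSC capsule distance: 51.7 ± 1.0 μm (n=2001) vs RD 371.7 ± 0.6 μm (p=0) → preferential=True
occupancy: 66.1% of pHSCs within 0–60 μm (RD 10.4%), 84.9% within 0–100 μm, 15.1% within 100–200 μm
blood vessels: cells 24.4 μm vs RD 23.3 μm → preferential=False (no vascular association)
```

Reading: planted cells average ~52 μm from the capsule while random dots
on the same section average ~372 μm, so the capsule verdict is positive;
two thirds of cells sit within the first two 30-μm intervals; vessel
distances are indistinguishable from random placement, so no vascular
verdict is issued. The other drivers follow the same pattern:
`01_simulate_sections.py` (all five scenario presets),
`03_stratified_contrasts.py` (sex, Ki-67, G-CSF, 5-FU shifts),
`04_zones_and_intensity.py` (zone areas, vascular density, capsular
SDF-1α drop), `05_proteomics.py` (differential sets → secretome →
pathways → interactome).

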