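# Methods

## The question and the estimator

A cell population shows *preferential proximity* to a tissue structure
when its distance distribution is stochastically smaller than that of
matched random placements on the same section. For each image we measure,
for every cell, the Euclidean distance from the cell surface to the
nearest pixel of the reference structure; the null is built from random
dots (RDs) matched to the observed cell count and size (radius 3 μm,
i.e. ≈6 μm diameter), placed uniformly over the cross-section with the
capsule band excluded, 100 iterations per image. Distances are pooled
across iterations for the null distribution; per-iteration means are
retained as an envelope summary. The verdict for a structure is positive
iff mean(cells) < mean(RDs) with an unpaired two-tailed Student's
*t*-test p below α = 0.05.

Statistical units follow the two figure types the workflow produces:
distance-level tests treat cells/dots as observations; per-bin profile
tests treat image-level bin percentages as observations (≥2 images
required). Bins empty in every image of both groups are flagged ND and
not tested. No multiplicity correction is applied across bins by default
(a Holm option exists but is off), matching the per-bin-star convention
of the underlying protocol.

## Distance semantics

* Reference distance maps are exact Euclidean distance transforms
  (`scipy.ndimage.distance_transform_edt`), not chamfer approximations;
  an oracle test checks equality with the brute-force minimum over
  reference pixels to 10⁻⁶ μm.
* Cell distance = max(0, EDT interpolated bilinearly at the centroid −
  cell radius). This reproduces surface-to-surface distance for convex
  ~6 μm cells without mesh machinery; cells overlapping the reference get 0.
* All distances are referenced to the capsule *band* (the structure the
  cells are claimed to associate with), not the tissue outline; a
  `capsule+trabeculae` combined reference is available because the α-SMA
  stain does not separate the two.
* Analysis is strictly 2-D per section (10-μm cryosections); any 3-D
  discrepancy is bounded by the section thickness.
* The 200-μm capsular zone / inner core partition is measured from the
  tissue outline (a peripheral band), so on a disk of radius R the inner
  core area fraction is exactly ((R−200)/R)².

## The synthetic section generator

Geometry is defined continuously in μm and rasterized last (5 μm pixels
by default), so analytic checks (ellipse area πab, annulus areas, the
uniform-in-disk mean distance R/3) separate discretization error from
logic error. The default section is an ellipse with semi-axes
1500 × 1000 μm: a 20-μm capsule band, 6 trabeculae (≈300 × 30 μm)
projecting inward along local normals, 8 white-pulp discs (radius
80–150 μm) with 25-μm marginal rings placed fully inside the core, blood
vessels as random disks (radius 6–15 μm) to a target 8% of red-pulp
area, and 1% lymphatics. Point-to-ellipse distances use the exact
orthogonal-projection root (vectorized bisection), accurate to <10⁻⁶ μm.

Vessels and lymphatics are planted over the whole tissue except white
pulp — the splenic vascular bed reaches the capsule (subcapsular sinuses,
penetrating trabecular vessels). This matters statistically: if the
vessel field stopped at the capsule's inner edge, cells hugging the
capsule would see a half-empty neighborhood and their nearest-vessel
distances would be inflated, spuriously coupling a capsule-directed
relocation to the vessel-referenced contrast. With the bed extending to
the outline, vessel proximity is independent of a cell's capsule
distance, which is the premise of the specificity analyses. The
SDF-1α⁺α-SMA⁻ stromal-cell (SRC) field is likewise a dense random subset
(10%) of red-pulp pixels, reflecting a pervasive reticular meshwork; the
SRC-referenced distances are therefore short (~10 μm scale) and nearly
placement-independent.

Cells are planted by rejection sampling on the continuous domain: a
target distance is drawn from the scenario's law, and uniform candidate
positions are accepted when their true capsule distance matches the
target within one pixel (bounded at 10,000 rejections per cell; uniform
laws sample positions directly). The continuous center-to-capsule
distance is stored per cell as ground truth; measured distances agree
with it to within pixel·√2.

Ki-67 state is Bernoulli with a logit-linear dependence on distance
(intercept −0.20, slope +0.009 μm⁻¹), calibrated so the steady-state
proliferative fraction is ≈55–57% and Ki-67⁺ cells sit measurably deeper
than Ki-67⁻ cells — an observed association, not a mechanism.

### Scenario presets

| preset | distance law | zone | notes |
|---|---|---|---|
| steady_female | TruncExp(scale 60 μm) | 200 μm | ~65% of mass within 0–60 μm |
| steady_male | TruncExp(scale 120 μm) | 200 μm | larger mean than female |
| gcsf | TruncExp(scale 60, shift 30 μm) | 200 μm | mode moved ~30 μm outward; capsular intensity ×0.4 |
| gcsf_rev | TruncExp(scale 60) | 200 μm | recovery: steady law, intensity restored |
| fu5 | uniform-area | 400 μm | myeloablation randomizes positions through an expanded zone (mean ≈185 μm) |

A single truncated exponential cannot simultaneously match every reported
moment of the real distance distributions (e.g. a 52-μm mean with 65%
below 60 μm, versus the published ~69-μm mean with 62% below 60 μm); the
family is a convenient parametric stand-in whose *scale* is exactly
recoverable by maximum likelihood, which is what the parameter-recovery
checks exercise. Passing tests therefore demonstrate that the pipeline
measures, bins, tests and recovers planted spatial structure correctly —
not that real spleens follow an exponential law.

The intensity channel writes `capsule_level × scale_factor` on capsule
pixels (the perturbation scale models the G-CSF-induced drop in capsular
SDF-1α), `stromal_cell_level` on SRC pixels, `base_level` elsewhere, plus
Gaussian noise; SRC levels are left unscaled so the perturbation is
capsule-specific.

### Proteomics simulator

Intensities are log-normal: per-protein baselines log2 ~ N(20, 2),
biological replicates add N(0, 0.5), technical runs add N(0, 0.2);
planted effects shift group means by their log2 fold change. Missingness
(default overall rate 5%) is intensity-dependent via a logistic dropout
whose midpoint is solved numerically to hit the target rate — emulating
the left-censoring of label-free MS that the lowest-value imputation rule
addresses. Ground-truth fold changes are stored on the matrix.

## Proteomics analysis choices

* Technical replicates are averaged into biological samples first
  (ignoring missing runs; an entry stays missing only if missed in every
  run). A flag to treat runs as observations is deliberately absent — the
  collapsed design is the conservative reading of replicate averaging.
* "Lowest abundance value detected" is read as the *global* matrix
  minimum; a per-protein-minimum variant is available via
  `impute_lowest(scope="protein")`.
* Differential abundance: equal-variance two-sample *t* on log2
  intensities (imputation guarantees positivity, so no pseudocount), BH
  step-up across all tested proteins, fold change as the ratio of group
  geometric means, enriched iff |FC| > 2 strictly and adjusted p < 0.05.
  An empirical-Bayes variance-shrinkage mode (scaled inverse-χ² prior,
  method-of-moments on log variances) is provided as `moderated=True`,
  off by default; both modes pass planted-effect recovery.
* Interaction score = mean(mean log2 sender ligand, receiver-side mean
  log2 with dimers taking the minimum over monomers); the null permutes
  sample cell-type labels (one-sided p, add-one correction). Pairs with
  an undetected partner on either side are dropped and logged.
* Pathway classification is membership-based: a pathway counts as
  LSK-detected if any LSK-detected protein maps to it, and CTM-/STC-
  regulated if any correspondingly enriched secreted protein maps to it
  (classes CTM_only / STC_only / common / neither). No pathway-level
  significance test is claimed.

## Numerical and reproducibility notes

* One master seed drives everything; per-image RNG streams derive from it
  by stable hashing of the image id, so results are independent of
  execution order. Same config + seed reproduces byte-identical
  `report.json` and artifact checksums.
* Profile bins are half-open [k·w, (k+1)·w); with an explicit upper edge
  the tail collects into a final open-ended bin, zero-count bins are
  retained, and percentages always sum to 100. Occupancy fractions are
  exact marginal sums over the 10-μm profile.
* Degenerate tests: identical zero-variance groups return t = 0, p = 1;
  per-protein t with zero pooled variance returns ±∞ (p → 0) or 0.
* Problem sizes in the test suite — 50,000-point law checks, 200-run null
  calibration, 50-seed contrast and proteomics replications, 6 × 667-cell
  recovery fits — were chosen to make the Monte-Carlo error comfortably
  smaller than each tolerance while keeping a full run in a few minutes.

## Known limitations

* No photorealistic microscopy (PSF, chromatic aberration, segmentation
  errors); the generator produces label masks directly, so upstream
  detection error is out of scope by construction.
* White pulp, vessels and trabeculae are idealized disks/rectangles;
  real compartments are irregular, which mainly broadens area statistics.
* The Ki-67 model is a monotone logistic in distance; it cannot represent
  non-monotone proliferation gradients.
* The moderated-t mode shrinks toward a single pooled prior; no
  intensity-dependent trend (as in limma-trend) is fitted.
* 2-D analysis bounds, but does not remove, the bias from measuring
  distances within thick sections.
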