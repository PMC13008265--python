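# Methods

## The measurement problem

Fission yeast divides at a threshold size. Which geometric quantity the cell
actually monitors — length, surface area (SA), volume, or the SA:Vol ratio —
is discriminated by measuring dividing cells precisely across strains and
growth conditions. `rodcell` implements that measurement chain: segment rod
cells and their nuclei from image stacks, keep the binucleate
(post-anaphase, pre-separation) cells in which division size is defined,
measure each cell's geometry by two independent methods, and run the
comparison statistics. Because real micrograph datasets are large, hard to
redistribute, and carry no pixel-level ground truth, the package includes a
first-class synthetic-scene generator whose exact truth makes every stage
testable for recovery, not just for plausibility.

## Cell model and the two geometry methods

A rod cell is a capsule: a cylinder of radius R with hemispherical caps,
tip-to-tip length L ≥ 2R. The degenerate case L = 2R is a sphere, and the
capsule formulas reduce to the sphere formulas there (a property the tests
assert).

**Mean-radius method.** SA = 2πR(L − 2R) + 4πR² and
Vol = πR²(L − 2R) + (4/3)πR³, with R from cell widths and L from the
symmetry axis (below). Two radius conventions are supported:

- `radius_mode="population"` (default): R is half the mean width over all
  cells of a condition — the uniform-radius-across-population convention
  appropriate for condition-level summaries, where it suppresses
  single-cell width noise.
- `radius_mode="per_cell"`: each cell's own width/2. This is the correct
  mode for *per-cell* cross-validation against the rotation method: under
  the population mode, per-cell disagreement is dominated by the genuine
  radius dispersion of the population — a cell 10% thinner than the
  population mean is ~20% off in volume by construction — which says
  nothing about either method's accuracy.

**Rotation method.** The radial profile R(x) — the shortest distance from
the cell border to the symmetry axis at axial position x ∈ [0, L] — is
rotated about the axis: Vol = ∫πR(x)²dx (trapezoid rule) and SA = ∫2πR(x)ds
along the profile polyline, i.e. the conical-frustum sum
Σπ(rᵢ+rᵢ₊₁)√(Δx²+Δr²). The frustum form is used deliberately: the
equivalent integrand 2πr√(1+r′²) requires the derivative r′, which diverges
at capsule tips where the profile is vertical, whereas the polyline
arc-length is finite and second-order accurate there. On analytic capsule
profiles with 401 samples the rotation method agrees with the closed form
to 0.002% (volume) and 0.005% (SA); the acceptance script recomputes this.

**Symmetry axis and length.** The axis is the leading eigenvector of the
covariance of the cell's pixel-center coordinates (PCA of the pixel cloud),
sign-canonicalized toward positive x. Length is the extent of the
projections onto the axis plus one pixel: projections measure pixel
centers, but a cell occupies pixel area, so the +1 px correction removes
the half-pixel bias at each tip. Cells whose covariance anisotropy λ₁/λ₂ is
below 1.5 have no meaningful long axis and are rejected (flagged rows, not
pipeline failures). Bent cells are out of scope: the axis is a straight
line, not a medial spline.

**Radial profile extraction.** R(x) is sampled at 101 stations (default)
along the axis; at each station the radius is half the perpendicular pixel
extent plus one pixel, which is robust to small off-axis shifts of the PCA
line. Terminal stations are forced to r = 0 so the surface of revolution
closes — capsule tips are genuinely closed. The profile is
Gaussian-smoothed (σ = 2 samples, configurable) before integration because
digitized borders are staircases; smoothing preserves the pinned tips.
Masks of dividing cells may have nuclear pixels excised, so holes are
filled before any measurement (`fill_holes=True` default).

**Width.** The default `profile_median` width is 2 × the median of R(x)
over the central 50% of the axis — an automated surrogate for a manual
mid-cell measurement that avoids tips and irregular regions, chosen because
a manual straight-line measurement is not reproducible in an automated
pipeline. `manual_like` mode reads 2·R(x₀) at one stated axial fraction to
document the correspondence. The population mean radius warns below 50
widths (the conventional per-condition floor) but proceeds flagged.

## Segmentation

Brightfield stacks are reduced to the in-focus mid-plane (nuclear stacks to
a sum projection), Gaussian-smoothed (default σ = 0.1 µm), and globally
thresholded — Otsu by default, fixed value as an override. Polarity is
auto-detected: whichever thresholded class occupies < 50% of the frame is
foreground, so bright-interior and dark-interior contrast both work. Cell
masks are then opened and closed with 2 px discs (separating near-touching
cells and closing septum-line gaps), labeled with 8-connectivity, and
filtered by an area window (default 10–200 µm² for cells, 0.5–12 µm² for
nuclei), border contact, and — for cells only — a solidity floor of 0.8.
The solidity filter is the automated replacement for manual removal of
unresolved cell clumps: a single rod is nearly convex, a clump is not. The
nuclear area window doubles as a guard against uneven marker illumination
(abnormally small/large thresholded nuclei are dropped). All filters are
idempotent, and every mask carries a provenance record sufficient to
reproduce it.

## Dividing cells

Nuclei are eroded by 2 px (detaching them from cell borders), assigned to
the cell containing their centroid, and cells with exactly two nuclei are
retained. Centroids over background are reported as unassigned; nuclei
whose pixels straddle two cells are flagged with a warning while the
centroid still decides — these reports replace the by-eye confirmation step
of interactive workflows. The retained-cell mask can keep or excise nuclear
pixels; excision is the default, and geometry's hole-filling makes the two
orders equivalent for all measured quantities.

## Statistics

- **Growth.** OD(t) = od_max·od₀·e^{kt}/(od_max + od₀(e^{kt}−1)) — the
  logistic sigmoid, fit per replicate by nonlinear least squares with k
  initialized from a log-linear regression of the early (OD below half
  final) phase. Doubling time = ln(2)/k, an exact identity of the returned
  object. Readings that noise pushes to ≤ 0 are excluded from the
  initialization only. A Gompertz alternative is not provided; the logistic
  form is fixed so that simulation truth and fitting model coincide.
- **Condition comparisons.** One-way ANOVA, then Bonferroni-adjusted
  unpaired two-tailed t tests of each condition against the reference
  (a conservative stand-in for Dunnett's test), reported with the tier
  convention ns / *p<0.04 / **p<0.01 / ***p<0.001 / ****p<0.0001.
  Replicate cultures are pooled before testing; hierarchical modeling of
  replicate structure is out of scope.
- **Septation.** Overall r×2 χ² on raw septated/unseptated counts; only
  when significant at α are pairwise 2×2 χ² tests vs the reference
  genotype run, Bonferroni-adjusted. No Yates continuity correction by
  default (a flag enables it); a zero expected count raises with an
  instruction to merge categories. The simulated null type-I error of the
  overall test sits within the binomial 95% CI of α (recomputed by the
  acceptance script over 1000 tables of 100 cells/genotype).

## Synthetic data: what it emulates and what it does not

The generator emulates: fields of non-overlapping capsules with
configurable radius/length distributions (defaults R ∈ [1.8, 2.2] µm,
L ∈ [10, 16] µm — the realistic envelope for dividing fission yeast), one
or two nuclei rendered as isotropic Gaussian blobs on the symmetry axis
(binucleates symmetric about midcell), an optional 1-px septum line drawn
at 75% of the interior contrast so it is visible without breaking the
midpoint-threshold identity, Gaussian blur and additive Gaussian noise,
and z-stacks built by replicating the in-focus plane with defocus blur
growing 0.15 µm per step away from the middle plane (27 planes by default).
Default pixel size is 0.1083 µm/px, a typical 60×/sCMOS scale. Growth
curves are logistic with default k = ln(2)/136 min⁻¹, od₀ = 0.05, four
replicates read every 2 min for 33 h; septation tables are binomial draws.

It does **not** emulate: brightfield optics (no phase rings, no intensity
gradients across cells), touching or clumped cells, curved cells,
illumination fields, or true 3D blur. Passing recovery tests therefore
demonstrates the correctness of the measurement chain on capsule-shaped
ground truth — the same geometric null model the capsule formulas assume —
not robustness to every artifact of real micrographs. Real-data use still
warrants visual QC of masks.

Determinism is a contract: every generator is a pure function of its
parameters and a seed, rendered noise is drawn from a generator seeded per
scene (or per explicit `noise_seed`), and a pipeline run re-executed from
its emitted YAML config reproduces all CSV outputs byte-identically.

## Numerical and design choices

- Coordinates are 0-based pixel indices; pixel centers at (i + 0.5); all
  physical outputs in µm, µm², µm³, µm⁻¹ via the pixel size.
- The +1 px conventions (length, perpendicular extent) compensate pixel
  area vs pixel center; at 0.1 µm/px they matter at the 0.5–1% level.
- Otsu threshold, 8-connectivity, 2 px morphology radii and the 0.8
  solidity floor are defaults, not laws; all are configurable and recorded
  in mask provenance.
- Per-cell measurement failures (too round, too small, degenerate profile)
  become flagged rows so a scene-level run never dies on one bad cell.
- Problem sizes in the test suite and acceptance script (8–50 cells per
  scene, 400–1000 simulation replicates) were chosen as the smallest sizes
  at which the checked properties are stable across seeds.

## Known limitations

Straight-axis assumption (no bent or T-shaped cells); 2D geometry from a
single focal plane (the z-stack informs projections only); no sub-pixel
edge localization — accuracy is half-pixel-limited, ~1% at default scales;
Dunnett's exact post-hoc distribution approximated by Bonferroni; the
septation procedure's pairwise stage inherits the usual caveats of
data-dependent gating on the overall test.
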