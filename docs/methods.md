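# Methods

## Scope and model

`phaquant` quantifies intracellular PHA granules per cell from three
co-registered 2-D epifluorescence channels — DNA (cell counting), membrane
(cell outlines), PHA (granules) — and reports sample-level statistics: the
percent of cells with detectable PHA and the distribution of single-cell PHA
mass fractions. A companion module computes batch growth-cycle metrics for
serum-bottle methanotroph enrichments. A synthetic scene generator with
exact ground truth makes every stage testable without raw micrographs.

## Bernsen thresholding

Binarization uses Bernsen's local method: within a circular window of radius
*r* centred on each pixel (pixels at Euclidean distance ≤ *r*; window
clipped at image borders, no padding), `contrast = max − min` and
`midgray = (max + min)/2`. If `contrast < t` the whole window is treated as
one phase: object iff `midgray ≥ cut`; otherwise the pixel is object iff its
intensity is strictly greater than the midgray. Defaults (*r* = 15,
*t* = 15, `cut` = 128) follow the de-facto reference implementation in the
ImageJ Auto Local Threshold plugin. All comparisons are done on doubled
integer intensities so the half-integer midgray is exact; 16-bit input is
min–max rescaled to 8-bit first because the cut is defined on that scale.
The implementation (rank filters with a circular footprint) is checked for
exact pixel equality against a per-pixel brute-force oracle in the tests.

A practical constraint worth knowing: with window area ≈ 700 px, the
expected range of i.i.d. Gaussian noise is ≈ 7σ, so background regions flip
from the low-contrast rule to the per-pixel rule once σ ≳ *t*/7 (σ ≈ 2 at
the default *t* = 15), at which point roughly half the background pixels
binarize as object. For noisier images raise `contrast_threshold` to
≈ 8σ — granule and cell edges in the defaults' intensity regime
(interior ≈ 180, background ≈ 20) have contrast ≈ 160 and remain detected.

## Particle analysis and cell assignment

Connected components use 8-connectivity, matching the particle-analysis
convention of the reference plugin. Components are filtered by area
(defaults: ≥ 20 px for DNA/membrane cells, ≥ 4 px for granules — small
enough for diffraction-limited granules, large enough to reject speckle) and
optionally by border contact (cells touching the image edge have truncated
areas and are excluded by default). Survivors are relabeled 1…n in raster
order of their first pixel, making label assignment deterministic.

Granules are attributed to the membrane cell whose region contains the
granule centroid; if the centroid lands on background (e.g. between
touching structures), the cell with maximal pixel overlap wins, ties going
to the lowest label. Granules overlapping no cell are counted and reported
but excluded from per-cell fractions.

## Fraction conversions

Per cell, the area fraction is `f = min(1, Σ granule areas / cell area)`.
The sphere assumption converts cross-sections to volumes,
`V = (4/3)π (A/π)^{3/2}`; applied to cell and PHA aggregate alike, the
volume fraction reduces to `v = f^{3/2}`. The mass fraction uses the
PHA-to-biomass density ratio ρ = 1.099 in two-component mixture form
`w = ρv / (ρv + (1 − v))`, which is strictly increasing with fixed points
w(0) = 0 and w(1) = 1; the linear small-v form `w = ρv` is available via
`mass_model: linear` for sensitivity analysis but cannot satisfy w(1) = 1.

Two volume models are exposed because the choice is genuinely open:

- **aggregate** (default): the sphere assumption applied to the *summed*
  granule cross-section, `v = f^{3/2}` — the literal reading of
  "fraction of membrane area, converted to volume".
- **per_granule**: each granule converted separately,
  `v = Σ Aᵢ^{3/2} / A_cell^{3/2}` — consistent with k discrete spherical
  granules. For k equal granules the aggregate form overestimates the
  granule-wise one by a factor √k (≈ 1.41 for the typical two polar
  granules), so validation against 3-D geometric truth, and any sample where
  most cells carry two granules, should use `per_granule`. All ground-truth
  recovery tests and the acceptance script do.

The percent of cells with PHA uses the DNA-channel count as denominator and
membrane-channel PHA-positive cells as numerator; the mixed denominator is
deliberate (the membrane stain misses some cells) and values above 100%
are reported with a warning rather than clipped. Sample summaries pool cell
counts over fields (typically 15 images per sample) and report the mean
single-cell mass fraction over PHA-positive cells, with an all-cells mean
alongside.

## Synthetic scenes

The generator renders fields of non-overlapping coccoid cells as 2-D
equatorial projections: whole-cell disks in the DNA and membrane channels,
and 0–2 polar granule disks in the PHA channel, placed at ±0.6·R along a
random cell axis (clamped so granules stay inside the cell). Rendering
applies a Gaussian PSF (σ = 1 px default), then per-pixel noise (none,
Gaussian, or Poisson shot-like), then rounds to 8-bit. Cell placement is
random-sequential with bounded retries; infeasible packings raise an error.

Defaults emulate the target morphology and study conditions: 512×512 fields
of 50 cells, radii 18 ± 2 px, granule count per cell distributed
(0.6, 0.1, 0.3) over {0, 1, 2} — 40% of cells granule-bearing, mostly with
two polar granules — granule radii 7.2 ± 0.5 px, interiors ≈ 180 over
background ≈ 20. With these radii the mean true mass fraction of
granule-bearing cells is ≈ 12% (m/m). The default Gaussian σ = 1.5 keeps the
background noise range (≈ 10) below the Bernsen contrast threshold (15) with
margin, i.e. "low camera noise"; σ = 2 sits exactly at the flip boundary
derived above and is a useful stress case, not a default.

Ground truth records, per cell, the 2-D area fraction `Σ r² / R²` and the
*3-D* volume fraction `Σ r³ / R³` (spheres, not projections), converted to a
true mass fraction with the same density ratio. Passing recovery tests
therefore show that segmentation + granule-wise conversion recover the
geometry the sphere assumption idealizes. They do **not** show robustness to
features real micrographs have and the generator deliberately omits: rod
shapes, touching/clumped cells, uneven illumination, stain bleed-through,
out-of-focus granules, and membrane stains that miss cells.

## Growth-cycle arithmetic

Headspace CH₄ mass uses the ideal gas law with bottle defaults of 110 mL
headspace over 50 mL medium at 303.15 K and 1 atm
(R = 0.082057 L·atm·mol⁻¹·K⁻¹; 12.011 g C/mol). Consumption fractions are
(initial − final)/initial, clipping negative apparent consumption (from
measurement fluctuation) to zero with a warning. Cell yields divide the
total-bottle cell gain (cells·mL⁻¹ × liquid volume) by grams of C or N
consumed; since the published yield unit does not fix the cell basis, and
yield *ratios* are basis-invariant, the basis is configurable. Mean ± SD
reporting defaults to the population (divisor-n) form, which is the form
that reproduces the published summary of the three per-core GC values
(sample SD gives 2.9 rather than 2.4); both modes are exposed.
Abundance-normalized PHA content divides the community mass percentage by
the methanotrophs' relative abundance (in %), computed from means since
per-core abundances are not available.

## Numerical and design notes

- Bernsen comparisons are exact integer arithmetic; no floating-point
  thresholding ties exist. Strict `>` against the midgray follows the
  reference behaviour.
- Determinism: fixed config + seed give byte-identical TIFF/CSV outputs;
  every CLI run writes a provenance JSON (config echo, seed, version)
  sufficient to reproduce it.
- Degenerate inputs fail loudly: empty images, mismatched channel sizes,
  zero-area cells, zero DNA counts, zero initial substrate.
- Problem sizes in the test suite and acceptance script (20 scenes × 50
  cells, 512×512) were chosen as the smallest fields that hold 50
  non-touching cells at realistic radii; they run in ~1 minute.

## Known limitations

- No watershed splitting: touching cells merge into one "cell".
- The sphere assumption is exact only for spherical cells and granules
  imaged at their equator; real images add focus and projection errors the
  synthetic scenes do not model.
- Bernsen with default contrast breaks down at background noise σ ≳ 2
  (8-bit); the config must be adapted to the noise level (see above).
- Only the Bernsen threshold is implemented (no Otsu/Niblack/Sauvola), and
  only 2-D single-plane images are supported.
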