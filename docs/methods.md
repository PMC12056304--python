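# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the `plaquemetrics` pipeline. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The measurement problem

Amyloid-burden studies in plaque-bearing transgenic mice quantify, from
stained sagittal sections: total immunopositive area and integrated optical
density (IOD) per region; per-plaque maximum diameters and box-counting
fractal dimensions; plaque–vessel distances and contact frequencies;
Aβ40/Aβ42 channel areas, their ratio, and a two-color overlap coefficient;
and thioflavin-S (fibrillar) area and counts. Group comparisons use one-way
ANOVA with Fisher's LSD, correlations use Pearson's r, and correlation
magnitudes are compared with the one-tailed Fisher Z test. Because such
measurements are usually produced interactively in commercial packages, the
pipeline here re-implements each step as open, deterministic code and pairs
it with a synthetic-histology generator whose ground truth makes every step
testable.

## Synthetic histology generator

The generator defines the study conditions; its defaults are fixed and the
tests run against them.

**Field.** 512×512 px at 2 µm/px (~1.05 mm²) by default. Region label maps
are either a single region ("cortex") or quadrants named cortex /
hippocampus / striatum / thalamus. Anatomical parcellation of real sections
is an input, never computed.

**Plaques.** Counts, a type mix over {diffuse 0.40, dense 0.35, dense-core
0.25}, and diameters uniform on 14–36 µm (bracketing the ~20–25 µm regional
mean diameters reported for cortical deposits in such models; no published
size distribution exists, so the range is a package choice). Plaque
boundaries are angularly modulated discs (low-order Fourier perturbation,
strongest for diffuse plaques); DAB density profiles are soft-radial
(diffuse), near-plateau (dense), or a compact core of 0.3× the plaque
radius over a pale corona (dense-core). Every plaque pixel carries at least
0.35 OD of DAB so the support is unambiguous at the default segmentation
threshold. Placement is rejection sampling with a non-overlap margin;
a per-plaque exhaustive center scan runs before a sizing error is raised.

**Vessels.** Smoothed random-walk centerlines entering from a field edge,
dilated to a 5 µm radius; the default of 3 per ~1 mm² field only needs to
exercise the distance logic. A configurable fraction of plaques is placed
in contact with a vessel (center within 0.8 plaque radii of the vessel
surface); the rest are placed in a distance band drawn from a Gaussian
copula against plaque diameter (default correlation −0.2, distances
~60 ± 25 µm), so pooled records carry a negative diameter–distance
correlation like real cohorts. The copula is best-effort at scene level:
with pooled n in the hundreds the planted correlation is recovered (the
generator-level check at n = 360 recovers −0.38 for a planted −0.4);
per-scene n of a few dozen is sampling-noise dominated, exactly as
per-animal correlations would be.

**Fibrillar cores.** Assigned to the stated fraction (default 0.5) of
dense/dense-core plaques as discs of 0.45× the plaque radius — large enough
that every core clears the 20 µm² minimum ROI area at default calibration.

**Brightfield render.** Transmitted light per channel is
`T_c = W·10^(−Σ_s D_s·V_s[c])` with the published Ruifrok–Johnston unit OD
vectors for hematoxylin and DAB and the published Fast Red vector (all
overridable). Stored 8-bit codes follow `code = round(T) − 1` on a
`W = 256` scale, which makes the downstream conversion
`OD = −log10((code+1)/W)` unbiased to half a count. Noise is additive
Gaussian on T (default sd 2 in 8-bit counts) — the simplest model that
stresses thresholds; autofluorescence, scanner artifacts and 3D structure
are out of scope. A 16-bit render (256× finer scale) exists for
quantitative roundtrips: through the 3×3 unmixing inverse (row 1-norms
≈ 4), half-count quantization at 8 bits bounds recoverable density accuracy
near 0.02–0.03 OD elementwise, while 16-bit renders recover densities to
~2×10⁻⁴ OD. Both bounds are asserted in the tests at their respective
depths.

**Fluorescence render.** Aβ42 covers every plaque at a fixed foreground
intensity. With equal-intensity binary channels the Manders coefficient
reduces to `|A∩B|/√(|A||B|)`; giving Aβ40 a support of equal size with a
fraction ρ inside the plaque (core-tropic, nearest the centroid) and the
remainder in a halo just outside makes the noiseless coefficient exactly ρ.
The constructed default is 0.6, the upper end of the 0.43–0.62 coefficients
typical of untreated animals in this kind of study. The Aβ40 support size
relative to Aβ42 (`ab40_area_fraction`, default 1.0) sets the true area
ratio; it must be ≥ ρ² for the construction to exist.

**Fractal fixtures.** Exact constructions with known dimension: a 1×n line
(FD 1), filled square (FD 2), the depth-d Sierpinski triangle via the
Pascal-parity identity `(i & j) == 0` (3^d pixels, FD log₂3 ≈ 1.585), and
the depth-d Sierpinski carpet (8^d pixels, FD log₃8 ≈ 1.893). Because the
triangle is dyadically self-similar and the box grid is dyadic and anchored
at the bounding box, its measured slope is exactly log₂3; the carpet's
3-adic structure does not align with dyadic boxes, so its measured slope
(~1.7 at depth 4) is only loosely bounded in tests.

## Measurement conventions

* Coordinates are (row, col), 0-based, origin top-left. All physical
  quantities use `pixel_size_um`; densities are per mm² of *region* area.
* **Unmixing**: OD per channel from the `(I+1)` convention, solved against
  the stain matrix, negatives clipped. This replaces interactive RGB
  histogram gating with its standard reproducible realization; the original
  threshold patterns of interactive workflows are unrecoverable, so
  equivalence is claimed at the level of pipeline behavior on known ground
  truth, not of any specific historical threshold.
* **Segmentation** thresholds (DAB OD 0.15, Fast Red OD 0.20, ThS intensity
  60, min plaque area 20 µm², closing radius 1 px) are configuration, echoed
  into every run log. Closing merges cores with coronas; hole filling makes
  pale plaque centers measure as part of the deposit; components use
  8-connectivity. Raising a threshold never increases segmented area
  (asserted as a property test).
* **Maximum diameter** is the max pairwise distance between foreground
  pixel centers, computed on the convex hull (brute force on tiny masks,
  and validated against the all-pairs oracle).
* **IOD** uses the deconvolved DAB OD as "intensity" — stain-linear and
  reproducible, unlike raw inverted gray whose scale is package-specific.
  The product form (area × mean) and sum form (Σ OD × px area) agree to
  1e-9 relative by construction.
* **Fractal dimension**: dyadic box sizes 2…side/2 on the padded bounding
  square, single grid offset anchored at the bounding-box origin (offset
  averaging deliberately omitted to match the plain box-count definition),
  OLS slope of log N vs log 1/s, ≥3 sizes required. ROIs whose padded
  bounding square is under 16 px cannot be box-counted and carry FD = NaN;
  they are excluded from FD means. FD is translation- and 90°-rotation
  invariant by construction. Absolute FD values from interactive packages
  reflect those packages' internals; only rank behavior on controlled
  fixtures is claimed.
* **Distances**: nearest-vessel distance is the minimum over plaque pixels
  of the exact Euclidean distance transform of the vessel mask. Contact
  (distance := 0) is overlap or 8-adjacency, i.e. a raw minimum ≤ √2 px —
  the raster-precision operationalization of "running through or in direct
  contact". Sub-pixel boundary geometry is ignored (pixel-center
  semantics), which is what makes the brute-force oracle exact.
* **Correlations** pool plaque-level records within a treatment group
  across animals (matching the very large pooled n such studies imply);
  per-animal correlation and a contact-excluding mode are both available,
  and the pipeline reports the contact-including and contact-excluding r
  side by side since published analyses rarely state which was used.
* **Aggregation**: mean-type metrics average per animal-region then per
  group; IOD cumulates per animal-region then averages per group. SEM uses
  the n−1 standard deviation over animal-level values — the animal, never
  the plaque, is the experimental unit. SEM for a single animal is NaN,
  flagged rather than raised.
* **ANOVA/LSD**: classical sums-of-squares decomposition; LSD pairwise t
  uses the pooled MSE with N−k df and no multiplicity adjustment (that is
  its definition), reported regardless of omnibus significance with the
  omnibus p alongside. All-identical data take the F = 0, p = 1 path.
  Stars: *p<0.05, **p<0.01, ***p<0.001.
* **Fisher Z**: `Z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`,
  one-tailed by stated direction (two-tailed available); |r| = 1 or n < 4
  are usage errors.
* **Behavior**: the discrimination index is reported in both conventions —
  fraction `t_n/(t_n+t_f)` (chance 0.5) and signed `(t_n−t_f)/(t_n+t_f)`
  (chance 0) — because published values are consistent with either; no one
  form is presumed. Time-in-center is frame counting times the frame
  interval, boundary inclusive. The longitudinal mixed-model (REML) fit
  used for repeated behavior sessions is out of scope; the module emits the
  tidy per-session table such a fit would consume.

## Pipeline and the planted-effect study

The demo cohort has three arms (control, facilitator ×0.4 burden,
inhibitor ×1.4 burden — ratios taken from the ~6.1:15.9:22.3 ×10³ µm²/mm²
cortical burdens reported in the motivating study design — with planted
vessel-contact fractions 0.279/0.178/0.256). Per-animal plaque counts are
Poisson with a lognormal animal effect (sd 0.22). Everything downstream of
the generator is the same code a real study would run on its TIFF exports.

The parameter-recovery study (`pipeline.burden_recovery_replicate`) uses
reduced 192×192 px fields, diameters 10–24 µm, one vessel, a base
expectation of 10 plaques per control field truncated at 24 (the field's
packing capacity), and 15 virtual animals per arm; the LSD burden contrasts
are evaluated over 200 replicates. Problem sizes were chosen once from a
power analysis (a 0.6× burden drop at total CV ≈ 0.4 gives d ≈ 1.5, power
> 0.9 at n = 15) and are stated here as the package's own study design.

Determinism: every random draw descends from the run seed (scene seeds,
animal effects, render noise); rerunning a config byte-identically
reproduces `summary.json`, whose config hash covers the analysis-relevant
settings (paths excluded).

## Limitations

* The generator emulates geometry and stain mixing, not tissue realism:
  no autofluorescence, no section thickness, no scanner shading, no CAA /
  dysphoric-angiopathy morphologies. Passing recovery tests demonstrates
  the correctness of the measurement code on known geometry, not
  performance on real slides.
* Plaque-type classification (diffuse vs dense vs dense-core) is a
  generator input, not a measurement output — no quantitative rule for the
  distinction exists to implement.
* 8-bit brightfield quantization bounds unmixing accuracy (~0.03 OD worst
  case through the 3-stain inverse); quantitative roundtrip claims at the
  0.01 OD level hold for the 16-bit render path.
* Per-region colocalization on quadrant layouts slightly underestimates the
  constructed overlap for plaques straddling region borders.
* Whole-slide pyramid formats are out of scope; inputs are flat TIFF/PNG
  exports with user-supplied µm/px calibration (scan-magnification metadata
  is not parsed).
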