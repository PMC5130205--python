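# Methods

## Section geometry

**Pixel model.** A section is a binary raster; each cortical pixel
contributes an area element d*A* = *p*² (pixel size *p*, mm) located at its
center, plus a self-moment *p*⁴/12 to each planar second moment of area
(the second moment of a square about its own centroid). The self-moment
term removes the leading discretization bias at coarse resolutions; the
convergence tests show monotone error decay as *p* shrinks, and agreement
with analytic values of 0.27% worst-case at *p* = 0.05 mm and 0.12% at
0.02 mm over a ten-spec grid of hollow, eccentric-canal and rotated
ellipses.

**Areas.** *CA* counts cortical pixels only. *TA* is the area of the
filled subperiosteal region: cortex plus all cavities enclosed by the
periosteal contour (medullary canal and intracortical voids), obtained by
binary hole-filling. A disconnected cortex is rejected with an explicit
error; an *unclosed* periosteal ring cannot be distinguished from a
genuinely open (C-shaped) section on a binary raster, and is treated as
enclosing no cavity — broken sections should be repaired upstream, as is
standard practice.

**Axes and sides.** Image columns are mediolateral and rows
anteroposterior (anterior up), configurable via `axis_convention`;
left-side specimens are mirrored to right-side orientation before any
computation so the medial direction is consistent across specimens.
*I*x is computed from A-P distances (bending rigidity in the A-P plane),
*I*y from M-L distances. Mirroring is an exact invariance of all reported
properties.

**Principal axes.** *I*max/*I*min are the eigenvalues of the centroidal
second-moment tensor. `theta` is reported as the orientation of the axis
about which the SMA is *minimal* — the long axis of the section — measured
counterclockwise from the M-L axis in (−90°, 90°], with exact ties (e.g.
circular sections) reported as 0. Under this convention the measured theta
of a synthetic ellipse equals its rotation angle.

**Section moduli.** True moduli: *Z*x = *I*x / max|A-P distance|,
*Z*y = *I*y / max|M-L distance|, *Z*p = *J* / *r*max, with distances taken
from the cortical-area centroid to the periosteal contour (boundary pixels
of the filled region, pixel centers). Using pixel centers biases the
maximum distance by at most half a pixel, ≤ 0.3% at the resolutions used.

## Femoral-neck cortical thickness

The measurement line is vertical (superoinferior, superior = image top)
and placed at a configurable M-L offset from the cortical-area centroid
(default: through the centroid). Each thickness is the total cortical
intercept of the line on its side of the centroid, i.e. the summed lengths
of contiguous cortical runs, so a single-pixel crack does not zero a wall.
The line must cross the cortex exactly twice; any other crossing count is
an error naming the count. Mid-neck versus neck-base is metadata only. The
superior/inferior ratio is exact on constructed phantoms (shifted-canal
annulus with intercepts *R* − *r* ∓ *s*) and stable to < 2% under pixel
refinement.

## Allometry

All fits are on log₁₀ scale. The RMA slope is
sign(*r*)·sd(log *y*)/sd(log *x*); the line passes through the bivariate
mean.

**SEE convention.** SEE is the standard error of estimate of the
*vertical* (y-direction) residuals about the RMA line with *n* − 2 degrees
of freedom, and %SEE = (10^SEE − 1)·100. Vertical rather than orthogonal
residuals keep "SEE units" dimensionally on the y variable, which is how
fossil deviations are reported; an orthogonal convention would rescale
deviations by √(1 + b²) but not reorder them for near-unity slopes.

**Prediction interval.** Halfwidth
*t*·√(2·SEE²·[1 + 1/*n* + (*x*ᵢ − x̄)²/Σ(*x* − x̄)²])·|*b*|, with Σ(*x* − x̄)²
the *corrected* sum of squares. The radical spans the 2·SEE² term and the
bracket (so the halfwidth scales with SEE, not SEE²), and the slope factor
multiplies outside. At the bivariate mean and large *n* the halfwidth
tends to *t*·√2·SEE·*b* ≈ 2.8 SEE — so a point must lie nearly 3 SEE off a
line to escape the band.

**Quick Test.** Elevation differences: classify every point of both groups
as above/below a single pooled RMA line, then Fisher's exact test
(two-sided) on the group × side 2×2 table. Points exactly on the pooled
line (a floating-point tie, realizable with constructed data) are excluded
and tallied. Fisher's exact test is conservative on coarse tables; at 500
points per group its null rejection rate is within Monte-Carlo tolerance of
the nominal 5% (measured 0.045–0.048 over 1000 replicates), while at 200
per group discreteness pulls it down to ≈ 0.036.

**Slope test.** A seeded permutation test on |*b*₁ − *b*₂| under
group-label shuffling, with the add-one p-value estimator (exactly valid
under exchangeability; with 199 permutations the attainable 5% level is
exact). Permutation replaces the likelihood machinery of standard SMA
software with an assumption-light, fully reproducible test. Note that a
label-permutation slope test is only well-posed when the two groups
overlap in elevation: if the groups are vertically separated, permuted
mixtures have slope variance dominated by the separation itself.

**RMA estimand.** With residual scatter σ in y only, the RMA slope
converges to *b*·√(1 + σ²/(*b*²·var log *x*)), not *b*. At a narrow
x-range (0.6 decades, σ = 0.06) the inflation is ≈ 4%; recovery of a
generating slope to ±0.01 therefore requires the x spread to dominate the
scatter, and the parameter-recovery tests use a 2-decade range (inflation
≈ 0.4%). SEE-unit deviations are unaffected near the sample mean, where
the fitted and generating lines cross.

## Derived indices

Bilateral asymmetry is ((R − L)/((R + L)/2))·100, positive when the right
side dominates, bounded in (−200, 200). The sensitivity table enumerates
every pairing of candidate right/left section offsets and summarizes
min/median/max. Power-law surrogates *Z*p ≈ *J*^0.75 and *Z* ≈ SMA^0.73
cover samples lacking contour distances; in proximal-femur shape analyses
the SMA^0.73 conversion is applied uniformly to *all* individuals so that
fossils and comparative samples share one convention. Conversion fits come
in three kinds: pure exponent (through-origin least squares on log scale),
log-linear regression, and mean ratio (arithmetic mean of pairwise y/x),
each reporting r and %SEE where defined.

## Synthetic data

The generator emulates two things and only two things: (1) diaphyseal
sections as hollow ellipses — optionally rotated, with an eccentric canal,
and with seeded radial boundary jitter (off by default) — whose properties
have exact composite closed forms (parallel-axis theorem, analytic tensor
rotation, dense boundary sampling for maximum radii); and (2) comparative
groups with exact log-linear allometry, log₁₀ *x* uniform on a stated
range and Gaussian residuals in log₁₀ *y*. The default reference groups
are near-isometric (slope 1.0, σ = 0.06) with an elevation gap of 0.37
log₁₀ units and sizes 1000 and 95 — the order of magnitude of real modern
human and chimpanzee comparative samples, with a separation wide enough
that their 95% prediction bands do not overlap.

What the generator does **not** emulate: real cortical contours are not
elliptical; real medullary boundaries are textured by trabecular
structure; real comparative samples have measurement error in *x*,
non-uniform size distributions, and taxon-specific slope differences.
Passing tests therefore validate the *machinery* — geometry extraction,
fitting, deviation scoring, test calibration — not any biological claim
about real samples.

## Fixtures and problem sizes

The packaged tables carry 13 sections of A.L. 288-1 and 26 comparative
fossils with sparse fields; comparisons are computed pairwise-complete per
fossil, and a fossil missing a variable is skipped with a logged warning,
not an error. The acceptance script uses a 10-spec geometry grid at 0.05
and 0.02 mm pixels, deviation recovery against n = 1000 fits, and 1000
null replicates per test calibration (500/group for the Quick Test,
100/group with 199 permutations for the slope test); the whole script
completes in well under a minute on one CPU.

## Known limitations

- Segmentation (endosteal boundary identification) is the caller's
  responsibility; only a fixed-threshold binarization helper is provided.
- No repair of cracked or missing cortex; defective sections must be
  repaired before measurement.
- The Quick Test excludes on-line points rather than splitting them; with
  continuous data this is a zero-measure event.
- `theta` for near-circular sections is numerically ill-conditioned (any
  axis is principal); it is reported as 0 only on exact ties.
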