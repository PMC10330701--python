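# Methods

## The localization model

The package assumes an affine relationship between the 3-D coordinates
of an early-activation site on the left-ventricular endocardium and the
eight initial-120-ms QRS time integrals of the independent ECG leads
(I, II, V1–V6).  Three 9-term coefficient sets (intercept + 8 slopes,
one set per coordinate) are fitted by ordinary least squares on labelled
pacing data and applied as constants at prediction time.  There is no
predictor standardization and no regularization: the method operates on
raw integrals, and its output units are mm (intercepts) and mm/(µV·s)
(slopes).

Rank-deficient designs are solved by the minimum-norm least-squares
solution (`numpy.linalg.lstsq`), with a `RankDeficientWarning`.  This is
not an edge case: data generated exactly by an affine lead-field map
occupy a 3-D affine subspace of the 8-D feature space, so the 9-column
design has rank 4.  The minimum-norm solution is deterministic,
consistent with the observations, and reproduces the exact-recovery
limit (zero noise → zero error), which ordinary OLS implementations
that refuse rank-deficient designs would not.

## The generic surface

Predictions are expressed as one of the 238 triangle centroids of a
generic LV endocardial surface.  The original surface was digitized from
a necropsy specimen and is unavailable, so `build_generic_lv_mesh`
reconstructs an equivalent geometry: a prolate ellipsoid of revolution
with semi-axes 45 / 22.5 / 22.5 mm (the normal echocardiographic 2:1
long-to-minor ratio), truncated by a basal plane at 0.75 of the
semi-long axis, tessellated as a 14-sector apex fan plus 8 latitude
rings of split quads — exactly 14 + 2·14·8 = 238 triangles with an open
basal rim of 14 boundary edges.

Two reconstruction details were genuinely open and are our choices:

* **Ring placement.** Latitude rings are spaced uniformly in meridian
  arc length, not in parametric angle, keeping triangle areas
  near-uniform from apex to base.  The resulting edge-adjacent
  centroid spacing is 5.82 ± 1.42 mm, inside the documented
  5.4 ± 1.4 mm band (and matching its SD); the equal-angle alternative
  gives 5.73 ± 1.84 mm.
* **Basal truncation at 0.75** of the semi-long axis; the true level is
  undocumented.

The cavity center is the generating ellipsoid's center for generated
meshes, and the area-weighted mean of face centroids for meshes loaded
from OFF/PLY files without a sidecar.  Neighbor spacing is measured over
edge-adjacent face pairs; a vertex-adjacent or all-pairs definition
would give systematically different (for all-pairs, order-of-magnitude
larger) numbers.

Element ids are 1-based everywhere a user sees them; 0-based indexing is
confined to arrays and file I/O.

## Projection rules

Both rules assign a predicted point to a triangle centroid, never to a
triangle interior or edge:

* **SA (smallest angle):** minimize θₜ = arccos(**A**ₜ·**B**/|**A**ₜ||**B**|)
  over the 238 centroid vectors **A**ₜ (cavity center → centroid), with
  **B** the cavity center → predicted point vector.  The cosine is
  clamped to [−1, 1] before arccos (floating-point safety at θ ≈ 0).
  The rule is exactly invariant to positive radial scaling of the
  predicted point about the cavity center.
* **KNN (1-nearest neighbor):** minimize Euclidean distance to the
  centroids.  K is fixed at 1 — with one labelled point per class a
  majority vote over K > 1 is undefined, so larger K is rejected rather
  than guessed at.

Ties are broken toward the lowest element id (deterministic and
reproducible); `tie_count` reports co-optimal elements within a 1e-9
relative band.  `knn_oracle` is a plain exhaustive scan retained as the
reference that the vectorized implementation must match exactly,
tie-breaks included.

Why the rules differ on a prolate ventricle: centroid radii range from
≈ 22 mm (equatorial waist) to ≈ 43 mm (apex), and at mid latitudes the
ray from the cavity center meets the surface obliquely.  The angular
rule therefore (a) ranks candidates by an angle that undervalues
large-radius elements and (b) amplifies direction noise by ≈ 1/sin ψ
(ψ the ray–surface angle, down to ≈ 53° at 2:1 eccentricity).  On a
sphere the two rules agree for any radial perturbation; the
disagreement rate and the error gap grow with eccentricity.

## Distances

Localization error on the pacing-site protocol is a geodesic
approximated as a spherical arc: r̄·θ, where θ is the angle between the
two centroid vectors at the cavity center.  The sphere radius is not
uniquely defined on an ellipsoid; we use the mean of the two centroid
radii, which is symmetric and avoids biasing apical (large-radius)
against equatorial pairs.  The VT-exit protocol uses the plain Euclidean
centroid distance.  Exact curved-surface geodesics (Dijkstra / heat
method) are deliberately out of scope: the method's published protocol
is the arc approximation.

## Evaluation protocol

* **Split:** train fraction 0.8, train size rounded half-up (1,012 →
  810/202), uniform unstratified permutation given a seed.
* **Out-of-bag bootstrap:** each of 1,000 trials draws n sites with
  replacement as the training set, refits the coefficients, and
  evaluates on the unique left-out samples (expected count
  n(1−1/n)ⁿ ≈ n/e ≈ 372 for n = 1,012).  An empty out-of-bag set is
  redrawn (logged).  Per-trial gmean/gsd/gmedian are aggregated across
  trials with mean, SD, median and 5th/95th percentiles.
* **Method comparison:** two-sided Wilcoxon signed-rank as the primary
  paired test (errors are right-skewed, with outliers), with the paired
  t-test p-value and a percentile-bootstrap 95% CI of the mean
  difference reported alongside.  `bootstrap_compare` runs both
  projectors on identical resamples (same seed → same draws and fitted
  coefficients per trial), so the per-trial mean errors are exactly
  paired; the signed-rank test over those 1,000 paired trial means is
  the bootstrap significance assessment.  A single 202-sample split is
  underpowered for a ≈ 0.25 mm mean gap; the paired bootstrap resolves
  it.
* **Outliers:** Tukey fences at 1.5·IQR beyond the quartiles; quartiles
  and all percentiles use linear interpolation between order statistics
  (the 5th/95th summary columns depend on this convention).

## The synthetic scenario

The generator emulates the structure of the clinical development data
(1,012 pooled endocardial pacing sites with paced ECGs, registered onto
the generic surface), none of which is publicly deposited:

| parameter | default | meaning |
|---|---|---|
| `n_sites` | 1012 | pooled pacing-site count of the development dataset |
| lead field | 8×3, N(0, 1) µV·s/mm | random full-rank affine site→integral map; offsets N(0, 10) µV·s |
| `source_scatter_sd` | 8.0 mm | displacement of the effective electrical source from the registered centroid (calibrated, see below) |
| `integral_noise_sd` | 2.0 µV·s | beat-to-beat / measurement noise on the integrals |
| `jitter_sd` | 3.7 mm | interobserver registration variability, applied to the regression targets |

Sites are drawn uniformly over the 238 elements (the clinical spatial
distribution is unknown; the assumption is recorded in each dataset's
manifest, which suffices to regenerate the dataset bit-identically).

**Where the error lives matters.**  The labelled element and the
regression target sit on (or jittered about) a registered centroid, but
the ECG of a real paced beat is generated by the true continuous source:
continuous catheter positions are hand-registered onto a discrete
238-element grid, and capture physics displace the effective origin
further.  The generator therefore feeds `centroid + scatter` to the
lead-field map.  This makes the regression's prediction errors scatter
isotropically around the labelled centroid.  The alternative — placing
all the error in integral (feature) space — induces errors-in-variables
attenuation: predictions are biased radially inward (on the default
scenario, mean predicted radius 25 mm against 30 mm true), which
penalizes the Euclidean projection rule toward the small-radius waist
by almost exactly the amount the prolate geometry penalizes the angular
rule, erasing a real geometric effect of the projection stage.  Source
scatter is both the more faithful account of the data-generating
process and the configuration in which the projection comparison
reflects projection geometry rather than regression bias.

**Calibration.** The scatter SD is the one deliberately tuned constant:
`scripts/calibrate_noise.py` sweeps it and 8.0 mm puts the default
scenario's 1-NN mean geodesic error at ≈ 9.4 mm on the split protocol
(seed 0) — the method's reported clinical working point.  All other
defaults were fixed a priori.

**What passing tests do not show.**  The generator is exactly affine
with Gaussian, patient-homogeneous noise on an idealized ellipsoid of
revolution.  Real data violate all of this: the ECG–site relationship is
only approximately linear, 38 patients contribute correlated clusters,
the necropsy surface is irregular (which plausibly makes the angular
rule's projection error considerably larger than the ≈ 0.25 mm mean gap
seen here — clinically a ≈ 3 mm gap is reported), and pacing sites are
not uniform over the LV.  Synthetic results validate the machinery and
the direction of effects, not clinical effect sizes.

## Waveform layer

`simulate_ecg_waveforms` realizes a requested integral vector as
raised-cosine QRS-like bumps supported exactly on the 120 ms window, so
the left-rectangle integral reproduces the request exactly at integer
sample counts (within 0.5% otherwise).  This exercises the ECG-feature
path (file I/O, unit normalization, onset detection, integration) end
to end; it makes no claim of morphological realism.  QRS integration is
a left-rectangle sum (the published description is a plain area sum);
at ≥ 500 Hz the trapezoid correction is far below the noise level.  The
window takes `floor(window·rate)` samples; no baseline subtraction by
default (the published method applies none), with an optional
pre-onset-mean flag.  Onset detection thresholds a smoothed multi-lead
absolute-slope statistic at a fraction of its baseline-to-peak
excursion; it is plumbing, always overridable by a user-supplied onset,
and refuses flat records rather than guessing.

## Numerical and degenerate-input policy

* cos θ clamped into [−1, 1] before every arccos; identical-element
  distances are exactly 0 (not ulp-level arccos residue).
* A site at the cavity center has no direction: the angular rule
  refuses it rather than returning an arbitrary element.
* Fits refuse empty or non-finite training data; predictions refuse a
  lead order differing from the coefficients' metadata rather than
  silently reordering.
* Coefficient files are versioned JSON carrying lead order, units and
  training size; loads validate all three.
* Every stochastic step takes an explicit seed; CLI runs write a
  manifest sufficient for bit-identical re-execution.

## Problem sizes

Default test and evaluation runs use the clinical-scale protocol
directly (1,012 sites, 1,000 bootstrap trials) — the vectorized
projection and the small design matrix make a full paired bootstrap a
matter of seconds — with smaller site counts in unit tests where the
property under test does not depend on scale.

## Known limitations

* The reconstructed ellipsoid reproduces the element count and spacing
  statistics of the original surface, not its shape; patient-specific
  registration is out of scope.
* k > 1 nearest-neighbor voting, projection onto triangle interiors,
  curved-surface exact geodesics, and epicardial/right-ventricular
  extension are deliberately not implemented.
* The bootstrap refits coefficients every trial by design (it estimates
  the optimism of the full fitting pipeline); there is no no-refit mode.
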