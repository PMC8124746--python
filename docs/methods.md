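# Methods

This note documents the models, procedures and numerical choices behind
`shrubspec`, and what the synthetic-data tests do and do not establish
about real field data.

## Data model and preprocessing

Spectra live on a uniform wavelength grid, by default 350–2500 nm at
1 nm (2151 points), with a boolean validity mask instead of deletion so
band bookkeeping stays aligned across operations. Three atmospheric
water-vapour windows are masked by default — 1350–1430, 1750–1980 and
2330–2500 nm, endpoints inclusive — leaving 1668 valid points on the
default grid. Replicate spectra within a quadrat are averaged
arithmetically; a point is valid in the mean only where every replicate
is valid, which makes masking and averaging commute (the order of the
two steps is therefore immaterial, and both orders are exercised in
tests). Reflectance is validated to [0, 1.5]: values in (1, 1.5] occur
in real field spectra near panel calibration and are accepted with a
warning; anything outside is rejected as corrupt.

On disk a library is a wide CSV (wavelength column plus one column per
sample, 6 significant digits, masked cells empty) with a metadata
sidecar. Write→read→write is byte-identical; numeric round-trip error is
bounded by 5 × 10⁻⁶ relative.

## Synthetic transect generator

The generator emulates the statistical structure of a shrub-encroached
fescue-prairie transect, not any particular site:

* **Geometry.** 381 m line, quadrats every 3 m → 128 quadrats; three
  seasons; five replicate spectra per quadrat; ten pure-shrub endmember
  spectra per season. These defaults are the study conditions the
  analysis assumes and are not tuned per test.
* **Shrub fraction field.** A moving-average-smoothed Gaussian field
  along the line, logistic-squashed to [0, 1]. The squash offset is
  calibrated analytically (probit-style correction
  `logit(m)·sqrt(1 + π s²/8)`) so the realised mean tracks the
  configured mean (default 0.20). Fractions below 0.03 are floored to
  exactly zero, creating the shrub-free quadrats that anchor group 1.
  An alternative *planted strata* mode assigns fixed fractions
  cyclically (used for recovery tests).
* **Composition.** The non-shrub remainder is split among green grass,
  forb, standing dead, litter and bare soil by a Dirichlet draw with
  season-specific concentrations chosen for realistic orderings
  (standing dead largest in fall, green grass peaking in summer). The
  shrub fraction itself carries seasonal multipliers (1.0 / 0.92 / 0.88)
  for leaf loss. Exact cover means of any field campaign are not
  reproduction targets.
* **Endmembers.** Parametric spectra: a visible baseline with optional
  NPV slope, Gaussian pigment wells at 450 and 680 nm, a logistic red
  edge onto an NIR plateau, a gentle SWIR roll-off, and Gaussian water
  wells at 1200/1450/1940 nm. Season scalars modulate pigment depth,
  water depth, NIR level and visible brightness (senescence brightening
  in fall). These shapes encode the qualitative contrasts the analysis
  relies on — pigments in the visible, leaf structure in the NIR,
  moisture in the SWIR — and make no quantitative claim about species
  reflectance.
* **Spectra.** Per quadrat, reflectance is the exact linear mixture of
  class endmembers weighted by true fractions; replicates add i.i.d.
  Gaussian noise (default SD 0.01, a typical field-spectroradiometer
  noise floor) and are clipped to [0, 1]. With zero noise the mixture is
  exact, which the linearity tests use.
* **Sampling protocol.** Visual cover quantization follows the field
  rule: nearest 1% below 5% and above 90%, nearest 5% between. The
  5–10% band is not covered by the stated rule; the coarse 5% rounding
  applies from 5% upward (7 → 5, 8 → 10), read as the simpler two-regime
  scheme. Line-intercept cover derives from canopy patch intervals
  (one patch per shrubby quadrat, length proportional to its fraction),
  with overlapping patches merged before summation.
* **Reproducibility.** All randomness flows from one integer seed
  through `numpy.random.SeedSequence.spawn` — one sub-stream per quadrat
  plus streams for the field and the endmember library — so scenes are
  identical across platforms and runs.

**What passing tests show, and don't.** The generator provides linear
mixtures with Gaussian noise, spatial autocorrelation, quantization and
seasonal modulation. It does not model canopy radiative transfer
(multiple scattering, shadowing, leaf angle distributions), detector
splice artefacts, illumination drift, or observer bias in visual cover.
Recovery results on synthetic scenes therefore validate the *pipeline
logic* — grouping, scanning, thresholding, post-hoc testing — not the
detectability of shrubs in any particular real landscape.

## Biophysical screening and seasonal change

The outlier screen is a single-pass 3-SD rule per variable, applied per
season (seasonal quadrat-shifting noise is the target, so pooling
seasons would blur it); mean and sample SD (n−1 throughout) are computed
once over all records including candidates, and the screen is applied to
the visually estimated covers and PAI. Seasonal change is the per-quadrat
difference summer−spring and fall−summer, with the fraction of quadrats
increasing / stable / decreasing per variable; the two deltas telescope
to fall−spring exactly.

## Cover grouping

Quadrats with cover strictly between 0% and 100% are clustered on their
preprocessed spectra (Euclidean distance) with K-means (10 seeded
restarts, best inertia) and Ward agglomeration, over k = 2…15. The
cluster count is the majority vote of five internal-validity indices —
silhouette, Calinski–Harabasz, Davies–Bouldin, Dunn, and a spherical
Gaussian BIC — with ties broken toward the smallest k. A published
variant of this step used a larger, unenumerated index panel; the panel
here is configurable and the majority rule is panel-agnostic.

Clusters are ordered by mean cover and merged while their cover ranges
overlap; breakpoints fall at midpoints between adjacent merged ranges,
and the top cluster's maximum cover closes the last intermediate group,
so any cover above it joins the ~100% endmember group. Group 1 always
holds exactly the 0%-cover quadrats, intermediate groups are half-open
intervals (low, high], and the endmember spectra are appended as the
final group (they do not participate in clustering). When K-means and
Ward disagree, the scheme with the lowest variance of group counts wins —
the balance criterion. The automated midpoint-merge rule replaces what
is, in practice, an analyst-judged step; reproducibility was preferred
over fidelity to manual judgement.

## Wavelength scanning

Spearman's rank correlation is computed per valid wavelength against
visual shrub cover, as the Pearson correlation of average ranks (the
tie-corrected form — quantized cover is heavily tied). Significance uses
the two-tailed critical value of r: for n > 30 the Student-t
approximation `r = t/sqrt(n−2+t²)` (0.1736 → 0.17 at n = 128); for
n ≤ 10 the exact permutation null is enumerated exhaustively; for
11 ≤ n ≤ 30 exhaustive enumeration is computationally out of reach, so a
seeded Monte Carlo permutation null (200,000 draws by default) stands
in, using the same definition — the smallest attained |r| whose tail
probability is at most α. No multiple-testing correction is applied
across wavelengths by default, matching a per-wavelength screening read
of the correlogram; a Bonferroni option exists. Significant regions are
maximal runs of one sign, broken at masked windows, with no width
filter.

## Separability and region extraction

Group moments use the sample SD; a zero-variance wavelength raises an
error naming the indices rather than silently flooring (an explicit
variance-floor option, default off, suggested floor 1e−8, exists for
degenerate synthetic groups). JM uses the `2(1−e^(−B))` convention so it
shares the [0, 2] scale with TD and the two are directly comparable; at
equal variances D = 8B exactly, hence TD = JM, asserted to 1e−12. All
metrics are univariate per wavelength; no multivariate covariance
version is offered. In IEEE double precision TD and JM saturate to
exactly 2.0 once the exponent underflows (around 30 SDs of separation);
the mathematical bound is strict.

Thresholds: TD/JM ≥ 1.8 good, (1.5, 1.8) moderate, ≤ 1.5 poor; M > 1
good with no moderate class. The moderate band's upper edge is read as
1.8 (the operational table rule). Ensemble regions require both TD and
JM to clear the threshold over a contiguous run ≥ 10 nm, broken at
masked windows; a season where the ensemble is empty can fall back to
TD-only regions, labelled as such (senescent seasons can leave JM
saturated low). The Shapiro–Wilk normality diagnostic per wavelength is
advisory only and never blocks the pipeline.

## Broadband simulation and group statistics

A band value is the response-weighted mean reflectance over valid
wavelengths; bands fully inside a masked window yield NaN. Bundled band
sets are parametric Gaussians at the nominal centres/FWHMs of Landsat 8
OLI and Sentinel-2A MSI — acknowledged approximations that keep the
package download-free; a loader accepts official SRF tables in long CSV.
Solar irradiance weighting is omitted because reflectance, not radiance,
is resampled. Effective bandwidth is the trapezoid integral of the
response over its peak.

Group comparison is a classical one-way ANOVA per band and season,
followed by Tukey–Kramer HSD (harmonic-mean correction, since group
sizes are unbalanced by construction) with significance at adjusted
p < 0.05 and p < 0.1; k groups yield k(k−1)/2 pairs. The endmember group
enters with all its spectra as members, not an average. A Welch ANOVA
option exists but the classical form is the default. The
minimum-detectable-cover summary reports, per season and level, the
lowest-cover group whose pair with the shrub-free group is significant
in at least one band, with supporting bands, plus the per-band tally of
separable pairs.

## Pipeline and determinism

Stages run in a fixed order, each writing its CSV so any stage can rerun
standalone; a JSON manifest records config, seed and library versions.
Identical config + seed reproduces every CSV byte for byte (timestamps
live only in the manifest). A failure aborts with the stage name after
writing a partial manifest. Degenerate scenes are handled explicitly: a
shrub-free transect yields a two-group scheme (0% + endmembers) and the
correlation scan is skipped where cover is constant.

## Problem sizes in tests

Unit tests use tiny grids (10 points) and short transects (11–32
quadrats); the end-to-end recovery test runs the full 128-quadrat,
three-season scene with planted strata at 0/15/45/75% cover and a
tightened composition concentration (×4), an engineered construction
whose purpose is an unambiguous ground truth for group recovery. The
bound sweeps use 10,000 random normal pairs; the quadrature
cross-validation of the Bhattacharyya closed form uses 1,000 pairs at
1e−8 absolute tolerance, with the integration window centred on the
analytic peak of √(p₁p₂) so vanishingly small overlaps remain resolvable.

## Known limitations

* Linear mixing only; no radiative-transfer canopy model (PROSAIL-class)
  and no topographic or atmospheric effects.
* Parametric SRFs, not official release curves.
* No spatial-autocorrelation adjustment of effective sample size in the
  correlation scan, and no mixed models for the transect structure.
* The exact-permutation critical value is exhaustive only to n = 10.
* Cover-group breakpoints depend on the clustering; with heavily
  overlapping cluster cover ranges the merge rule can collapse groups.
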