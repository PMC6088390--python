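# Methods

## Registration into the spherical ROI system

Chromatin is segmented on the DAPI channel by an Otsu threshold followed by
26-connected component labelling; components below `min_volume`
(default 20 µm³) are discarded. Each component is summarized by its
second-moment ellipsoid: centroid = mean of voxel centers, axes =
eigenvectors of the voxel-coordinate covariance, half axes = √(5λ) (the
covariance–half-axis relation of a uniform solid ellipsoid). All geometry
is done in physical micrometres with the stack origin at the center of
voxel (0,0,0), so results are voxel-spacing independent.

The mitotic frame is phase-specific. Metaphase: one component; axis = the
shortest principal direction of the plate, center = centroid, sphere radius
`R = 1.5·a₁`. Segregation: two components; axis = the normalized
centroid-to-centroid vector, center = midpoint, `R = 1.5·(d/2)` with `d`
the centroid distance. The 1.5 factor expresses "the fourth of six equal
shells ends at the landmark" (`R = (6/4)·landmark`); for segregation the
fourth shell boundary passes through both daughter centroids. The paper's
alternative phrasing for the segregation orientation ("average of the
first two eigenvectors…") is ambiguous; the centroid-to-centroid axis is
used, matching the geometric construction in the reference figure. The
axis sign is arbitrary (cell poles are indistinguishable); it is
normalized to a nonnegative z-component (ties: y, then x) and all
downstream geometry uses |latitude| only, so results are invariant to the
sign.

Voxel assignment: stacks are first resampled to isotropic spacing (linear
interpolation along z to the in-plane pixel size), then every voxel center
with ρ = |x − center| ≤ R is assigned shell `μ = min(6, ⌊6ρ/R⌋+1)` and a
latitude band — equatorial [0°, 30°), diagonal [30°, 60°), polar
[60°, 90°] — with lower-inclusive boundaries and ρ = 0 mapped to
(shell 1, polar). Binning by latitude band is used directly instead of
first tiling the sphere into many equal-area segments and then merging
them into the same three bands; band membership is mathematically
identical. Partitioning is total: every in-sphere voxel counts exactly
once.

The eccentricity scores `r_μ = (μ−½)/6` (mid-shell radii) and orientation
scores `φ_ν` = 15°/45°/75° (angle of the sector mid-latitude direction
from the mitotic axis, so larger = closer to the division plane) are the
symmetric, monotone choice for the intensity-weighted "center of
eccentricity/orientation" summaries; their numeric values are a convention
of this package. Positive Δr means movement toward the periphery, positive
Δφ movement toward the division plane.

## Group statistics

c and a are log-transformed before Welch's t-tests (protein content is
log-normal across cells); r and φ are bounded location scores and are
tested on raw values. Effects are log2 fold changes for c/a (difference of
log means, i.e. geometric-mean ratios, matching the scale of the test) and
additive differences for r/φ. Significance uses Bonferroni with m = 52 by
default (13 species × 4 measures); per-ROI comparisons use m = 18.
Confidence intervals are seeded percentile bootstraps (default 1,000
resamples, 95%); BCa was not used — the plain percentile interval is
sufficient for the effect sizes and sample sizes involved and keeps the
procedure transparent. Whether a published Δr/Δφ is a difference of group
means or a mean of per-cell differences is not decidable from the source;
group-mean differences are implemented.

## The affinity model

Binding of species i to the structures in ROI l and pairwise dimerization
inside the ROI are modelled by mass-action kinetics with non-limiting
binding sites; at steady state the bound monomer is `Aᵢ/Kᵢₗ` and the dimer
`AᵢAⱼ/(KᵢₗKⱼₗθᵢⱼ)` — verified in this package by integrating the ODE system
to equilibrium and comparing with the closed form (`steady_state_oracle`).
After median normalization the measured fold-change intensities obey

    Ĩᵢₗ = dᵢ α̃ᵢₗ Ĩᵢ,ₜ (1 + Σⱼ α̃ⱼₗ βᵢⱼ Ĩⱼ,ₜ)

with phase-specific d and α̃ and phase-independent symmetric β. Cell
averages Ĩᵢ,ₜ enter as model inputs; the residual vector covers the 18·S
ROI values of every cell, weighted by ε = 0.05·value + 0.05·(species
maximum over all included cells). A typography ambiguity in the source's
residual formula (placement of the square on ε) is resolved as
`residual = (data − model)/ε`, the standard weighted least squares
consistent with its χ² usage.

**Identifiability and the canonical gauge.** The model is *exactly*
invariant under `(α̃, d, β) → (s·α̃, d/s, β/s)` for any s > 0 — every
prediction is unchanged, so one scale direction is structurally
unidentifiable (numerically: a single zero eigenvalue of JᵀJ). Fitted and
generated parameters are therefore expressed in a canonical gauge, chosen
as geometric mean α̃ = 1 across the phases carrying data: for
median-normalized data α̃ᵢₗ is a typical bound fraction of order one, so
the convention is the natural centering, and the transformation preserves
the RSS exactly. The gauge-invariant, directly interpretable quantities
are the products dᵢ·α̃ᵢₗ (reported by `rescale_roi_affinities`) and the
combinations α̃ⱼₗβᵢⱼ. Beyond the exact gauge there are *soft* directions:
per-species rescalings are resisted only by the partner interaction terms,
so individual β values are well determined only when the dimerization term
contributes a non-negligible share of the signal. Fisher-information
analysis at the ground truth of the standard recovery study shows
worst-entry product uncertainties of tens of percent, while the median
product error stays in the few-percent range; recovery is therefore scored
by the median relative product error and the (gauge-fixed) log10 RMSE of
β.

**Fitting.** Parameters are optimized in log10 space by bounded
trust-region-reflective least squares with an analytic Jacobian (validated
against finite differences), bounds α̃, d ∈ [10⁻³, 10²] and
β ∈ [10⁻⁷, 10²], multi-start with log-uniform starts (default 50; a fit is
flagged converged when the RSS gap between the two best starts is below
the largest single-datapoint squared residual), tolerances 10⁻⁶, at most
2,000 function evaluations per start. Forward selection is best-first: at
each step every remaining candidate pair is refit (multi-start plus a warm
start from the incumbent fit) and the largest RSS drop is accepted if it
exceeds χ²₀.₉₅(1) = 3.841 — under the fixed Gaussian error model the
weighted RSS is −2·log-likelihood up to a constant. Withdrawal
(contribution) tests refit without one pair and report the χ² increase at
the same threshold.

With a k-candidate pool the greedy step accepts the *best* of k correlated
tests at a fixed threshold, so its null acceptance rate is roughly
1 − (1−α)ᵏ (measured ≈21% at k = 5, with per-candidate rate 5%) — an
intrinsic property of fixed-threshold forward selection, not an
implementation artifact. The calibration study therefore measures the
per-test step rate with a single candidate per replicate (rotating the
candidate pair), and a separate planted-signal study verifies that a true
interaction wins the multi-candidate race.

## Synthetic data

**Image phantoms** place a metaphase plate (solid ellipsoid, short axis
along the configured mitotic axis) or two congruent daughter ellipsoids
separated along the axis, plus antibody channels with canonical patterns:
spindle (Gaussian fibre between the poles), centrosomes (Gaussian blobs at
the poles), uniform, and cytoplasmic shell. Chromatin edges get a ~1-voxel
linear soft edge so ROI means are stable under rotation of the sampling
grid; the center voxel still reads exactly background + amplitude. Noise
is optional Gaussian read noise plus Poisson shot noise (both can be
disabled for exact tests); no PSF convolution, photobleaching or
multi-cell scenes are simulated — phantoms validate geometry and binning,
not optics. Pattern SNR defaults are chosen for testability; real antibody
SNR varies widely and is not emulated.

**Intensity tables** are generated directly from the steady-state model:
per-cell species totals are i.i.d. log-normal (default μ = 0 so the
population median is 1 — already on the normalized scale; log-sd 0.5, a
typical cell-to-cell spread of protein content), phases are labelled
metaphase/segregation by configurable fractions, and ROI values are the
exact model prediction with optional additive Gaussian noise whose sd is
the same 5% + 5%-of-max error scale used as the fitting weight (truncated
at zero), making recovery studies self-consistent. Default ground-truth
parameters are log-uniform: α̃ in (0.5, 2) — a 2–4× localization contrast
that keeps every ROI value well above the 5%-of-max error floor — d in
(0.5, 2), and planted β in (0.2, 1), which makes dimerization a 20–100%
correction on top of direct recruitment for interacting pairs. This is the
regime the model itself presumes (free content approximately proportional
to total content holds when direct compartment affinity dominates
recruitment) and the regime in which β is identifiable at all; with
dimerization dominating, the products d·α̃ drift along near-flat
directions. What passing recovery tests show is that the estimation
machinery is correct and well calibrated in this regime — not that every
parameter of a 13-species network fitted to real images is equally well
determined.

## Validation studies and problem sizes

`sphericell.validation` packages the standard studies (also run by
`scripts/acceptance.py`): 100 random-rate toy systems for the equilibrium
check (agreement to 10⁻⁶ relative); 20 noisy phantoms per phase at 0.5 µm
spacing for geometry recovery (median axis error ≤ 3°, median radius error
≤ 5%); 4 species × 18 ROIs × 200 cells × 3 planted β × 50 starts for
parameter recovery (β log10 RMSE ≤ 0.3, median product error ≤ 10%); 200
single-candidate, 60-cell, metaphase-only replicates for selection
calibration (the null acceptance behavior does not depend on the second
phase, and the smaller problem keeps the study desk-scale) plus 30
planted-signal replicates; 300 null families of 52 comparisons for the
family-wise error and 500 replicates for bootstrap coverage. These sizes
are the package's standard study conditions; they keep each study in the
minutes range on a single CPU.

## Known limitations

- No inter-round registration, mitosis classification, deconvolution or
  multi-cell segmentation: input stacks are assumed registered and cropped
  to one annotated cell.
- The affinity β is an enrichment-based association measure, not proof of
  direct physical binding, and is reported in a gauge convention (above).
- Cell-average values serve as model inputs and normalization anchors;
  `cell_average_consistency` reports (but does not fit) the volume-weighted
  consistency between modelled ROI values and measured averages.
- Empty ROIs (clipped spheres, masked voxels) propagate as missing values
  into measures and comparisons rather than being imputed.
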