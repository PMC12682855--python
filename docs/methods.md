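# Methods

This note records the models, conventions and numerical choices behind
`pindicator`, and what the synthetic-data generators do and do not emulate.

## Trial design and units

A trial is 26 genotypes × 2 phosphorus levels (optimal `P+`, deficient
`P-`) × k replicate tubes (defaults 6 and 4, the layouts of the two
platforms the package models: 312 and 208 tubes). `p_applied` is the mass
of P (g) made available per tube at each level; the defaults
(5.0 mg at `P+`, 0.053 mg at `P-`) correspond to the two Hoagland
phosphate concentrations used in such trials (0.3 mM vs 0.0032 mM, 31 g/mol
P) at a common reference solution volume. PAE is invariant to a joint
rescaling of uptake and applied P, so the volume convention cancels as long
as both sides are per tube.

The PUE formula is implemented literally as DW²/concentration — dry weight
divided by tissue P concentration, times dry weight again (the balance
method). Its unit is therefore g²·(concentration unit)⁻¹; the
concentration unit is carried as a configuration label (`mM` by default)
and never converted silently. APUE and relative efficiency are computed
from genotype-mean *whole-plant* (shoot + root) dry weight; a shoot-only
basis is available via `MetricConfig(biomass="shoot")`. Replicate summaries
use the sample (n−1) standard deviation.

One harvest record is one tube. Where a platform sows multiple seeds per
tube the values are per tube, not per plant; the data model does not try
to resolve that ambiguity, it only documents it.

## The P indicator

Each of the five metrics is min–max normalized across genotypes
(min → 0, max → 1; a constant column maps to 0.5 everywhere with a
warning, contributing equally to all genotypes), oriented, and summed, so
scores live in [0, 5] with both bounds attainable. One indicator is
computed per P level; PAE/PRAE/PUE enter at that level while relative
efficiency and APUE are level-free and shared. The default condition is
`P-`, the regime the indicator is meant to rank genotypes for. Ranks are
dense (1 = best; ties share a rank).

**Orientation.** PAE, PUE, relative efficiency and APUE are higher-is-
better. PRAE (uptake per unit root biomass) is treated as
*lower*-is-better by default: for a fixed amount of P captured, a low
PRAE identifies the genotype that built the larger root system, and root
investment — foraging — is the adaptive trait the deficient condition
selects for. A genotype with high PRAE achieved its uptake with little
root, which under sustained deficiency leaves no margin. This choice also
makes the composite reproduce the cross-platform agreement observed when
the packaged two-platform tables are scored (Pearson r = 0.426 between
platforms; with PRAE taken higher-is-better the agreement drops to
r ≈ 0.30). Orientations are per-component configuration, so either
reading is available.

**Quadrants.** Responsiveness (APUE) is crossed with efficiency
(whole-plant dry matter under `P-`) at the across-genotype mean (or
median) of each axis. Boundary genotypes classify upward (`>=`), so a
genotype exactly on both thresholds is ER. The mean rule is the default;
switching to the median moves only genotypes lying between the two
thresholds.

## Agreement statistics

* Pearson r with the two-sided t-based p-value (n − 2 df).
* Lin's CCC with population (1/n) moments:
  `2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)`. Its p-value tests CCC = 0 via the
  Fisher z-transform with the Lin (1989) asymptotic standard error. |CCC|
  never exceeds |r|, and equals it only without location/scale shift.
* Bland–Altman: differences d = x − y, limits x̄_d ± k·SD_d with sample SD
  and k = 1.96 by default; pairs outside the limits are flagged. Note the
  small-n subtlety: a single huge difference inflates the SD enough to
  contain itself (at n = 4, d = [0,0,0,10] flags nothing).
* The metric correlation matrix masks cells with p ≥ α (default 0.05,
  no multiplicity correction within the matrix).

Correlations between platforms and between metrics are computed on
genotype means (n = 26), the granularity of the packaged tables;
replicate-level correlation mixes within- and between-genotype variation
and is deliberately not the default surface.

## Trial statistics

Two-way ANOVA with interaction (genotype × P level) via an OLS fit;
balanced designs report the classical decomposition (where sequential and
Type II sums of squares coincide), unbalanced designs fall back to Type II.
Assumption checks are the Brown–Forsythe variant of Levene's test
(median-centered; robust to non-normality) and Shapiro–Wilk on pooled
within-cell residuals. Within-genotype `P+` vs `P-` contrasts use the
pooled-variance Student t (not Welch), two-sided, with Bonferroni
correction over the number of genotypes actually tested; adjusted p is
clamped to [raw p, 1].

## Root imaging

* **Stitching.** Adjacent 60° views are registered by normalized
  cross-correlation of column-mean intensity profiles over candidate
  overlaps (≥ 8 px — shorter windows are degenerate), with near-ties
  resolved toward the larger overlap; overlapping columns are averaged.
  Rotation correction is approximated by horizontal translation; no
  cylindrical unwarping.
* **Denoising.** `svd_denoise` is the best rank-r approximation
  (Eckart–Young), clipped to [0, 1]; error is nonincreasing in rank. It
  is *not* part of the default measurement chain: thin oblique roots are
  far from low-rank, and aggressive truncation destroys them. It is kept
  for structured (line/banding) sensor noise with a generous rank.
* **Segmentation.** Laplacian of Gaussian at scale σ, which responds
  positively on structures darker than their surroundings; a polarity
  flag negates the response for inverted contrast (an inverted image
  yields the identical mask). Binarization is Otsu's threshold on the
  response. σ should be matched to the expected stroke width — about half
  the width (σ = 1.6 for 3-px strokes, 3.0 for 5-px strokes in the
  rendered-scene tests).
* **Cleaning.** Keep the largest 8-connected component whose topmost
  pixel lies in the top 10 % of rows (roots hang from the seed at the
  tube top). Because thresholded masks fragment at branch junctions,
  connectivity is decided on a copy dilated by `bridge_px` (default 3)
  while output pixels come only from the input mask, preserving the
  output ⊆ input invariant.
* **Area.** Foreground count × coeff². The default coefficient 0.0042
  length-units/px is kept configurable; note that a true 600 dpi pixel
  pitch would be 25.4/600 ≈ 0.0423 mm/px, an order of magnitude larger —
  the default is retained as the conventional value, not endorsed as
  physically consistent.
* **Growth curves.** Descriptive least-squares B-splines (default cubic)
  with interior knots at time quantiles; the basis dimension `df` trades
  smoothness for fidelity (df = 8 reproduces a noise-free logistic over
  13 scan times within 1 % of its asymptote). Unconstrained least-squares
  splines can overshoot by a fraction of a percent at plateaus, so exact
  monotonicity is not guaranteed. Mixed-effects growth inference is out
  of scope; only per-tube descriptive fits are provided.

## Synthetic-data generators

All generators draw from per-purpose substreams of one seeded NumPy
generator, so runs are reproducible and independent of call order.

**Factorial trial.** Log-scale model for whole-plant dry weight of
genotype i at level l:

    log DW_il = log(dw_pminus) + τ_l + w_l·σ_g·e_i + γ_il,

with latent genotype efficiency e_i ~ N(0,1), treatment lift
τ_{P+} = 1.41 (about a four-fold biomass gain under optimal P),
genotype scale σ_g = 0.25 expressed fully under `P-` and at weight 0.4
under `P+`, and interaction wobble γ ~ N(0, 0.08²). Root allocation
rises with e_i under `P-` (slope 0.30 on the root/shoot ratio) — efficient
genotypes forage; tissue P concentration is an order of magnitude lower
under `P-` and rises weakly with e_i (slope 0.05); uptake is exactly
DW × concentration. Replicates multiply every response by log-normal
noise matched to a 10 % CV. Scales were chosen once so the simulated
metric ranges bracket those of real 26-genotype wheat trials (PAE
roughly 10–90 %, PUE tens to hundreds, APUE tens). Ground-truth metrics
are computed in closed form from the noise-free backbone, so recovery
tests compare the pipeline against an independent arithmetic path.

What this emulates: the effect structure the analysis assumes (genotype,
treatment, interaction, multiplicative replicate error) and internally
consistent biomass/uptake/concentration responses. What it does not:
soil-P dynamics, uptake kinetics, multi-seed tubes, block effects,
measurement error correlated across organs. Passing recovery tests
therefore shows the *analysis chain* is faithful under its assumed error
model, not that real trials behave this way.

**Paired platforms.** Platform latents are standard normal with
correlation ρ_true; each metric column is an affine map of the platform
latent (negative slope for PRAE) plus independent genotype-level noise
(SD 0.15) and a platform-specific scale/offset distortion. Min–max
normalization removes affine distortion exactly, so the recovered
cross-platform indicator correlation tracks ρ_true with only mild
attenuation (≈ 0.44 recovered at ρ_true = 0.45 over 500 runs).

**Growth series.** Logistic area(t) = A/(1 + exp(−k(t − t₀))) with
genotype-specific asymptote (log-normal around 30 000 px²), rate
k ∈ [0.08, 0.16] d⁻¹ and midpoint t₀ ∈ [30, 55] d; the `P-` asymptote is
multiplied by 0.55; tubes add a log-normal intercept (SD 0.10) and
additive Gaussian noise, clipped at zero. Scan times default to weekly
from day 7 to day 91.

**Rendered scenes.** A single trunk random-walks downward from the top
row with up to n−1 side branches splitting off the upper trunk, so the
skeleton is one connected component anchored at the top, as a real root
system is. The skeleton is dilated to the stroke width, drawn dark (0.20)
on a bright background (0.85) over a smooth low-amplitude substrate
texture (σ = 3 px, amplitude 0.04 — enough registration signal for
stitching, negligible for segmentation), plus Gaussian pixel noise. Six
views of equal width with 24 shared columns are cut at known offsets
(wrapping around the cylinder). On these scenes the default chain recovers
the true area with mean error ≈ 4 % and stays within 10 % for roughly
97–100 % of scenes depending on stroke width; residual error is Otsu
threshold variance across scene content, slightly under-covering wide
strokes and over-covering thin ones.

## Degenerate inputs and tie-breaks

Constant metric column → 0.5 components with a warning; constant ANOVA
response → error; both-constant CCC input → error; zero-variance Pearson →
error; empty mask → empty cleaned mask and zero area; blank image → empty
segmentation; featureless view strips → zero overlap (plain
concatenation); quadrant boundary values classify upward; genotypes
missing a metric are excluded from the indicator with a warning and
normalization runs over the remainder.

## Known limitations

* The indicator weights all five components equally; no PCA or weighting
  scheme is offered.
* The CCC p-value is asymptotic; at n = 26 it is approximate.
* Segmentation accuracy is quoted for the renderer's contrast regime
  (dark roots, ~0.6 contrast, noise σ ≤ 0.05); low-contrast or blurred
  imagery will need σ and threshold tuning.
* The simulated trial is fully randomized; block/position effects present
  in real platform layouts are not modelled.
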