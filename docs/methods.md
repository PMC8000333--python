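# Methods

This note documents the models and algorithms implemented in `chromaqc`,
the choices made where the design was genuinely open, and what the
synthetic test bed does and does not demonstrate.

## Baseline estimation (peak filling)

UV chromatograms acquired near the solvent cut-off ride on a large, slowly
varying baseline.  The estimator proceeds in four steps:

1. **Primary smooth.** A Whittaker smoother: `z` minimizes
   `Σ(yᵢ−zᵢ)² + λ·Σ(Δ²z)²` with `λ = 10^lambda_exponent`
   (default exponent 6).  The linear system `(I + λDᵀD)z = y` is solved
   sparsely.  The penalty acts in *sample* units, so its effective width in
   minutes scales with the sampling interval; at typical UV sampling rates
   (≥ 10 Hz) the default smears peaks by only a few hundredths of a minute.
2. **Bucketing.** The smoothed trace is aggregated into `buckets`
   (default 2000) contiguous segments of near-equal point count (sizes
   differ by at most one), each represented by its mean value at its mean
   time.
3. **Iterative chord suppression.** For each of `iterations` (default 10)
   passes, with the window half-width `w` shrinking geometrically from
   `hwi` (default 30) to 1, every bucket is replaced by
   `min(v[i], (v[i−w]+v[i+w])/2)` — the chord through the window
   endpoints.  The update runs left-to-right *in place*, so filled values
   propagate across wide peak clusters; buckets whose window is truncated
   at the trace ends are left untouched (a clamped endpoint would drag a
   sloping baseline down).  We use the endpoint chord rather than window
   *means* deliberately: window means are dominated by the area of any
   peak inside the window (mass/width), so a mean-based fill stalls a few
   mAU above the baseline wherever peaks sit closer than the window width;
   the chord sees through peaks narrower than `2w` in one pass.
4. **Stretching.** Bucket values are interpolated linearly back to the
   full grid (linear extrapolation over the half-bucket overhang at each
   end) and lightly re-smoothed (`λ = 10^(lambda_exponent−2)`).

The suppression is monotone (each pass takes a minimum), exact on linear
baselines away from the edges, and idempotent on peak-free smooth signals
to well below 0.1 % RMS.  Its main systematic error is inherited from the
primary smoother: a second-difference-penalized smooth of a tall peak
undershoots on both flanks (~2 % of peak height), which the fill then
keeps, so the corrected trace slightly *over*-estimates areas next to
dominant peaks.  This bias is approximately proportional to the injected
amount and therefore cancels in calibration-based quantitation.

## Peak model and deconvolution

Peaks are Gaussians parameterized by height `h` (AU), center `c` (min) and
half width at half maximum `w` (min): `f(t) = h·exp(−ln2·((t−c)/w)²)`,
with analytic area `h·w·√(π/ln 2)`.  A chromatogram is modelled as the
plain sum of its peaks — no offset term, since the baseline is removed
beforehand.

Fitting is bound-constrained damped least squares
(`scipy.optimize.least_squares`, trust-region reflective, analytic
Jacobian): heights positive, centers inside the time window, widths
between a tenth of the sampling interval and `max_hwhm` (default
0.3 min).  The cost never increases from the initial point; non-converged
fits are returned flagged, never raised.  Peaks thinner than one sampling
interval are excluded as degenerate.

Automatic peak discovery seeds a Gaussian at the residual maximum (height
= residual, width = `init_hwhm`, default 0.06 min), refits, and repeats
until the residual maximum falls below `min_height` (default 1.2 mAU) or
`max_peaks` is reached.  Components that end below `min_height` or at the
width bound are then pruned and the set refitted once: UPLC peaks at this
scale are seconds wide, so a component that runs to a 0.3 min half-width
is absorbing left-over baseline structure, not a peak.

Runs are matched to a reference run greedily by nearest retention time
within `rt_tolerance` (default 0.15 min, below half the smallest gap
between named peaks); unmatched reference peaks get area 0 with a warning.
Peak names are retention times rounded to two decimals (`peak_14.35`), so
a fitted center may round one hundredth away from its nominal name —
matching is always by time, not by name string.

The two method-optimization responses are the sum of adjacent-pair
half-height resolutions `Rs = 1.18·(c₂−c₁)/(fwhm₁+fwhm₂)` and the sum of
analytic areas.

## Univariate calibration and validation

Each peak gets an OLS line `area = B0 + B1·c` over the calibration levels
(default 100/130/160/190/220 µg mL⁻¹).  `Sy.x = √(SSR/(n−2))`.  Models
with `R² > 0.99` (strict inequality) are retained.  Inverse prediction
uses `x₀ = (area−B0)/B1` with the standard 95 % interval half-width
`t₀.₉₇₅,ₙ₋₂·(Sy.x/|B1|)·√(1/m + 1/n + (x₀−x̄)²/Sxx)`.  Detection and
quantitation limits are `3.3·Sy.x/B1` and `10·Sy.x/B1`; with σ read as
Sy.x these reproduce the published range endpoints of the CMS assay
(4.12–17.98 and 12.48–54.50 µg mL⁻¹) from the printed coefficients.
Validation summaries follow pharmaceutical convention: accuracy as
`%E = 100·(mean−nominal)/nominal`, precision as `%RSD = 100·s/mean` with
the sample (n−1) standard deviation; repeatability is within-run,
intermediate precision pools all days at a level (no variance-components
model), stability covers timed re-injections and robustness the
deliberately perturbed runs.  Cells with fewer than two values are
reported missing, never zero.

## SIMPLS, jack-knife intervals, PCA

The PLS regressor is SIMPLS (direct deflation of the cross-covariance):
for each factor the weight vector is the current cross-covariance,
scores are normalized, and the cross-covariance is deflated by an
orthonormalized loading basis.  Regression coefficients are kept per
component count.  Leave-one-out cross-validation refits every fold from
scratch; the component count defaults to the smallest whose RMSEP is
within 5 % of the minimum.  On the synthetic calibration set one
component suffices (fitted R² ≈ 0.996).

Prediction intervals use Tukey jack-knife pseudo-values over the
leave-one-out coefficient sets: `θᵢ = n·θ̂ − (n−1)·θ̂₍ᵢ₎`,
`SE² = Var(θᵢ)/n`, with a `t(n−1)` quantile.  This is a standard
construction chosen because published per-batch limits for this assay are
not internally reproducible.

PCA is SVD-based on mean-centered (optionally autoscaled) data;
eigenvalues are `s²/(n−1)` and explained percentages sum to 100 over all
components.  The bootstrap summary resamples sample rows with replacement
(default 7 resamples, configurable), reporting mean and 2.5/97.5
percentiles of the explained percentages; degenerate resamples are
skipped with a warning.

## Batch conformity

Ratio vectors divide every retained peak area by a designated reference
peak (by default the retained peak with the highest calibration R², the
analogue of the assay's `peak_14.42` ≡ `peak_14.35` naming).  The
19-measure battery reports five similarities as-is (cosine, eJaccard,
eDice, Pearson correlation, Gower with ranges pooled over all samples)
and fourteen distances converted by `s = 1/(1+d)` so every score lives on
a 0–1 similarity-like scale and identical vectors score 1 everywhere.
Formula notes: Canberra sums `|xᵢ−yᵢ|/|xᵢ+yᵢ|` without dividing by the
length; Hellinger and the symmetrized Kullback–Leibler divergence
`Σ(pᵢ−qᵢ)·ln(pᵢ/qᵢ)` operate on sum-normalized vectors; Whittaker is
`½Σ|pᵢ−qᵢ|`; Bhattacharyya-type is `√(Σ(√xᵢ−√yᵢ)²)` on the raw vectors;
Podani is implemented as an ordinal discordance index — the fraction of
component pairs ranked in opposite order by the two vectors.  Pearson
correlation of a constant vector is undefined; we score 1 when both
vectors are constant and 0 otherwise.

Ratio matrices put every pairwise ratio `M[i,j] = areaᵢ/areaⱼ` in a fixed
global peak order (diagonal 1, `M[i,j]·M[j,i] = 1`).  Two matrices are
min–max scaled to [0, 1] by their *pooled* range and compared by SSIM with
the universal constants `K1 = 0.01`, `K2 = 0.03` and dynamic range 1.
Global mode (the default — a 23×23 matrix is small for windowing)
computes the statistic once over all entries with sample (n−1) moments;
windowed mode averages the same statistic over sliding odd-sized windows
with uniform weighting and border cropping, matching the standard
image-quality implementation to ≤ 1e-6.  Both the battery and SSIM are
invariant to overall concentration scaling because ratios cancel it.

The conformity report scores every batch against the reference (battery,
SSIM, Euclidean distance in the first two PCA score dimensions of the
ratio vectors) and flags the batch with the minimum SSIM when it falls
below a threshold (default 0.97; under the generator's default conditions
conforming batches score ≈ 0.999, a moderately deviating batch ≈ 0.994
and the expired-like batch ≈ 0.957).  Heatmaps use a fixed peak order and
a symmetric diverging palette so extremes are dark and mid-values light;
a text twin of every matrix is written for diffing.

## Box–Behnken design and desirability

The 3-factor design places all ±1 combinations on each factor pair with
the third factor at center (12 edge runs) plus replicated center runs
(default 5; 17 runs total).  Factor levels default to the assay's:
ammonium formate 1–3 mM, wavelength 214–220 nm, column temperature
29–40 °C.  Response surfaces start from the estimable cubic-type candidate
set (linear, two-way interactions, squares, and the mixed `xᵢ²xⱼ` terms;
aliased columns are dropped by rank) and are reduced by backward
elimination at α = 0.05 with hierarchy preserved.  The ANOVA partitions
the residual into lack-of-fit and pure error from the center replicates
(pure-error df = n_center − 1); without replicates lack-of-fit is
reported unavailable.  Desirability is Derringer–Suich for maximize
goals, `d = clip((ŷ−L)/(U−L), 0, 1)^weight`, combined as a geometric
mean and maximized over a deterministic coded-space grid (default 21³)
polished by Nelder–Mead; anchors default to the observed response range.

## Synthetic data generator

The generator emulates the assay's statistical structure with exact
ground truth.  Twenty-nine Gaussian peaks span 7.28–24.20 min over a
0–34 min window; the 23 peaks named in the assay's calibration table use
its published slopes (1.18×10⁻⁶–3.62×10⁻⁵ AU·min per µg mL⁻¹) as linear
response factors, and six additional peaks respond *quadratically*
(`rf·(2c²/160 − c)`, which meets the linear response at 160 µg mL⁻¹ but
bends to a best-line R² ≈ 0.979 across 100–220 µg mL⁻¹) with threefold
area noise, so the R² > 0.99 filter reproducibly splits 29 → 23.  Widths
are 0.05–0.08 min (narrow UPLC peaks; the closest named pair, 0.23 min
apart, stays resolvable at Rs ≈ 1).  Traces sample at 1 ms intervals
(0.001 min; a typical UV detector rate, and fine enough that the fixed
smoothing penalty barely smears peaks), ride on a drift
`0.02 + 0.0006·t + 0.008·sin(πt/34)` AU and carry i.i.d. Gaussian
detector noise (sd 2×10⁻⁵ AU) plus 0.4 % relative area jitter.  Batch
profiles perturb areas multiplicatively: conforming ≤ ±3 %, moderate
deviation ~±15 % on eight peaks, and expired-like raising most peaks by
~+35 % while dropping four (the degradation pattern of an aged lot) by
~−20 %.  Truth records carry the analytic areas actually synthesized —
numerical integration never enters the truth side.

What the generator does *not* emulate: retention-time drift between runs,
asymmetric (tailing) peak shapes, heteroscedastic or correlated detector
noise, gradient-dependent baseline shapes beyond the smooth drift, and
inter-day effects.  Passing tests therefore demonstrate correctness of
the algorithms under the assay's nominal structure, not robustness to
instrument drift; the matching tolerance and the validation machinery
exist for those effects but are exercised only synthetically.

## Problem sizes and numerical choices

The pipeline estimates the baseline at full resolution and decimates the
corrected trace to ~3000 points for the nonlinear fit (areas are analytic,
so integration accuracy does not depend on the fit grid).  The full
synthetic campaign (5 calibration + 6 batch traces) runs in ~10 s; the
seeded end-to-end recovery study uses 50 independent seeds of a
6-trace assay each.  Solver tolerances: Whittaker systems are solved
exactly (sparse direct); peak fits use `ftol = 1e-10` (1e-9 for
warm-started refits) with an iteration cap per auto-add cycle and a
tighter final refit.  Ties in the desirability grid break in row-major
order; SIMPLS truncates with a warning on rank deficiency; bootstrap
resamples that collapse to a single row are skipped with a warning.

## Known limitations

- The baseline estimator's flank undershoot (~2 % of a peak's height)
  biases absolute areas of peaks adjacent to dominant ones; quantitation
  is unaffected because the bias is concentration-proportional, but
  absolute area comparisons across very different profiles should allow
  for it.
- Severely overlapped peaks (Rs ≲ 0.7) may exchange area between
  neighbours; the deconvolution assumes the Gaussian shape is exact.
- The jack-knife interval assumes the leave-one-out coefficient sets are
  exchangeable; with only five calibration samples the intervals are
  indicative, not exact.
- `similarity_battery` requires strictly positive vectors (ratio data);
  measures on probability simplices (Hellinger, Kullback) are undefined
  at zero entries, so exactly-zero areas must be excluded upstream.
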