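# Methods

## The hierarchical model

`erpglm` analyses epoched multichannel evoked responses with a two-level
mass-univariate general linear model.

**Level 1 (within subject).** For each electrode, the trials x frames
data slice Y is modelled as Y = XB + E, where X is a single-trial design
matrix with one 0/1 indicator column per experimental condition, optional
(mean-centred) trial covariates, and a constant. Because every condition
gets its own column alongside the constant, X is rank deficient by
construction; B is estimated with the Moore–Penrose pseudoinverse,
B = pinv(X) Y, fitting all frames of one electrode at once. The
minimum-norm solution is not unique in the parameters, but every
*estimable* contrast c'B — any c in the row space of X — is unique, and
the associated T and F statistics are identical to those of a full-rank
reparameterization solved with a standard inverse. This equivalence is
asserted against an independent full-rank oracle in the test suite
(tolerance 1e-10). Estimability is checked by projecting c onto the row
space of X with tolerance 1e-10·max(‖c‖, 1). Error degrees of freedom
are dfe = trials − rank(X), and MSE = SSE/dfe.

**Level 2 (across subjects).** Per-subject beta (or contrast) maps are
stacked and analysed with robust bootstrap tests. All resampling draws
*whole subject maps*: each bootstrap iteration draws one subject-index
vector that is reused at every channel/frame cell. This preserves the
spatio-temporal dependence structure of the maps, which is what makes the
resampled maps valid inputs for the cluster-level corrections.

## Second-level tests

- **One-sample bootstrap-t.** Observed T = mean/(s/√n). The pivot
  T\*_b = (mean\*_b − mean)/(s\*_b/√n) is computed for each draw; the CI is
  [mean − T\*₍U₎·s/√n, mean − T\*₍L₎·s/√n] with L = round(αB/2) (half away
  from zero) and U = B − L, positions taken 1-based in the sorted pivot
  vector. The two-sided p doubles the smaller tail proportion of the
  pivot distribution at the observed T, clipped to [1/B, 1]. Doubling is
  a package decision: it makes the p-value decision agree with the CI
  decision at the same α.
- **Two-sample / paired percentile bootstrap.** Groups are resampled
  independently (pairs jointly for the paired test); the CI on the mean
  difference is [D₍L+1₎, D₍U₎] of the sorted bootstrap differences, and
  significance is the CI excluding zero. The accompanying parametric
  statistic is always Welch's t with Satterthwaite degrees of freedom —
  variance homogeneity is never assumed. Joint pair resampling makes the
  paired test algebraically identical to a percentile one-sample
  bootstrap of the subject-wise differences under the same draws (tested).
- **Percentile-bootstrap regression.** Subject maps and predictor rows
  are resampled jointly. For a simple regression the default is B = 599
  with sample-size-dependent interval positions (a, c): a = 6/7/10/13/15
  for n < 40/80/180/250/∞ and c = 599 − a (Wilcox's modified percentile
  bootstrap). For k > 1 regressors a Bonferroni-style rule applies:
  a = round(αB/(2k)), c = B − a. No p-value is produced; a slope is
  significant iff its CI excludes zero.
- **Trimmed means.** The 20% trimmed mean drops floor(0.2n) values at
  each end; its CI is estimate ± z₁₋α/₂ · SE_boot, with SE_boot the SD of
  the bootstrap trimmed means.
- **ANOVA family.** Between-subject ANOVA is plain OLS. Repeated
  measures use Hotelling's T² on k−1 successive-difference scores
  (T² = n·d̄'S⁻¹d̄, F = T²(n−k+1)/((n−1)(k−1))), which bypasses the
  sphericity assumption; any full-rank contrast gives the same T²
  (asserted). Within-by-between interactions use the Hotelling–Lawley
  trace U = tr(E⁻¹H) on the difference scores with the standard F
  approximation F = 2(sn'+1)U/(s²(2m+s+1)), df (s(2m+s+1), 2(sn'+1)),
  s = min(p, g−1), m = (|p−g+1|−1)/2, n' = (N−g−p−1)/2; exact whenever
  s = 1 (two groups, or k = 2). ANCOVA tests are OLS
  extra-sum-of-squares (partial) F tests against the rank-deficient
  group coding.
- **ANOVA p-values** come from an H0 bootstrap: every design cell
  (group and/or condition) is mean-centred, subjects are resampled with
  replacement (keeping repeated-measures tuples together), and
  p = (1 + #{F\* ≥ F_obs})/(B + 1). The add-one estimator is a package
  decision — a counting rule against the upper quantile gives the same
  binary decision at α, but a continuous p is needed for cluster forming
  and reporting. Cell means are asserted to be zero (1e-12, relative)
  before every H0 resample.
- An optional univariate repeated-measures path applies a Huynh–Feldt
  correction using the corrected epsilon formula
  ε̃ = ((n−g+1)(k−1)ε̂ − 2)/((k−1)(n−g−(k−1)ε̂)) on the Greenhouse–Geisser
  ε̂, clipped to [ε̂, 1]. It exists for comparison only; the multivariate
  route is the default and the only one used by the corrections.

## H0 resampling and familywise-error control

Null map streams follow the test's own scheme: one-sample, paired,
two-sample and the ANOVAs centre each cell/group/condition so H0 is
exactly true, then resample subjects; regression and ANCOVA resample the
data rows against the *original* design matrix, breaking the data–design
link. One index draw produces one entire channels x frames map.

Three corrections consume the stream (t statistics are squared first, so
everything lives in F space; effect direction is read from the sign of
the difference map):

1. **Max statistic** — the empirical (1−α) quantile (1-based position
   ceil((1−α)B)) of the per-resample maximum over all cells is the height
   threshold.
2. **Spatio-temporal cluster sum** — cells with parametric uncorrected
   p < 0.05 (the forming threshold; configurable) are clustered: two
   cells connect iff same channel and adjacent frames, or same frame and
   graph-adjacent channels. The diagonal (both adjacent) is excluded by
   default (configurable). A cluster is significant iff its sum of F
   values reaches the (1−α) quantile of the per-resample maximum cluster
   sums; its corrected p is the add-one proportion of null maxima at or
   above its sum. A resample with no suprathreshold cells contributes 0.
3. **Temporal cluster sum** — clusters are per-channel runs in time; each
   resample contributes the largest run sum over all channels. With an
   edgeless neighbourhood graph this coincides exactly with method 2
   (asserted).

The forming threshold is parametric (the test's reference distribution)
on both the observed and the null maps, keeping formation symmetric. A
bootstrap-derived forming threshold can be supplied through the
`null_masks` argument.

## The synthetic generator

`SimulationSpec` emulates a face-discrimination-style recording at desk
scale: components are Gaussian temporal windows (latency, width in ms)
times a spatial channel-weight vector, with amplitude
(base + condition offset + slope·trial covariate); noise is Gaussian with
lag-one spatial correlation across the channel axis (AR(1) filter, unit
marginal variance, scaled by `noise_sd`). Defaults: 8 channels, 50 frames
at 250 Hz, one component at 170 ms (width 25 ms, amplitude 5) peaking
mid-array, noise SD 5, spatial correlation 0.6 — amplitudes on a
microvolt-like scale with single-trial SNR well below 1, as in real ERP
data. `generate_group_dataset` runs the full two-level path: per-subject
trial designs (two conditions, one uniform trial covariate), subject
covariate slopes drawn as fixed effect + N(0, between-subject SD), then
level-1 fits.

What the generator does **not** emulate: temporal noise autocorrelation
(1/f background), realistic electrode geometry (the spatial correlation
is a 1-D chain), artifacts, or trial-to-trial latency jitter. Passing
tests therefore show the estimators and resampling schemes are correct
under controlled dependence, not that real recordings meet their
assumptions.

## The type-I-error harness

The harness measures the familywise error of cluster-corrected
two-sample trial tests under a true null. A pool of 1000 synthetic null
trials (8 channels x 50 frames, shared evoked template plus correlated
noise) stands in for a recording session; per simulation, two fake
conditions of 100 trials are drawn with replacement from the pool. Three
nulls are compared, each with 1000 resamples: random partitioning of the
pooled 200 trials (permutation), with-replacement sampling of the pooled
trials (bootstrap), and independent per-group resampling after mean
centring (centered bootstrap). Every resample computes Welch's t per
cell, squares it, forms spatio-temporal clusters at parametric p < .05,
and records the maximum cluster sum; the original comparison's largest
cluster is tested against the 95th percentile of those maxima. The FWER
is the proportion of 200 simulations with any significant cluster. At
these sizes the run takes a few minutes on one CPU; `scripts/acceptance.py`
reproduces it from a seed.

## Numerical choices

- Rounding of quantile positions is half away from zero throughout.
- Cells with zero residual variance (perfect fits, constant maps) are
  flagged `degenerate`; T/F are reported as 0 (no effect) or the p floor
  (nonzero effect at zero error), never NaN. Zero-variance detection is
  relative (SSE ≤ 1e-24 · scale).
- Bootstrap index draws in which all entries name the same subject are
  redrawn (at most 100 times, then an error); residual per-cell
  zero-variance draws yield a pivot of 0.
- Singular difference-score covariances are an error for observed
  statistics (with the exception of an exactly zero mean difference,
  where T² = 0) and fall back to the pseudoinverse inside bootstrap
  draws.
- R² ties in optimized-electrode selection go to the lowest channel
  index, with a logged warning.
- All randomness flows from one `numpy` Generator per call; fixed seed
  implies bit-identical output.

## Known limitations

- The centred bootstrap-t null has heavier tails than the true sampling
  distribution of t at small subject counts; the max-statistic and
  cluster corrections are therefore *conservative* for group-level
  analyses with n ≲ 20 subjects (measured in the test suite: near-nominal
  max-statistic FWER by n ≈ 40, cluster FWER ~0.01–0.02 at that n).
  Near-nominal familywise error is a large-sample property and is
  verified at the trial level (100 trials per condition) by the harness.
- Level 1 treats every condition independently (one-way coding); factorial
  variance pooling and weighted least squares are out of scope, as are
  M-estimators beyond the 20% trimmed mean, TFCE and FDR control.
- Unbalanced repeated-measures designs with missing cells are not
  supported.
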