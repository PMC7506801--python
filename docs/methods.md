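# Methods

## Model and algorithms

### NIPALS PLSR

Single-response PLSR is fitted by NIPALS on column-centered data (no
variance scaling inside the core — scaling is an explicit, separate step).
For one response the inner loop is closed form: with the current response
residual u, each component computes w = Xᵀu/‖Xᵀu‖, scores v = Xw, loadings
p = Xᵀv/vᵀv, response loading q = uᵀv/vᵀv, then deflates X ← X − vpᵀ and
u ← u − qv. The regression vector is b = W(PᵀW)⁻¹q; the equivalent
score-space expression b = XᵀU(VᵀXXᵀU)⁻¹Vᵀy (U the matrix of response
residuals entering each component) is implemented behind
`regression_vector(form="direct")` and agrees to numerical precision — the
identity follows from XᵀU ∝ W columnwise and VᵀX = (VᵀV)Pᵀ. Coefficients
of all nested sub-models are kept (`coef_path_`) so one fit serves a whole
RMSEP curve.

Degenerate inputs: a numerically zero deflated X stops extraction with a
warning and a truncated model; a zero-norm weight vector while X still
carries variation raises `DegenerateComponentError` naming the component.
The orthogonality of scores, conservation of SSX under deflation and
agreement with an independent NIPALS implementation are asserted in the
test suite.

### OPLS

For a single response the predictive direction is w ∝ Xᵀy. Each orthogonal
component takes the current loading p, removes the predictive part
(w_o = p − (wᵀp)w, normalised), and deflates X by t_o p_oᵀ where
t_o = Xw_o. Because w_o ⊥ w, the orthogonal scores have exactly zero
sample correlation with y, and Xᵀy is unchanged by the deflation. After
`n_orthogonal` such components, `n_predictive` ordinary NIPALS components
are fitted on the filtered matrix; with `n_orthogonal=0` the model is
identical to plain PLSR. Per-component explained sums of squares are
recorded as SSX_g = ‖v_g p_gᵀ‖²_F and SSY_g = the reduction of the response
residual sum of squares at that component (zero for orthogonal components
by construction, up to rounding); the cumulative values sum over both
blocks.

### VIP scores

Classical VIP: VIP_j = √( m · Σ_g v_gj² SSY_g / Σ_g SSY_g ) with v_g the
unit-norm weights, so Σ_j VIP_j² = m. The conventional relevance reading is
score > 1 relevant, < 0.5 irrelevant, with strict inequalities (values in
[0.5, 1] are "intermediate").

OPLS-VIP weights the squared normalised weights of each block by the
explained SS of both X and y: the predictive score is
(m/2)(Σ v² SSX_g/SSX_cum + Σ v² SSY_g/SSY_cum), the orthogonal score the
same over orthogonal components with factor m_o/2, and the total score
combines all four sums with factor M/2. The published definition of the
effective counts m, m_o, M is circular, so this package uses a documented
fallback: m is the number of predictors, m_o = m when at least one
orthogonal component exists and 0 otherwise, M = m + m_o. Consequences: the
total score reduces exactly to the predictive score when no orthogonal
components exist, and the scores are reported on the printed (not
square-root) scale. Since the scores enter the pipeline only as diagonal
scaling factors, any common constant in these counts is immaterial: scaling
every column by one positive constant leaves centered PLS predictions
unchanged (asserted in the tests).

### MCUVE and the robust cut-off

Artificial noise columns — uniform(0, 1) values scaled by 1e-10, one per
real variable by default, the classical UVE convention — are appended to
the predictor matrix. r sub-models (default r = 500, each on a random 80%
subsample without replacement) yield an r × (m + m_artif) coefficient
record; the reliability of a column is c_j = mean(b_j)/sd(b_j) with the
(r−1)-denominator standard deviation. Reliability is scale-invariant, so
the tiny amplitude keeps the noise block harmless to the fit while its
reliabilities remain a valid null reference. A column whose coefficient
never varies (sd = 0) is flagged degenerate and reported as maximally
reliable (±∞); an all-zero column therefore surfaces explicitly rather than
silently.

Cut-offs on the artificial reliabilities:

* classical: max_j |c_artif,j|; a real variable with |c_j| below it is
  uninformative. Breakdown point 1/m_artif — one unstable noise column
  determines it.
* robust: median(c_artif) + k · MAD(c_artif) with k the one-sided normal
  tolerance factor k = (z_γ + √(z_γ² − a·b))/a, a = 1 − z_α²/(2(r−1)),
  b = z_γ² − z_α²/r. Defaults γ = 0.95, α = 0.05. The closed form agrees
  with the exact noncentral-t construction within 2% at r = 500 and tends
  to z_γ as r → ∞ (both asserted). Classification under the robust rule
  uses the signed reliability c_j > cut-off, as the procedure defines it;
  the classical rule uses |c_j|.

The MAD carries the 1.4826 normal-consistency factor by default so that
median + k·MAD mimics mean + k·sd under Gaussian reliabilities
(`mad_scale="raw"` disables it). Sub-models use a fixed component count per
run — by default the CV-selected count on the full (scaled) matrix — rather
than re-selecting per resample, for tractability.

Robustness caveat, quantified in the tests: when gross outliers contaminate
the *tails* of the artificial reliabilities (where spurious noise
reliabilities occur and where the classical maximum rule is anchored), the
robust cut-off is essentially unchanged while the classical one is driven
to the outlier value. When outliers instead replace values at random
positions, the MAD itself inflates — asymptotically by ~13% at 10%
contamination, since the MAD becomes the 0.5/(1−ε) quantile of the clean
part — so "unchanged" should be read as "bounded and dominated by the clean
bulk", not "numerically identical".

### The pipeline

Step 1 fits OPLS on the raw (uncentered-in-advance, internally centered)
predictors with 1 predictive and 3 orthogonal components by default — one
predictive direction is the single-response OPLS convention; three
orthogonal components let the total score see several dimensions of
response-orthogonal variation, as is typical of spectral data, and the
score is insensitive to more. X̃ = X · diag(VIP_total). Step 2 runs MCUVE
with the robust cut-off on X̃ (noise columns are appended after scaling so
they stay uninformative). Step 3 rescales cumulatively,
X̃* = X̃ · diag(|c_j|) — reliabilities are signed, Ω must be non-negative —
and fits the final PLSR with the CV-selected component count.
`step3="from_raw"` rescales the raw X instead. If every combined factor is
zero the fit aborts with an error advising a threshold review rather than
returning an empty model.

Comparator methods ("vip", "mcuve") are input-scaling analogues: the
classical VIP scores or classical-cut-off MCUVE reliability magnitudes
become the diagonal factors. Hard selection (zeroing factors below the
method's cut) is available behind `hard_selection=True`; soft scaling is
the default, matching the input-scaling framing of the procedure. "plsr" is
auto-scaled classical PLSR (columns centered and divided by the ddof-1
standard deviation).

## Cross-validation and metrics

Component counts are selected on the pooled out-of-fold RMSEP curve from
shuffled k-fold CV (default 10 folds; one NIPALS fit per fold covers all
nested counts). Two rules are available: `abs_minimum` (global minimum,
smallest count on ties) and `one_se` (smallest count within one standard
error — across folds — of the minimum). The library default is `one_se`;
the simulation study uses `abs_minimum`, the global-minimum rule the
benchmark describes.

Metrics: RMSE = √(Σe²/n); R² = squared Pearson correlation between
reference and predicted (kept in [0, 1] regardless of basis);
RPD = sd(reference)/RMSE; SE = ddof-1 standard deviation of the residuals
(SEP), satisfying SE² = n/(n−1) · (RMSE² − mean(e)²). Two evaluation bases
are computed for every benchmark repetition: *CV-pooled* (out-of-fold
predictions at the selected count — honest prediction error) and *refit*
(the model refitted on all samples at that count — a fit statistic). The
study summary reports the refit basis, which is the basis whose magnitudes
match the published benchmark table; the CV-pooled values are retained
per-repetition alongside.

## Synthetic data generator

Each scenario (n, m, IV) draws m_o observable covariates uniform on (1, 10)
and m_e = ⌊(m − n_iv)/2⌋ artificial-noise covariates uniform on (5, 20),
adds N(0, 1) noise elementwise, picks n_iv = round(IV·m) important columns
(ties rounded up) without replacement among the observable ones, draws
their coefficients uniform on (0, 7), and sets y = X[:, iv]·b + e₀ with
e₀ ~ N(0, 1). The response is generated from the noisy observed X, so y is
exactly linear in the recorded predictors and the attainable RMSE floor is
the response noise sd. All bounds and sds are exposed in
`SimulationConfig`; coefficients are redrawn every repetition. Repetition
seeds derive deterministically from the base seed, and all four methods see
the identical dataset and fold assignment within a repetition.

What the generator emulates — and what it does not: it reproduces the
dimensionality, the informative/uninformative split and the noise structure
of the benchmark design, but *not* real NIR physics: no wavelength
autocorrelation, no multiplicative scatter, no baseline drift, no
band-shaped signals. Passing benchmarks here show that the selection
machinery recovers sparse linear structure under these conditions; they do
not by themselves certify performance on instrument spectra.

Known deviation: the published benchmark's RMSE/RPD magnitudes imply a
response standard deviation larger than these distributions generate (and
error levels at large n that exceed what any consistent estimator leaves
when y is exactly linear in the observed predictors with unit noise).
R² values are reproduced within Monte-Carlo tolerance; RMSE values land at
or below the published levels and are compared one-sidedly — a smaller
error is acceptable, a larger one would indicate a defect. The benchmark
summary therefore reports both bases so the comparison is transparent.

## Problem sizes

The shipped study and acceptance script use 200 Monte-Carlo repetitions per
scenario (the published study used 10,000) and r = 500 MCUVE resamples;
at these sizes the full acceptance run takes a few minutes on one CPU and
the scenario means are stable to well within the comparison tolerances.

## Limitations

* Single response only (no PLS2), dense matrices, no sparse or kernel
  variants.
* The orthogonal-component count is a fixed default, not selected by CV.
* Supervised scaling factors are estimated on the full data before
  cross-validation, as the procedure defines them; CV-pooled metrics are
  therefore mildly optimistic for the scaled methods. The shared-fold
  design keeps the comparison between methods fair.
* Spectral pre-treatments (SNV, MSC, derivatives) are out of scope.
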