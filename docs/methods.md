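# Methods

## Activity descriptor

Per-minute activity counts `a` are mapped to 8 states: state 0 for
`a < b₁`, state k for `b_k ≤ a < b_{k+1}` (half-open intervals), and the
top state for `a ≥ b₇`, with `b_k = e^k − 1` (≈ 1.72 … 1095.6).  The edges
are log-spaced because count distributions are heavy-tailed; the top edge
(~1096) sits well below the abnormal-activity exclusion threshold (5000),
so the top state is populated in plausible tracks.

Transition counts are accumulated only **within** maximal runs of
consecutive valid days: invalid days are non-wear, and a pair spanning one
would fabricate a transition that never happened.  The occupancy `N(j)`
counts only minutes that have a successor inside the same segment, so
every visited column of `T_ij = N(j→i)/N(j)` sums to exactly 1.  Columns
of states never visited are set to identity columns (an inert
self-transition): they carry no information, and the descriptor flooring
then maps their off-diagonal zeros to the floor value.

The descriptor is the flattened `T` with entries below `10⁻³` imputed at
`10⁻³` (for a 7-day track this is the resolution of ~10 observed
transitions), then log-transformed.  Flattening is **column-major** —
all destinations of source state 0 first.  Any consistent order would do;
it is fixed so that models trained and applied in different sessions
agree, and the CSV column names (`t_i_j` = destination i, source j) encode
it.

Two inclusion filters precede everything: participants with mean count
below 50 or above 5000 are excluded (boundary values retained — the
abnormal ranges are strict inequalities), and a day is valid only if at
least 200 of its 1440 minutes are in a non-sedentary state (> 0), with at
least 4 valid days required per participant.  Days are consecutive
1440-minute blocks from the start of the track; the source recordings are
aligned to midnight, and block partitioning is device-agnostic, so no
calendar handling is attempted.  The participant-mean filter is computed
on the full track before day filtering.

## Spectral characterization

For the stationary distribution the chain is restricted to the visited
states; if these split into more than one closed communicating class the
chain is reported as reducible (the identity chain is the canonical
example).  Detailed balance is scored as `‖F − Fᵀ‖_F/‖F‖_F` with flux
`F_ij = T_ij π_j`; chains scoring below 0.1 are treated as reversible (the
threshold is exposed in `spectral.DB_TOLERANCE`).

For a reversible chain, the π-symmetrized generator
`S = D^{-1/2} W D^{1/2}` (D = diag π) is symmetric; with `g = D^{1/2} f`
for an observable `f`, the stationary autocovariance is
`C(τ) = Σ_m (gᵀv_m)² e^{−λ_m τ}` over the non-stationary eigenmodes, and
the PSD is the Lorentzian sum `Σ_m c_m·2λ_m/(λ_m²+ω²)`.  The weights sum
to the stationary variance of the observable, and the integral of the
two-sided PSD equals 2π times that variance.  The observable defaults to
the state index: states are log-spaced in counts, so the index is a
log-activity proxy.

Two conventions are provided: `kind="angular"` (two-sided density on a
rad/min grid — the closed form above) and `kind="cyclic"` (one-sided
density on a cycles/min grid, `2×` the angular form at `ω = 2πf`, directly
comparable to a Welch estimate).  The Welch estimator for per-minute
series uses 1024-sample segments, Hann taper, 50% overlap.

The Lorentzian form treats the chain as continuous-time; a sampled chain
actually relaxes at `−ln(1−λ)` per minute rather than `λ`.  The
discrepancy is ~1% for the slow mode that dominates the low band but grows
for fast modes, so reconstruction–Welch agreement is asserted on the
low-frequency band (periods ≥ 20 minutes), where it holds within ~10%
relative L2 at 10⁶ simulated minutes.

## Cross-device harmonization

Raw magnitude signals (tri-axial input is reduced by the Euclidean norm)
are split into 1-minute slices; each slice becomes
`ln(Σ Welch PSD)` (512-point Hann segments, 50% overlap).  The PSD sum is
floored at `10⁻¹²` before the log; the floor's value is immaterial because
the subsequent quantile normalization is monotone-invariant.  Slices
shorter than one Welch segment are flagged missing (NaN).

Reference cohorts on both devices are trimmed of the lowest and highest
**1/6** of participants by mean activity before pooling.  New bin edges
`b′_k` are the empirical quantiles of the pooled per-minute values at the
cumulative reference occupancy fractions, computed on pooled values rather
than per participant.  Discretizing with `b′_k` reproduces the reference
occupancies up to sampling error, and because quantiles commute with
strictly increasing transforms (up to interpolation inside an
order-statistic gap that contains no data), the state assignment is
invariant under shift, scaling, and monotone nonlinear distortion of the
device values.

## Biological age

PCA is computed on the descriptor covariance matrix (no per-variable
standardization — the descriptors already share the log scale), on
participants aged ≥ 40, where mortality grows exponentially and the score
drifts linearly.  The first loading's sign is fixed by requiring a
non-negative score–age correlation on the training set; PCA itself leaves
the sign free.  BAA is the OLS residual of the score on age and gender
(the alternative — subtracting binned age/gender-cohort means — is
available as a diagnostic through `BAAResult.bin_means`).  Gender is
encoded 0/1; residuals are invariant to which label is 1.

`variance_by_age` removes each age bin's own linear age trend before
taking the variance and places the bin at its members' mean age.  Both
choices matter: the aging drift across a bin's width otherwise leaks into
the spread (more so in wide bins), and edge bins may cover only part of
their nominal range.  With them, the slope of variance vs age is stable
(< 20% change when the bin width doubles).

## Hazard models

The ridge Cox objective is the Efron partial log-likelihood minus
`(λ/2)‖β‖²`, maximized by L-BFGS with the analytic gradient.  Efron tie
handling is the default because follow-up is recorded at yearly
resolution, making ties certain.  The penalty family is L2: all 64
descriptor coordinates are jointly meaningful and no sparsity is sought.
Covariates are centred and scaled to unit variance before penalization
(the penalty is otherwise scale-dependent; λ = 0.01 refers to the
standardized scale) and coefficients are mapped back.  Age is deliberately
not a covariate, so the linear predictor acts as a log-scaled biological
age rather than a recalibrated chronological age.  Zero-variance columns
are left with zero coefficients.

The Cox–Gompertz likelihood

    logL = Σ (M₀/Γ)·e^(Γt_i)·(1 − e^(ΓΔt_i)) + Σ δ_i(ln M₀ + Γt_i + ΓΔt_i)

is maximized over `(ln M₀, ln Γ)` (enforcing positivity) by bounded
L-BFGS-B from three starts, inside the box `M₀ ∈ [e⁻³⁰, 1]/yr`,
`Γ ∈ [e⁻⁷, 1]/yr` — generous for any human-like mortality while keeping
`e^(Γt)` finite during line searches.  The censored term is exactly minus
the integrated hazard over `[t, t+Δt]` (cross-checked by quadrature).
Standard errors come from the numerical curvature at the optimum, mapped
back from the log scale.  With no events the likelihood is unbounded
toward `M₀ → 0` and the fit refuses to run.

Association tests detrend the score by age and gender first, standardize
it, and enter it into an unpenalized Cox model together with age and
gender (via lifelines).  Hazard ratios are reported **per standard
deviation** of the detrended score, a unit that is comparable across
scores with arbitrary scales.  Group comparisons report median ± S.E.M.
per group with two-sided Mann–Whitney pairwise tests.

## Synthetic cohort generator

The generator's purpose is to emulate the statistical structure the
analysis assumes, with effect sizes chosen once as plausible for
population accelerometry:

- **Activity dynamics.** Per participant, a birth–death chain over the 8
  states with Metropolis rates against a discrete-Gaussian stationary
  bump (peak state 4.0, width 1.8 at reference bioage 40).  Adjacent-only
  jumps balanced against the target distribution give *exact* detailed
  balance and a real spectrum by construction.  The attempt rate is 0.15
  /min at bioage 40 and multiplies by `e^{0.012·(bioage−40)}`, so the
  slowest relaxation rate rises strictly with bioage (≈ 0.042/min at 40,
  0.068/min at 80 — relaxation times of tens of minutes); the stationary
  peak slides down by 0.02 states/yr, so mean activity falls strictly
  (mean count ≈ 272 at bioage 40, ≈ 158 at 80 — inside the 50–5000
  inclusion band across the whole configured range).  A rate high enough
  to push a one-minute exit probability past 1 is rejected.
- **Counts within a state** are log-uniform over the state's count bin
  (top state capped at `e⁸ − 1`): states are log-spaced, so this keeps
  log-count roughly uniform within bins.
- **Biological age.** `bioage = age + N(0, 0.5·(age−40)₊) + 3·[current
  smoker]` years.  The diffusion constant 0.5 yr²/yr produces the linear
  growth of score variance with age; the +3-year shift for current (not
  former) smokers builds in a reversible lifestyle effect of realistic
  size.
- **Survival.** Hazard `M₀·e^(Γ·age)·e^(β·BAA)` with `M₀ = 5×10⁻⁵`/yr,
  `Γ = 0.085`/yr (human-like: doubling time ≈ 8 yr, mid-life hazards of
  0.2–6%/yr across ages 40–85), `β = 0.14` per year of BAA (≈ 1.6 hazard
  ratio per SD of BAA at the cohort's mean age), administrative censoring
  at 9 years.  Event times come from inverting the cumulative hazard
  against Exp(1) draws.  Morbidity is an independent draw with a 3×
  baseline (disease incidence outpaces mortality).  No competing risks.
- **Raw device signal.** Per-minute Gaussian bursts with standard
  deviation `0.05·√(count + 0.01)` at 10 Hz — the variance (hence the
  log-PSD-sum) is strictly increasing in the count.  10 Hz keeps a
  one-minute slice (600 samples) longer than the 512-point Welch segment
  while staying cheap; the harmonization path is invariant to the actual
  rate as long as that holds.
- **Seeding.** A master seed drives cohort-level draws; per-participant
  track and raw-signal streams are keyed by `(seed + index, stream)` so
  generation is reproducible participant by participant.

What the generator does **not** emulate: circadian structure, non-wear
patterns, device noise spectra beyond the monotone power link, competing
risks, or any real-data covariance between descriptor coordinates beyond
what the chain family induces.  Passing tests therefore demonstrate the
correctness and calibration of the estimators under the assumed structure,
not the field performance of the models on real cohorts.

## Problem sizes and numerical tolerances

Tests and the acceptance script use: 10⁶-minute tracks for estimator
convergence (sup-norm < 0.01 on `T`, occupancy < 0.01), cohorts of 2000
(biological age), 5000 (ridge recovery, correlation > 0.9), 20000
(Gompertz recovery, |Γ̂ − 0.085| < 0.005), 20 participants × 4 days for the
harmonization bridge (occupancy error < 0.01, mean |ΔT| < 0.05), and 500
replicates of n = 500 for the null calibration of the association test
(94–96% observed coverage of HR = 1).  Optimizer tolerances: ridge Cox
L-BFGS `gtol 1e-8`; Gompertz `gtol 1e-10` with agreement across starts to
1e-5 in Γ.  The ridge fit declares non-convergence rather than returning a
poor optimum.

## Known limitations

- The Lorentzian PSD reconstruction is a continuous-time approximation of
  a sampled chain; it is quantitatively reliable only below ~0.05
  cycles/min (see above).
- The PCA biological age is identified up to the synthetic cohort's
  structure; on real data the age–score correlation is expected to be far
  lower than the ≈ 0.96 seen here, because real descriptors carry
  non-aging variance the generator does not model.
- Hazard-ratio estimates for a model evaluated on its own training cohort
  (e.g. the pipeline's LogMort row) are optimistic; use a held-out or
  independently simulated cohort for honest effect sizes.
- `read_tracks` loads everything into memory; cohorts of ~10⁵ week-long
  tracks should be processed in batches.
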