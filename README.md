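# locoage

Biological age and mortality-risk models built from wearable locomotor
activity records.

## The problem

Week-long accelerometer tracks — per-minute "activity counts" from
hip-worn monitors, or 100 Hz tri-axial acceleration from wrist-worn
devices — carry far more information about an organism's physiological
state than the average activity level alone.  `locoage` turns each track
into a compact dynamical descriptor, derives an unsupervised biological
age from it, and links the result to mortality and morbidity.  It is aimed
at biostatisticians and epidemiologists working with population
accelerometry cohorts, and at methodologists who need a fully synthetic,
reproducible test bed for such analyses.

## The model

1. **Markov descriptor.** Per-minute counts are discretized into 8
   activity states with log-spaced edges `b_k = e^k − 1, k = 1..7`.
   Transitions between consecutive minutes give the column-stochastic
   transition matrix `T_ij = N(j→i)/N(j)` and the generator `W = T − I`.
   The flattened matrix, floored at `10⁻³` and log-scaled, is a
   64-dimensional physiological state vector.
2. **Spectrum.** For a reversible chain the nonzero eigenvalues of `W` are
   inverse relaxation times, and the power spectral density of any state
   observable is a sum of Lorentzians `PSD(ω) = Σ c_m·2λ_m/(λ_m²+ω²)`.
   The slowest rate λ_min sets the PSD's crossover frequency and rises
   with age — older subjects lose long-time activity correlations.
3. **Biological age.** PCA of the descriptors (age ≥ 40) yields a first
   principal component score, PC₁, oriented to grow with chronological
   age: the biological age.  Its OLS residual on age and gender is the
   biological age acceleration (BAA).
4. **Hazard models.** A ridge-penalized Cox model (Efron ties, penalty
   `(λ/2)‖β‖²` with λ = 0.01) on the 65 covariates (64 descriptor elements
   + gender, no age) gives a supervised log-hazard score ("LogMort" /
   "LogMorb").  A parametric Cox–Gompertz likelihood fits the mortality
   law `μ(t) = M₀·e^(Γt)`; `ln 2/Γ` is the mortality-rate doubling time.
5. **Harmonization.** High-frequency tracks are downsampled to per-minute
   log-summed Welch PSD values and quantile-normalized so that their
   activity-state occupancy fractions match a reference cohort's, making
   descriptors comparable across devices.
6. **Synthetic cohorts.** A generator produces participants with
   age-parameterized reversible birth–death activity chains, linearly
   growing biological-age variance, and Gompertz survival modulated by the
   true BAA — so every stage above is testable without restricted data.

## Worked example

```python
import numpy as np
from locoage import (simulate_cohort, fit_pca, project, detrend, assoc_test,
                     fit_cox_gompertz, doubling_time, DiscretizationScheme)
from locoage.markov import descriptor_names
from locoage.pipeline import _descriptor_frame

cohort, tracks = simulate_cohort(1000, seed=42)           # 7-day tracks
df = _descriptor_frame(tracks, DiscretizationScheme())    # 64-dim descriptors
X = df[descriptor_names()].to_numpy()
meta = cohort.set_index("participant_id").loc[df["participant_id"]]
ages, genders = meta["age"].to_numpy(), meta["gender"].to_numpy()

model = fit_pca(X, ages, genders)                         # biological age model
pc1 = project(model, X)
print(f"corr(PC1, age)        = {np.corrcoef(pc1, ages)[0,1]:.2f}")

r = assoc_test(pc1, ages, genders,                        # age/gender-adjusted
               meta["followup_years"].to_numpy(),         # Cox association
               meta["delta_death"].to_numpy())
print(f"BAA mortality HR/SD   = {r.hr:.2f} (95% CI {r.ci_low:.2f}-{r.ci_high:.2f}), "
      f"p = {r.p:.1e}, events = {r.events}")

g = fit_cox_gompertz(ages, meta["followup_years"].to_numpy(),
                     meta["delta_death"].to_numpy())
print(f"Gompertz Gamma        = {g.Gamma:.3f}/yr "
      f"(doubling time {doubling_time(g.Gamma):.1f} yr)")
```

Output:

```
corr(PC1, age)        = 0.96
BAA mortality HR/SD   = 1.60 (95% CI 1.44-1.79), p = 3.0e-17, events = 237
Gompertz Gamma        = 0.095/yr (doubling time 7.3 yr)
```

The biological age tracks chronological age strongly on this synthetic
cohort; participants biologically older than their age- and gender-matched
peers die at a ~1.6× higher rate per standard deviation of BAA; and the
cohort's mortality follows a Gompertz law with a doubling time near the
canonical 8 years (the fitted Γ fluctuates with the seed around the
generating value 0.085/yr).

The same flow is available from the shell:

```bash
locoage run-all --out results/   # simulate → descriptors → bioage → hazards
locoage simulate --n 100 --seed 1 --out data/
locoage filter --tracks data/tracks.csv --out filtered/
```

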