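# Methods

`adhesiokin` models the time evolution of single-nanoparticle–cell adhesion
forces: a particle is placed on a live cell membrane, left for a contact
time *t* (minutes), and the piconewton extraction force needed to detach it
is recorded. This note documents the models, the numerical choices, the
synthetic-data generator, and what the validation studies do and do not
establish.

## The viscoelastic backbone

The Standard Linear Solid (SLS) — a spring in parallel with a Maxwell arm —
has the mono-exponential step response

    F(t) = F0 + (Fmax − F0) (1 − exp(−t/τ)),

which we treat as the effective mean adhesion force. `F0` ≥ 0 is the initial
contact force (pN), `Fmax` the adhesion plateau (pN; `Fmax < F0` is allowed
and gives a decaying curve), and `τ` > 0 the characteristic adhesion time
(min). These are *effective* kinetic descriptors of the membrane–cortex
response, not direct measurements of any single molecular process.

`fit_sls` minimizes the sum of squared residuals over all replicate-level
observations (never per-time means) with `scipy.optimize.least_squares`
under bounds `F0 ∈ [0, max F]`, `Fmax ∈ [0, 3 max F]`, `τ ∈ [0.05, 100]`
min. Exponential fits have local minima, so the solver is restarted from a
fixed 4×4×4 grid (force range × force range × τ ∈ {0.5, 2, 5, 10} min) and
the best optimum kept; the procedure is deterministic and invariant to
observation order. Degenerate inputs (all forces equal) return
`F0 = Fmax = value`, `τ = 1` min with an identifiability flag — a valid
prior center rather than an error. A fit pinned to a τ bound also raises
the flag.

## The hybrid model and its training

The hybrid prediction adds a neural correction to the frozen backbone:

    F̂(t) = F_SLS(t; F0*, Fmax*, τ*) + F_NN(t; θ).

`F_NN` is a fully connected MLP — one input (time normalized by the
dataset's largest observed time), two hidden layers of 32 SiLU units, a
linear scalar output. The final layer is zero-initialized, so at epoch 0
the hybrid model *is* the SLS fit exactly; the correction is then always
interpretable as the learned deviation from the deterministic backbone.
Freezing the backbone during training is the default (co-training is
available via `TrainConfig.train_backbone`).

The loss has two terms. The data term is the Smooth-L1 (Huber) mismatch,
quadratic `0.5 r²/β` below the transition `β` and linear `|r| − β/2` above,
averaged over observations; `β` defaults to 1 pN (configurable), keeping
the quadratic zone at sub-noise scale so outlier replicates do not dominate.
The physics term regularizes the correction itself:

    L_phys = 1/Var(F_data) · 1/M · Σ_j [ F_NN(t_j)² + (dF_NN/dt)(t_j)² ],

evaluated at M = 200 collocation times uniform on [0, t_max]. The first
summand keeps the correction small unless the data demand otherwise; the
second suppresses fast oscillations. The variance normalization is computed
once from the training forces before epoch 1 and held fixed, which places
both terms on a commensurate scale from the start. The time derivative is
exact: the network's forward pass propagates a tangent (dual-number) along
with the value, seeded with 1/t_max so the chain rule through the
normalization yields pN/min. Training the physics term needs gradients of
that derivative with respect to the weights, i.e. backpropagation through
the extended value+tangent graph; this requires SiLU's second derivative
and is implemented analytically (finite differences appear only in tests,
as the independent check).

Fixed weighting sums the two terms. Adaptive weighting optimizes

    L = e^(−s_d) L_data + e^(−s_p) L_phys + s_d + s_p

over the log-variances `s_d, s_p` jointly with the weights — the
multi-task uncertainty weighting in which each term's optimal variance
equals the term's loss (σ² = L at stationarity) and the `+s` penalty
prevents weight collapse. Both log-variances start at 0 (unit weights).
The optimizer is Adam at learning rate 1e-3 for (default) 8000 epochs,
implemented in numpy; runs are bitwise reproducible given the seed, and a
non-finite loss aborts with the epoch named. On the noisy synthetic
conditions the data weight `1/σ_d²` reliably decays (≈1 → 0.3 within 1500
epochs, further at full length) while the physics weight grows — the
adaptive run shifts emphasis toward physical consistency exactly when the
data are noisy, and its corrections are correspondingly smaller than the
fixed-weight run's on data that the backbone already explains.

## The Bayesian stage

Inference on the interpretable kinetics deliberately uses the SLS mean
only — the neural correction never enters the likelihood; the two stages
answer different questions (flexible reconstruction vs parameter
inference). The observation model is a heteroscedastic normal,

    F(t) ~ N(μ(t), σ(t)),   σ(t) = γ_μ μ(t) + γ_σ σ_l(t),

where `γ_μ` scales signal-proportional noise, `γ_σ` scales baseline noise,
and `σ_l(t)` is an empirical local SD: at each distinct observed time, the
SD of observations within ±1 min (window width 2 min, configurable),
linearly interpolated between times, constant beyond, floored at 1 pN;
windows with fewer than two points fall back to the dataset's global SD.
States with σ ≤ 0 anywhere get log-likelihood −∞.

Priors are empirical-Bayes: `Fmax ~ N(Fmax*, 300 pN)`,
`F0 ~ N≥0(F0*, 300 pN)` (zero-truncated), `τ ~ N≥0(τ*, 1 min)`, centers
from the deterministic fit; `γ_μ, γ_σ ~ Half-Cauchy(β = 3)`. The τ prior's
two-argument half-normal form is read as a zero-truncated normal centered
at τ* (a scale-only half-normal is available via `PriorSpec.tau_prior`).
The widths are deliberately broad so the likelihood dominates wherever the
data are informative; the centering mainly initializes the search region.

Sampling uses a No-U-Turn Sampler written for this package: multinomial
sampling over the doubled trajectory, generalized momentum-sum U-turn
criterion with cross-subtree checks, dual-averaged step size targeting 0.9
acceptance, and a dense mass matrix adapted over expanding warmup windows.
Positivity of `F0, τ, γ_μ, γ_σ` is enforced by log transforms with their
Jacobians. A MAP + inverse-Hessian (Laplace) approximation — obtained with
L-BFGS on the analytic gradient — seeds the metric and the per-chain
initial points; it only pre-conditions the sampler and never replaces it.
The default configuration is 4 chains × 500 warmup × 500 draws (2000
posterior samples). Convergence is reported per parameter as
rank-normalized split R̂ and bulk ESS (via `arviz`); divergences beyond 10%
of draws attach a warning. On the synthetic conditions the kinetic
parameters typically reach R̂ ≤ 1.01 and bulk ESS ≈ 700–1500; the noise
scales mix more slowly (heavy-tailed marginals), which matches their role
as nuisance parameters.

The posterior predictive at a time t* is, per draw, a normal truncated
below at zero (negative forces are unphysical). Per-draw truncated-normal
means and variances are analytic (`scipy.stats.truncnorm`); the mixture
mean/SD averages them over draws; the 90% prediction band inverts the
pooled mixture CDF by bisection (deterministic, no resampling); the 95%
credible band is the quantile band of the mean curve μ(t*; θ) across
draws, clipped at zero. The prediction band is the one to compare with
replicate observations; the credible band only bounds the mean curve.

## Evaluation harness

`loo_metrics` refits the supplied model once per held-out observation and
predicts it: LOO-RMSE is the root mean squared held-out residual; LOO-R²
compares held-out squared error with the grand-mean baseline; LOO-LL scores
each held-out point under a normal with SD equal to the pooled LOO-RMSE
(per-fold SDs were considered and rejected for stability at n ≈ 25); the
LOO-R² spread is the jackknife SD over leave-one-out recomputations of R².
Folds whose refit raises are excluded and listed in the report, never
imputed. Coverage counts observations inside the closed band. The prior
sensitivity sweep reruns inference under narrow (50 pN / 0.5 min), original
(300 pN / 1 min) and wide (600 pN / 3 min) prior widths and reports percent
shifts of the posterior means against the original regime (absolute
differences, flagged, if an original mean is zero). Pairwise Pearson
correlations are computed on pooled draws, with zero-variance parameters
reported as undefined.

## Synthetic data

The generator emulates the assay's design: six condition presets with
4–5 independent replicates at adhesion times 2–10 min (fibroblasts also
0.5 min), forces drawn from `N(μ(t), γ_μ μ(t) + γ_σ · baseline_sd)` and
resampled (not clipped) when negative — resampling keeps the sample mean
near the target curve, at the cost of a small upward bias when the mean is
within ~2 SDs of zero. Default noise is `γ_μ = 0.15`, `γ_σ = 1`,
`baseline_sd = 20 pN`, matching the scatter scale of the real assay.
Condition means are the SLS curve plus, where the measured trajectories are
non-monotone, a Gaussian bump in time (the qualitative shapes — overshoot
with late decline, mid-course dip — are reported without a generative
form; a smooth bump is the simplest choice): fibroblast (15, 300, 3.7 min),
MiaPaCa-2 (50, 450, 5.2 min; +215 pN overshoot at 8 min), chlorpromazine
(100, 525, 4.2 min; +300 pN at 8 min), genistein (50, 650, 6 min; −190 pN
dip at 4 min), nocodazole (15, 150, 5.1 min), combination (60, 180,
3.2 min). Replicates are independent; the generator does not model
cell-to-cell correlation, instrument drift, or the magnetic-extraction
physics, so passing tests demonstrate statistical correctness of the
pipeline under its own assumptions, not fidelity to any particular
laboratory's raw data.

## Validation studies and their problem sizes

`adhesiokin.validation` packages the end-to-end studies that
`tests/test_acceptance.py` and `scripts/acceptance.py` run; sizes were
chosen to give stable answers at desk scale.

* **Reduction and identities** — exact checks (zero-output network on a
  1000-point grid; Smooth-L1 branch values; the 32/3 hand-evaluated physics
  sum; adaptive stationarity by 1-D minimization).
* **Derivative check** — tangent vs central differences on 100 random
  networks, 1e-4 relative tolerance.
* **LOO oracle** — `loo_metrics` vs an explicitly coded refit loop on 20
  random datasets, exact equality.
* **Posterior oracle** — a 5-observation dataset at times (0.5, 2, 4, 7,
  10) min, one replicate each, mild noise, with the known baseline SD
  supplied as the sigma curve (the windowed estimator needs ≥2 points per
  window). NUTS (4 × 1000/1000) is compared with dense-grid quadrature of
  the full 5-parameter posterior, 3-MCSE tolerance. The quadrature
  integrates the right-skewed axes (`F0`, both noise scales) on log-spaced
  grids with Jacobians and re-centers the light-tailed axes on its own
  first pass; the 0.5-min point anchors `F0` — without it the `F0` marginal
  grows a tail that neither a grid nor a finite chain pins to ~1 pN.
* **Recovery** — fibroblast kinetics and design, 5 replicates per time,
  mild noise (`γ_μ = 0.03`, baseline 5 pN), full MCMC configuration;
  Fmax and τ recovered within 15%, R̂ ≤ 1.01, bulk ESS ≥ 400. At the full
  study noise the 15% bound is not identifiable from n ≈ 30 observations —
  the deterministic fit itself misses τ by more than that on most
  realizations, consistent with the intrinsically wide τ posteriors this
  assay produces — so the recovery study is defined at mild noise, where
  the bound probes the pipeline rather than the design.
* **Calibration** — 50 train/held-out dataset pairs at full study noise,
  reduced MCMC per fit (2 × 250/250, the fold-level cost driver); pooled
  coverage of the 90% prediction band on held-out observations, expected
  in [0.84, 0.96].
* **Adaptive weighting** — 10 seeds × (adaptive, fixed) at 1500 epochs;
  data-weight decay and correction-magnitude comparison.
* **Prior sensitivity** — a sparse boundary dataset (true τ = 9 min near
  the 10-min window edge, 2 replicates per time) where the wide regime
  pulls the τ posterior upward, and a 50-replicate dataset where
  narrow-to-wide shifts of Fmax and τ collapse below 5%. F0's shift is
  reported in absolute pN: at a true value of ~10 pN, percent shifts
  mostly measure the zero-truncation boundary pull of the prior (a
  fraction of a pN), not a failure of likelihood dominance. Both arms use
  the full chain configuration — percent shifts of small means are
  otherwise dominated by Monte-Carlo error.

## Known limitations

* τ is weakly identified when it approaches the observation window; the
  prior-sensitivity machinery quantifies this rather than hiding it.
* The sliding-window SD needs replicated time points; with single
  replicates it falls back to a global SD that conflates curve variation
  with noise.
* The noise scales `γ_μ, γ_σ` trade off against each other (the likelihood
  constrains mainly their combination), so their marginals are wide and
  heavy-tailed at n ≈ 25; kinetic inferences are insensitive to this.
* The resampling truncation in the generator biases means upward near zero
  force; at the default presets the effect is negligible except for the
  lowest-force condition at early times.
* Training-history weights are recorded pre-update per epoch; the final
  epoch's update is applied to the returned state but not re-logged.
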