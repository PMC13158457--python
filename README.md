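# adhesiokin

Modeling the kinetics of single-nanoparticle–cell adhesion from
piconewton-scale extraction forces.

In single-particle force assays, a magnetic submicroparticle is placed on a
live cell membrane, left to adhere for a controlled contact time (0.5–10
minutes), and then pulled off while the extraction force is recorded. The
resulting force–time data — a handful of replicates per contact time, noisy,
and different for every pharmacological condition — call for models that are
both mechanistically interpretable and honest about uncertainty. `adhesiokin`
implements a three-stage stack for exactly this setting:

1. **Viscoelastic backbone.** The Standard Linear Solid (SLS) step response

   *F(t) = F₀ + (F_max − F₀)(1 − e^(−t/τ))*

   with initial contact force *F₀* (pN), adhesion plateau *F_max* (pN) and
   characteristic adhesion time *τ* (min), fitted by bounded multi-start
   nonlinear least squares.

2. **Hybrid physics-informed network.** A 2×32 SiLU multilayer perceptron
   adds a correction *F_NN(t)* on top of the frozen backbone,
   *F̂(t) = F_SLS(t) + F_NN(t)*. Training minimizes a Smooth-L1 data term
   plus a physics regularizer that penalizes the correction's magnitude and
   time derivative (obtained by automatic differentiation), normalized by the
   empirical force variance. The two loss terms are balanced either with
   fixed unit weights or adaptively through trainable log-variances
   (*e^(−s_d) L_data + e^(−s_p) L_phys + s_d + s_p*), which down-weights
   whichever term carries more uncertainty.

3. **Bayesian stage.** A heteroscedastic normal likelihood over the SLS mean,
   *σ(t) = γ_μ μ(t) + γ_σ σ_l(t)*, with a sliding-window empirical SD curve
   *σ_l(t)*, empirical-Bayes priors centered on the deterministic fit
   (widths 300 pN / 1 min), Half-Cauchy(β=3) priors on the noise scales, and
   posterior sampling by a No-U-Turn Sampler (4 chains × 500 warmup × 500
   draws, target acceptance 0.9) with rank-normalized R̂ and bulk-ESS
   diagnostics. The posterior predictive truncates negative forces
   (truncated-normal mixture; 95% credible and 90% prediction bands).

Around the core sit a synthetic-data generator that emulates the assay's six
experimental conditions (untreated fibroblasts, untreated MiaPaCa-2 cells,
and MiaPaCa-2 under chlorpromazine, genistein, nocodazole, or combined
inhibition), a leave-one-out evaluation harness (LOO-R² ± SD, LOO-LL,
LOO-RMSE), prior-sensitivity sweeps, and posterior correlation reports.

The MLP (with exact backprop and forward-tangent derivatives), the Adam
optimizer and the NUTS sampler (multinomial trajectory sampling, dense mass
adaptation, generalized U-turn criterion) are implemented in numpy inside
the package; `arviz` supplies the convergence diagnostics.

## Worked example

```python
import numpy as np
from adhesiokin import (MCMCConfig, PriorSpec, SimConfig, condition_presets,
                        empirical_sd_curve, fit_sls, posterior_predictive,
                        sample_posterior, simulate_dataset)

data = simulate_dataset(condition_presets()["fibroblast"], SimConfig(seed=1))
fit = fit_sls(data)
print(f"SLS fit: F0={fit.params.F0:.1f} pN, Fmax={fit.params.Fmax:.1f} pN, "
      f"tau={fit.params.tau:.2f} min")

sigma = empirical_sd_curve(data)
post = sample_posterior(data, PriorSpec.from_fit(fit),
                        MCMCConfig(seed=2), sigma_curve=sigma)
for p in ("F0", "Fmax", "tau"):
    d = post.diagnostics[p]
    print(f"{p:>4}: posterior mean {post.mean(p):7.2f}  "
          f"rhat {d['rhat']:.3f}  ess {d['ess_bulk']:.0f}")

pred = posterior_predictive(post, np.linspace(0, 10, 5), sigma)
print("90% prediction band at t=10 min: "
      f"[{pred.pred_lower[-1]:.0f}, {pred.pred_upper[-1]:.0f}] pN")
```

Output:

```
SLS fit: F0=25.4 pN, Fmax=273.9 pN, tau=3.34 min
  F0: posterior mean   29.49  rhat 1.005  ess 639
Fmax: posterior mean  288.17  rhat 1.003  ess 1447
 tau: posterior mean    3.72  rhat 1.000  ess 931
90% prediction band at t=10 min: [226, 315] pN
```

The fitted plateau (~274 pN) and time constant (~3.3 min) sit near the
fibroblast preset's generating values (300 pN, 3.7 min); the posterior means
agree with the deterministic fit while attaching converged uncertainty
(R̂ ≤ 1.01, bulk ESS well above 400), and the 90% band quantifies the spread
expected of a new replicate measurement.

The same pipeline is available from the shell:

```sh
adhesiokin simulate --preset fibroblast --seed 1 --out runs/
adhesiokin fit-sls   --data runs/fibroblast.csv --out runs/
adhesiokin train-pinn --data runs/fibroblast.csv --epochs 8000 --out runs/
adhesiokin fit-bayes --data runs/fibroblast.csv --out runs/
adhesiokin evaluate  --data runs/fibroblast.csv --model sls --out runs/
```

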