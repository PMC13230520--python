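# cfdyn — counterfactual trajectories in noisy, possibly chaotic dynamical systems

`cfdyn` asks a concrete scientific question: **when can you trust a
counterfactual trajectory computed for a dynamical system you only
observe through noise?** It is aimed at modellers in systems biology,
epidemiology, neuroscience and related fields who fit ODE-based
state-space models to noisy time series and are tempted to re-run the
fitted model under a "what if" intervention — e.g. *what if the initial
condition had been slightly different?*

The package implements the full pipeline on classic benchmark systems
(Lorenz, Rössler, logistic growth):

1. **Simulate** a ground-truth state-space model

   $$X_t = F(X_{t-1}, \theta) + U_t, \qquad Y_t = H X_t + W_t,$$

   where $F$ is the RK4-discretized flow of an ODE
   $\dot X = h_\theta(X)$, $U_t \sim \mathcal N(0, \sigma_U I)$ is the
   process noise and $W_t \sim \mathcal N(0, \sigma_W I)$ the
   observation noise.
2. **Infer** hidden states and parameters jointly from $Y_{0:T}$ with a
   *nested particle filter*: an outer population of $M$ parameter
   particles (refreshed by a shrinking jitter kernel and resampled by
   the average inner likelihood) each carrying an inner bootstrap filter
   of $N$ state particles; a forward-filtering backward-smoothing pass
   then conditions the state weights on the whole sequence.
3. **Abduct** the exogenous noise: each particle's residual
   $\mu_t^{(n,m)} = x_t^{(n,m)} - F(x_{t-1}^{(n,m)}, \theta^{(m)})$
   along its ancestral path is pooled with the smoothed weights into a
   per-step Gaussian posterior
   $U_t^{\mathrm{cf}} \sim \mathcal N(\mu_t, \sigma_t)$.
4. **Intervene and predict**: re-solve the structural model from
   $X_0^{\mathrm{cf}} = X_0 + \delta e_j$ with the abducted noise, under
   three levels of parameter knowledge — the true $\theta$, the point
   estimate $\hat\theta$, or draws from
   $\mathcal N(\hat\theta, \sigma_\theta)$.
5. **Score** the sampled counterfactuals against the deterministic
   counterfactual reference with a time-resolved, moving-average
   smoothed $\mathrm{RMSE}_t$, plus a divergence-time summary.

The headline finding this pipeline exposes: for chaotic systems even the
*true-parameter* counterfactual decorrelates from the reference (the
butterfly effect amplifies the abducted-noise uncertainty), and any
parameter uncertainty accelerates the collapse — while a non-chaotic
baseline (logistic growth) stays pinned to its reference.

## Worked example

```python
import numpy as np
import cfdyn as c
from cfdyn.evaluation import run_cell, PipelineSettings

settings = PipelineSettings(T=2000, M=20, N=50, K=50)
rows, ref, curves = run_cell(
    c.get_system("lorenz"), 0.01, 4.0,          # (sigma_u, sigma_w)
    ("true", "point", "posterior"), 0, settings,
)
print("theta_hat =", np.round(rows[0]["theta_hat"], 3))
for r in rows:
    print(f"{r['mode']:>9}: final-window RMSE = {r['final_rmse']:.2f} "
          f"(reference SD = {r['ref_sd']:.2f})")
```

prints

```
theta_hat = [10.575 28.705  2.745]
     true: final-window RMSE = 11.19 (reference SD = 6.88)
    point: final-window RMSE = 11.98 (reference SD = 6.88)
posterior: final-window RMSE = 11.93 (reference SD = 6.88)
```

The filter recovers the Lorenz parameters well — $\hat\theta =
(10.6, 28.7, 2.75)$ against the truth $(10, 28, 8/3)$ — yet in *every*
parameter regime the counterfactual ensemble's terminal error (≈ 11–12)
exceeds the reference trajectory's own standard deviation (≈ 6.9): the
sampled counterfactuals are fully decorrelated from the true
counterfactual. Running the same cell for logistic growth gives a
final-window RMSE of about 0.16 against a reference SD of 0.43 — the
stable system keeps its counterfactuals honest.

The same pipeline is scriptable from a shell:

```bash
cfdyn simulate -c config.yaml -o run/      # hidden.csv, observed.csv
cfdyn infer    -c config.yaml -o run/      # state_mean.csv, theta.json
cfdyn abduct   -c config.yaml -o run/      # noise_posterior.csv
cfdyn counterfactual -c config.yaml -o run/
cfdyn evaluate -c config.yaml -o run/      # rmse.csv
cfdyn grid     -c config.yaml -o run/      # full study design, tidy CSV
```

See `docs/methods.md` for the model details, the tunable parameters,
and the numerical design choices (including which study conditions are
feasible under additive per-step noise and which are not).

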