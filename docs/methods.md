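# Methods

## Model

The object of study is a discrete-time state-space model built over an
ODE. An ODE family is a drift $h_\theta: \mathbb R^d \to \mathbb R^d$
with parameters $\theta \in \mathbb R^p$; the forward operator
$F(\cdot, \theta)$ advances the flow by one model step of $\Delta$ time
units with a fixed-step integrator (RK4 by default, Euler available for
ablation; `substeps` internal steps of size $\Delta/\text{substeps}$).
The generative model is

$$X_t = F(X_{t-1},\theta) + U_t,\qquad Y_t = H X_t + W_t,$$

with $U_t \sim \mathcal N(0, \sigma_U I)$,
$W_t \sim \mathcal N(0, \sigma_W I)$, $H = I$ by default, $X_0$ fixed,
and every step $t = 0..T$ observed. Interpreted as a structural causal
model unrolled over time, the $U_t, W_t$ are the exogenous variables and
the two equations above the structural assignments; a counterfactual is
computed by Pearl's abduction–action–prediction recipe.

Three systems ship in the registry:

| system | $\theta_{\text{true}}$ | uniform prior | $X_0$ | SSM step |
|---|---|---|---|---|
| Lorenz | $(\sigma,\rho,\beta)=(10,28,8/3)$ | $\sigma\!\in\!(5,15),\ \rho\!\in\!(20,35),\ \beta\!\in\!(2,4)$ | $(1,1,1)$ | $\Delta=0.01$ |
| Rössler | $(a,b,c)=(0.2,0.2,5.7)$ | $a,b\!\in\!(0.1,0.3),\ c\!\in\!(4,7)$ | $(1,1,0)$ | $\Delta=0.01$ |
| logistic | $(r,K)=(3.9,1)$ | $r\!\in\!(2,4),\ K\!\in\!(0.8,1.2)$ | $10$ | $\Delta=0.1$, 10 substeps |

Custom systems register through a drift callable (or an explicit
discrete map, used by the linear-Gaussian test system) plus metadata.

## Why the logistic system uses a coarser SSM step

Process noise is injected once per SSM step, as the state equation
says. For a contracting 1-D flow the stationary spread of
$X_t$ around the carrying capacity is
$\sqrt{\sigma_U/(1-e^{-2r\Delta})}$: at $\Delta=0.01$ the per-step
contraction ($r\Delta \approx 0.04$) is so weak that even
$\sigma_U = 0.01$ accumulates to a spread of $\approx 0.37$ around
$K=1$, and the state is knocked below zero — where the logistic flow
blows down in finite time — well before $T=2000$ in every seed. The
logistic system therefore uses $\Delta=0.1$ with 10 RK4 substeps: the
integration accuracy is the same ($h=0.01$) but noise enters at the
system's own relaxation timescale, giving a stationary spread of
$\approx 0.14$ and survival over the full horizon. This is a property
of the additive-per-step noise model, not of the integrator.

Related feasibility facts, measured and asserted in the tests: the
noisy Rössler system escapes its attractor basin (noise can push $z<0$
while $x>c$, an unstable direction) with probability $\approx 0.4$ over
2000 steps even at $\sigma_U = 0.01$; the grid runner therefore redraws
the ground-truth realization (up to 25 derived seeds) until it survives
the horizon — conditioning on basin survival, which is a different
phenomenon from the counterfactual divergence under study. Cells with
$\sigma_U \ge 1$ for Rössler or the logistic system are infeasible
under this model and are recorded as failed cells by the grid runner.
For the same reason the experiment grid's noise pairs
$\{(0.01,4),(0.01,9),(1,2),(4,1)\}$ are read as
$(\sigma_U, \sigma_W)$ — small process noise with large observation
noise is the only reading under which the non-Lorenz systems can be
simulated over the study horizon at all; both orderings remain runnable
through explicit configuration.

## Inference: nested particle filter + backward smoothing

Initialization draws $M$ parameter particles from the uniform prior
$\pi_0$ and, per parameter, $N$ state particles from
$\tau_0 = \mathcal N(Y_0, \sigma_W I)$ (anchoring on the first
observation when $H=I$; otherwise $\mathcal N(x_0^{\text{default}}, I)$).
Step 0 weights and resamples against $Y_0$ without propagation. Each
recursive update then:

1. jitters each $\theta^{(m)}$ with a reflected Gaussian kernel of SD
   $c \cdot (\text{prior width}) / \sqrt M$ per component (default
   $c = 0.05$; the $1/\sqrt M$ shrinkage keeps the jitter below the
   Monte Carlo resolution of the outer population, reflection keeps
   particles inside the prior support);
2. propagates states through $F$ plus fresh process noise;
3. computes inner weights $\propto p(Y_t \mid x_t^{(n,m)})$, normalized
   within each $m$ (log-space arithmetic; a degenerate block falls back
   to uniform with a logged warning);
4. weights each parameter particle by the *mean unnormalized* inner
   likelihood;
5. resamples the outer layer (carrying each parameter's state block)
   and then the inner layer, systematically by default, every step.

Particles whose propagated state is non-finite or exceeds norm $10^6$
receive $-\infty$ log-likelihood and are eliminated at the next
resampling instead of aborting the run — jittered or posterior-drawn
parameters can leave the stable regime.

The backward pass realigns all stored (pre-resampling) slices to the
final-time outer lineage and runs, per parameter block, the standard
forward-filtering backward-smoothing recursion

$$\tilde w_T = w_T,\qquad
\tilde w_t(n) \propto w_t(n) \sum_k \tilde w_{t+1}(k)\,
\frac{f(x_{t+1}^{(k)} \mid x_t^{(n)})}{\sum_l w_t(l) f(x_{t+1}^{(k)} \mid x_t^{(l)})},$$

with $f = \mathcal N(F(x_t, \theta), \sigma_U I)$. The denominator — the
particle predictive density — matters: without it the smoother is
biased, which the Rauch–Tung–Striebel oracle test detects immediately.
Parameters are static, so their smoothed posterior is the final-time
outer posterior, and the joint smoothed weight of particle $(n,m)$ is
$v_T^{(m)} \tilde w_t(n \mid m)$. With $\sigma_U = 0$ the transition
density is degenerate and the smoother falls back to ancestral-path
weights (final-time weights propagated back along the resampling
lineage), with a logged warning. Point estimates are the weighted means;
spreads the weighted (uncorrected) standard deviations.

Cost: the filter is $O(TMN)$; the smoother $O(TMN^2)$ and dominates.
Defaults $M=50, N=100$ suit single runs; the grid pipeline uses
$M=20, N=50$ (the qualitative contrasts it measures are insensitive to
the particle counts at this scale, and 36 cells × 5 seeds must stay at
desk scale).

## Abduction and the counterfactual SCM

Residuals are computed along ancestral paths —
$\mu_t^{(n,m)} = x_t^{(n,m)} - F(x_{t-1}^{(n,m)},\theta^{(m)})$ with
$x_{t-1}$ the actual parent under the recorded resampling lineage — so
the reconstruction identity holds bitwise on every particle. The
abducted posterior is the diagonal Gaussian with
$\mu_t = \sum \tilde w_t^{(n,m)} \mu_t^{(n,m)}$ and componentwise
weighted variance $\sigma_t$ (no Bessel correction). Residuals of
runaway particles (clamped at the divergence guard, smoothed weight
$\approx 0$) are zeroed so `0 * nan` cannot poison the moments.

The counterfactual model re-solves
$X^{\text{cf}}_t = F(X^{\text{cf}}_{t-1}, \tilde\theta) + U_t^{\text{cf}}$
from $X_0^{\text{cf}} = X_0 + \delta e_j$ (study design: $\delta=10^{-4}$
on $e_1$ for the chaotic systems, $+10$ for logistic). Each of the $K$
trajectories draws its own $\tilde\theta$ once (parameters are static)
and its own independent $U_t^{\text{cf}} \sim \mathcal N(\mu_t,
\operatorname{diag}\sigma_t)$ per step; sharing a single noise path
across the ensemble would collapse the spread that the posterior
expresses. Posterior-mode $\tilde\theta$ draws are *not* truncated to
the prior support; trajectories that diverge are flagged and NaN-filled
rather than fatal, and excluded (with a logged count) from the RMSE. An
ensemble that diverges entirely is reported as infinite final error by
the grid runner — every sampled counterfactual left the basin, which is
itself the finding.

## Evaluation

$$\mathrm{RMSE}_t = \sqrt{\tfrac 1{Kd} \sum_{k,i}
\bigl(X^{\text{cf}}_k[t,i] - \text{ref}[t,i]\bigr)^2},$$

pooled over ensemble and coordinates against the deterministic
counterfactual (noise-free propagation from the intervened initial
state under $\theta_{\text{true}}$), then smoothed with a centered
200-step moving average whose window shrinks at the edges (no padding
values are fabricated). The divergence time is the first step at which
the smoothed curve exceeds a threshold, by default 10% of the
reference's pooled per-coordinate SD (scale-free across systems). The
grid runner summarizes each cell by the mean smoothed RMSE over the
final 25% of steps and the divergence time; one simulation + one
inference serve all three parameter regimes of a cell.

At the grid's noise scales the ensemble spread crosses the 10%
threshold within the first smoothing window for *every* parameter
regime of the chaotic systems, so the divergence-time ordering
(true ≥ point ≥ posterior) typically holds as a tie at step 0; the
final-window RMSE carries the discriminating signal.

## Numerical choices and degenerate inputs

- Divergence guard at state norm $10^6$; public single-trajectory
  propagation raises a `DivergedStateError` carrying the step index,
  batched internal propagation clamps-and-downweights instead.
- All weight arithmetic in log space; `logsumexp`-style max-subtraction
  in the smoother's $N \times N$ kernel; the Gaussian normalizing
  constant cancels between transition and predictive densities and is
  dropped.
- $\sigma_W = 0$ is rejected for inference (point-mass likelihood);
  $\sigma_U = 0$ triggers the ancestral-path smoother.
- Seeds are explicit everywhere (simulator, filter, counterfactual
  sampler); identical seeds give bitwise-identical runs.
- The Benettin Lyapunov estimator uses separation $10^{-8}$ along
  $e_1$, renormalization every 1 time unit, 50-time-unit transient and a
  2000-time-unit horizon by default (resolves exponents of order 0.01);
  the Lorenz/Rössler scans run all parameter values as one integration
  batch.
- Butterfly checks spin up 50 time units first: sensitive dependence is
  an attractor property, and the finite-time exponents along the
  transient from $(1,1,1)$ are small for the first ~15 time units (unit
  separation from the raw start arrives only after ~2100 steps).

## What the synthetic data does and does not emulate

The generator produces exactly the model the inference assumes:
additive, isotropic, white Gaussian noise on state and observation,
identity observation map, known model structure, time-invariant
parameters. Real systems violate most of these (correlated and
state-dependent noise, partial observation, structural misspecification,
drift). Passing tests therefore demonstrate the *best case*: even with
a correctly specified model, full-sequence smoothing and a well-behaved
noise posterior, chaotic dynamics make counterfactual trajectories
unreliable. They say nothing about the additional degradation real data
would add — which only strengthens the cautionary conclusion in the
chaotic case, but means the logistic system's clean counterfactuals are
an upper bound on reliability, not a promise.

## Known limitations

- The smoother is $O(TMN^2)$; large $N$ with long horizons is the
  binding cost (the linear-Gaussian oracle at $N=5000$, $T=25$ runs in
  ~30 s).
- High-process-noise grid cells for Rössler/logistic are infeasible
  under the additive-per-step noise model (see above); the grid records
  them as failed cells rather than silently changing the model.
- The abducted posterior is per-step diagonal Gaussian; cross-time and
  cross-coordinate noise dependence is discarded by construction.
- Interventions cover initial conditions only (the counterfactual
  surface intentionally excludes mid-trajectory and parameter
  interventions).
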