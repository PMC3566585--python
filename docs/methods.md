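# Methods

`dcmodes` estimates effective connectivity — directed coupling among brain
regions — from region-summary BOLD timeseries, for models large enough
(16–20 nodes) that the usual fully-connected parameterisation becomes
badly over-parameterised.  The package implements a deterministic dynamic
causal model (DCM), shrinkage priors whose rank is constrained by
functional-connectivity modes, variational-Laplace inversion, free-energy
model comparison over the number of modes, and post-hoc reduction for
network discovery.  This note records the model, every tunable constant,
and the design choices made where the design was genuinely open.

## Generative model

Neuronal dynamics follow the bilinear state equation

    dz/dt = (A + Σᵢ uᵢ Bᵢ) z + C u

with one lumped activity variable per node.  `A` (Hz) is the endogenous
coupling matrix (negative diagonal = self-inhibition), `Bᵢ` (Hz) bilinear
input modulation (supported in code; all shipped experiments leave it
empty), and `C` (Hz) the driving efficacy of the exogenous inputs `u(t)`.
Self-connections are parameterised as deviations around the prior mean of
−1/2 Hz (not as exponentiated scale factors), so the parameter vector is
exactly the column-stacked vec(A) that the mode constraint acts on.

Each node's activity drives a single-compartment balloon–Windkessel model
with states (vasodilatory signal s, inflow f, venous volume v,
deoxyhemoglobin q):

    ds/dt = z − κ s − γ (f − 1)
    df/dt = s
    τ dv/dt = f − v^{1/α}
    τ dq/dt = f E(f)/E₀ − v^{1/α} q / v,   E(f) = 1 − (1−E₀)^{1/f}

and the nonlinear BOLD observation equation

    y = V₀ [ k₁ (1−q) + k₂ (1 − q/v) + k₃ (1 − v) ]
    k₁ = 4.3 ϑ₀ E₀ TE,  k₂ = ε r₀ E₀ TE,  k₃ = 1 − ε.

Constants (1.5 T conventions, all in `constants.py`): κ = 0.64 s⁻¹,
γ = 0.32 s⁻¹, τ = 2 s, α = 0.32, E₀ = 0.4, V₀ = 4, ϑ₀ = 40.3 s⁻¹,
r₀ = 25 s⁻¹, TE = 0.05 s, ε = 1.  Free hemodynamic parameters are
per-node log-scalings of κ and τ plus a global log-scaling of ε, each
with prior N(0, 1/256).  f, v, q are integrated in log space to enforce
positivity.

Integration is fixed-step classical RK4 on a microtime grid (default
TR/16) with inputs held piecewise constant per micro step; BOLD is
sampled at volume times.  Halving the step from TR/16 to TR/32 changes
predictions by < 1e-5 relative; TR/8 agrees with TR/16 to ~5e-5 and is
used for the scaled simulation studies; TR/4 is outside the RK4 stability
region for these dynamics.  The integrator accepts a batch of parameter
vectors and propagates them simultaneously, which is what makes
finite-difference Jacobians affordable.

Note the balloon model has a hard physiological wall: sustained neuronal
activity below −γ ≈ −0.32 drives the steady-state inflow negative and the
log-volume state to −∞.  Generated "true" parameters must respect this
(see the generator section).

## Priors

With n nodes, the coupling priors are

    self:     A_ii ~ N(−1/2, 1/(8n))
    between:  A_ij ~ N(1/(64n), 8/n),  i ≠ j

diagonal over all n² entries; the n-scaling makes the shrinkage stricter
for larger models, precluding runaway excitation.  Driving efficacies of
designated input nodes get N(0, 1); all other C entries are fixed at
zero.  B entries are fixed at zero by default.  Each node's noise
log-precision has hyperprior N(4, 1/8); the hyperprior variance is not a
published constant and is isolated in `constants.py`.

**Mode constraint.**  Functional connectivity means the node-by-node
sample correlation matrix of the observed timeseries.  Each node's series
is z-scored before the SVD, so the modes are exactly the correlation
matrix's eigenvectors; orientation is fixed by making each mode's
largest-magnitude element positive.  With the m leading modes U_m and
P = U_m U_mᵀ, the projector K_m = P ⊗ P (column-stacking convention) maps
vec(A) to vec(P A P), and the A-block prior covariance becomes
Σ_m = K_m Σ K_mᵀ: rank ≤ m², with prior correlations among couplings and
no prior variance outside the mode span.  Only the A block is
constrained; C, B, hemodynamic and noise priors are untouched.  For
m = n the projector is the identity analytically, and the code returns
the unconstrained prior bit-exactly rather than a numerically-identity
product.

## Inversion (variational Laplace)

Observation noise is modelled as independent Gaussian per node with
precision exp(λᵢ), iid over volumes.  The posterior over parameters and
log-precisions is approximated as Gaussian, maximising the free energy

    F = accuracy − complexity
    accuracy   = E_q[log p(y | θ, λ)]  (Laplace form, including the
                 −½ tr(Jᵀ Π J Σ_q) curvature term)
    complexity = KL(q(θ)‖p(θ)) + KL(q(λ)‖p(λ)).

Because Σ_m is singular by construction, optimisation runs in an
orthonormal eigenbasis of the prior covariance restricted to eigenvalues
> 1e-8 × the largest; fixed directions never move, so zero-prior-variance
parameters keep the prior mean exactly.  Per iteration: (i) a central
finite-difference Jacobian of the integrator over the support directions
(step 1e-4 prior standard deviations per direction), evaluated in one
batched integrator call; (ii) Newton updates of each λᵢ interleaved with
the posterior covariance (the λ objective is concave; steps clamped to
±2); (iii) a Gauss–Newton step with Levenberg–Marquardt regularisation —
three candidate regularisation strengths are evaluated in one batched
forward call and the best candidate that increases F is accepted, so F is
non-decreasing over accepted steps.  Convergence: |ΔF| < 1e-2 nats on
three consecutive iterations, max 128 iterations (library default); a
model that stalls (no candidate step improves F) stops at the incumbent.
If an accepted mode integrates but a finite-difference perturbation
crosses the integrator's stability boundary, the scheme retreats to the
previous mode with stronger regularisation.  Optionally the whole scheme
restarts from modes jittered within the prior (``n_starts`` > 1, draws
seeded by ``settings.seed``) and keeps the run with the highest F; the
default single start from the prior mean is fully deterministic.

On linear-Gaussian problems with fixed noise precision this free energy
is exact — it equals the closed-form Bayesian-linear-regression log
evidence, which the test-suite verifies to ~1e-9 nats.  With free λ the
accuracy uses the plug-in posterior mean of λ (not E[exp λ]); the
difference is absorbed into the λ posterior and is irrelevant to model
comparison at fixed hyperpriors.

## Model comparison over modes

One model per mode count m, with modes recomputed from each dataset's own
timeseries (prior covariances therefore differ between datasets).  Log
evidences are pooled over datasets by summation (fixed-effects
comparison); the winner is the argmax, ties broken toward smaller m.  A
model that fails on any dataset is excluded from pooling for all
datasets, so sums always compare identical model sets.  The
strong-evidence report flags (dataset, m) pairs where F(m) − F(n) exceeds
5 nats, the conventional margin.

## Post-hoc reduction and graphs

For Gaussian prior/posterior pairs the evidence of any reduced-prior
model follows analytically from the full model's moments (see
`reduction.py` docstring for the formula); no re-inversion is needed.  An
absent edge is prior variance 1e-8 (not exact zero) with mean 0 on that
vec(A) entry, keeping the covariance algebra well-posed.  The search is
greedy backward elimination (prune the single edge whose removal most
increases the score; stop when nothing improves), with an exhaustive mode
for ≤ 12 candidate edges used to validate greedy on small models.  Under
a rank-deficient (m < n) prior the reduction is computed in the support
basis of the full prior — exact for m = n, and an approximation
restricted to the prior-support manifold otherwise.

Group posteriors use Bayesian parameter averaging: group precision = sum
of posterior precisions minus K−1 copies of the shared prior precision
(the prior is counted once; the convention is switchable, and a flat-prior
variant simply sums precisions).  Graphs: per-edge posterior probability
is the Gaussian tail probability that the coupling shares the sign of its
posterior mean (0.5 at mean zero); the binary adjacency thresholds this
at 0.95 by default; the symmetrised strength is s_ij = max(|a_ij|,
|a_ji|) with zero diagonal; the spectral embedding takes the first three
principal components (scores scaled by singular values) of the
column-centred strength matrix, signs fixed deterministically.

## Synthetic data generator

The default protocol emulates a block-design activation study summarised
to 20 nodes: 198 volumes, TR 3.6 s, TE 0.05 s, one stimulus function
driving two nodes, task blocks of 18 s (events every 4.5 s, boxcar by
default) alternating with 14.4 s rest, SNR 1, ten datasets.  Noise is
white Gaussian convolved with a Gaussian kernel (FWHM = 1 TR default,
configurable to 0 for white noise) and rescaled per node to
sd(signal)/sd(noise) = SNR after baseline removal; nodes with negligible
signal receive the median node's noise scale.  The empirical lag-1 noise
autocorrelation matches the kernel's (~0.12 at FWHM 1 TR).

True couplings are drawn with off-diagonal entries present with
probability 0.25, magnitudes uniform 0.2–0.5 Hz, random signs, diagonal
−0.5 Hz; optionally the off-diagonal structure is projected onto a random
r-dimensional mode space (`coupling_rank`) for the mode-selection
studies.  A raw draw at this density is almost never admissible for large
n, so the off-diagonal block is scaled down globally until (i) all
eigenvalues of A have real part < −0.05 and (ii) the steady-state
activity −A⁻¹C lies in (−0.2, 1) — the lower bound keeps sustained
activity above the balloon model's inflow wall, the upper bound keeps
responses in a physiological range.  Same seed ⇒ bit-identical dataset;
the per-node SNR realises the target exactly by construction.

What the generator does **not** emulate: physiological (cardiac/
respiratory) noise structure, scanner drift, motion residuals, regional
variation in hemodynamics beyond the priors, or model mismatch (data are
generated from the same forward model that is inverted, aside from the
microtime-step difference).  Passing tests therefore demonstrate the
estimator's behaviour under its own assumptions at realistic noise
levels, not robustness to the full complexity of empirical fMRI.

## Scaled study sizes

The simulation studies shipped with the tests and the acceptance script
run at a reduced size chosen to exercise the full pipeline on a single
CPU: 8 nodes, rank-4 coupling, 5 datasets, 132 volumes, modes swept
1..8, microtime step TR/8, and an iteration budget of 28 shared by every
model in a sweep (a common budget keeps the fixed-effects comparison
fair).  At this size the qualitative phenomena of interest — an interior
free-energy peak, monotone accuracy and posterior-variance trends,
~50% variance explained at SNR 1, and ≥85% credible-interval coverage at
m = n — are reproduced.  The full 20-node default protocol is used for
the analytic and generator-fidelity checks.

The edge-recovery study (6 nodes, 8 true edges ≥ 0.3 Hz, SNR 1) uses a
stimulus-driven feedforward hierarchy with a single driven node and
temporally white noise.  Two design facts matter here: nodes receiving
identical input with no other afferents have *identical* noiseless
dynamics, making their outgoing edges unidentifiable in principle; and
smooth noise violates the white-noise likelihood, degrading edge
discrimination.  Even so, individual-edge recovery from slow BOLD has a
hard information limit that users should understand before interpreting
discovered graphs edge-by-edge: (i) the marginal posterior standard
deviations of the true edges, evaluated *at the truth with known noise
precision*, are 0.25–0.9 Hz at SNR 1 — comparable to the 0.3–0.55 Hz
effect sizes; and (ii) the likelihood is nearly degenerate along
path-swapping directions (credit for a chain i→j→k can be redistributed
onto a direct i→k edge), so the globally optimal explanation of a given
noise realisation can differ from the generating graph — warm-starting
the optimiser at the truth converges to the same alternative optimum.
Aggregate sensitivity/specificity over seeds is therefore around
0.5–0.9 per dataset at SNR 1 (and the degeneracy persists at higher
SNR); the shipped test asserts above-chance recovery and that retained
edges carry systematically larger true couplings than pruned ones.
Graph-level summaries (strength, embedding, hubs) are more stable than
individual edges.

## Known limitations

- Deterministic DCM only: no hidden-state noise (stochastic DCM) and no
  resting-state variant.
- The noise model is white within node; temporally correlated noise is
  generated but not modelled in the likelihood.
- Gauss–Newton on a nonconvex landscape can stall in local optima for
  weakly identified couplings; free energies remain valid lower bounds
  and model comparison is unaffected, but point estimates of individual
  edges can redistribute credit along correlated paths.
- The λ hyperprior mean of 4 presumes amplitude conventions in which BOLD
  noise precision is high; with arbitrary data scaling the data dominate
  this weak hyperprior, shifting λ by ≲ 0.5 nats.
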