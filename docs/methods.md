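# Methods

`spinedyn` implements a complete analysis-and-modelling chain for the
statistics of dendritic-spine head sizes and synaptic weights: fitting
skewed (lognormal-like) size distributions, comparing them across
experimental conditions with rank-based tests, simulating synaptic
weight dynamics under combined intrinsic (Kesten) noise and extrinsic
(STDP) plasticity, and inferring the simulator's parameters from summary
features of observed distributions.

## Distribution fitting

Spine head areas (µm²) are right-skewed and heavy-tailed. The headline
fit works on the binned density: the sample is histogrammed with
equal-width bins over `[min, max]`, counts are divided by the integral of
the raw histogram so that `sum(density_i * width_i) = 1`, and the
two-parameter lognormal PDF

    f(x) = 1 / (x sigma sqrt(2 pi)) * exp(-(ln x - mu)^2 / (2 sigma^2))

is fitted to the bin-center densities by nonlinear least squares,
initialized at the sample log-moments (mean and SD of `ln x`). Goodness
of fit is `r^2 = 1 - SS_res / SS_tot`, which may be negative for fits
worse than a constant; a failed fit is *flagged* (`converged=False`, NaN
parameters), never raised, so batch per-cell fitting always completes.

Numerical choices:

* **Bin count** — Freedman–Diaconis, clipped to [10, 50] bins. This
  keeps densities stable from per-cell samples (n ≈ 60–100) up to pooled
  samples (n ≈ 10⁴–10⁵). Configurable everywhere.
* **Optimizer** — a fast unconstrained Levenberg–Marquardt pass on
  `(mu, ln sigma)` (the log-reparameterization keeps `sigma` positive
  without bound handling), falling back to a bounded trust-region fit
  with `sigma` in `(1e-4, 10)` if the fast path fails or leaves that
  interval. Analytic Jacobians in both paths.
* **Log-domain check** — a Gaussian bump `a exp(-((x-b)/c)^2)` fitted to
  the binned density of `ln x`; for lognormal data `b -> mu` and
  `c -> sigma sqrt(2)`.
* **Skewness** — adjusted Fisher–Pearson (bias-corrected) on the raw
  sizes; zero-variance samples return NaN.
* **Model comparison** — maximum-likelihood fits of lognormal, gamma and
  Weibull on the raw sample with location fixed at zero (k = 2 parameters
  each) and `AIC = 2k - 2 ln L`; a failed MLE receives `+inf` and stays
  in the table.

Per-cell and pooled drivers share bin policy but compute bin edges per
sample; 'other'-type spines are excluded from fitting, and samples below
a configurable minimum (default 20 spines) are flagged.

## Group statistics

All metric comparisons (r², skewness, sigma = SD of log sizes) use
rank-based tests only: Mann–Whitney U between two independent groups
(hemispheres or genotypes; exact null distribution when the combined
tie-free sample is ≤ 20, normal approximation with tie correction
otherwise), Friedman's chi-square across the three dendritic layers
measured repeatedly within each cell, and Kruskal–Wallis across cell
ages. Omnibus tests with p < 0.05 trigger pairwise post hocs (Wilcoxon
signed-rank for the paired layer design, Mann–Whitney for ages) with
Bonferroni–Holm step-down correction. All tests are two-sided; being
rank-based, every p-value is invariant under strictly monotone metric
transformations.

## Weight-dynamics simulator

A population of `n_neurons` independent leaky integrate-and-fire cells,
each with `n_inputs` synapses (defaults 1000 × 100). Per neuron the
membrane potential decays toward rest with `tau_m = 10 ms`, each
presynaptic spike at input *i* adds `coupling_gain * w_i` (delta-current
coupling), and crossing `threshold = 10 mV` emits a spike and resets.
The default gain (1 mV/pS) is calibrated so that about 20 near-coincident
average-weight inputs reach threshold.

Weights evolve under three mechanisms:

* **Intrinsic (Kesten) noise** — per noise interval `dt_n`, an
  Euler–Maruyama step `w' = w (1 + m sqrt(dt_n) xi1) + a sqrt(dt_n) xi2`
  with independent standard normals per synapse, clipped at zero.
  `m` is in proportion of size per second (default 0.15/s), `a` in pS per
  second (default 0.001, deliberately weak: strong additive noise erodes
  the skew of the stationary distribution).
* **STDP** — exponential window with time constant
  `tau_STDP = 0.5 ms`: a pre-before-post pairing at lag Δt potentiates
  additively, `w -> w + c_p exp(-|Δt|/tau)` with `c_p = 0.007 pS`; a
  post-before-pre pairing depresses multiplicatively,
  `w -> w (1 - c_d exp(-|Δt|/tau))` with `c_d = 0.003`. Pairing is
  nearest-neighbour in both directions (each postsynaptic spike pairs
  with the most recent presynaptic spike per input and vice versa). The
  window magnitude decays with the pairing separation |Δt| in both
  branches — the only integrable choice for an exponential window.
* **Heterosynaptic scaling** — after each noise step, each neuron's
  weights are rescaled multiplicatively so their total equals its initial
  total (conservation of total conductance). Weight ratios are preserved
  exactly; all-zero rows are skipped.

Stimulation protocols drive only `floor(stim_proportion * n_inputs)`
inputs (default proportion 0.2): `silent` (none), `control` (10 Hz
Poisson), `hfs` (200 Hz periodic, random phase per input). Initial
weights are i.i.d. `U(0, 2 w̄)` with `w̄ = 0.5 pS` unless supplied.

**Numerical scheme.** Spikes and STDP require sub-millisecond resolution
(`tau_STDP = 0.5 ms`), so they run on a 0.1 ms grid. Between input
events the membrane only decays and cannot cross threshold, so the LIF
state is advanced lazily per neuron and the cost is proportional to the
number of spikes, not time steps (the event loop is JIT-compiled).
Events sharing a step are processed in array order with the threshold
checked after each one. Diffusive noise and scaling are statistically
equivalent on any grid finer than the dynamics of interest and are
applied on a coarser interval (default 10 ms); noise draws and input
events are pre-generated in blocks for speed (restricting a Poisson
process to sub-intervals is distributionally identical). Runs are
deterministic per seed via independently spawned streams for
initialization, noise and spikes; the three protocol runs of a suite
share one seed and hence identical initial weights and noise
realizations, so they differ only through the stimulus.

With scaling and STDP off and additive noise zero, the weights follow
geometric Brownian motion: `Var[ln w] = m^2 T`, which the test suite
verifies at 10⁴ synapses to within 10%; with constant suprathreshold
drive `I` the LIF interspike interval equals `tau_m ln(I/(I - theta))`
to within one time step.

## Simulation-based inference

Six parameters are inferred: stimulated proportion, multiplicative and
additive noise strengths, STDP timescale, potentiation rate and relative
depression rate. The summary features are the lognormal `(mu, sigma)`
fitted to the final weight distribution of each protocol in the suite
(six numbers); simulated weights are first rescaled to the observed mean
size per protocol, so `mu` shifts by exactly `ln c` under input scaling
by `c` and `sigma` is invariant.

The engine is sequential rejection ABC: round 1 samples a uniform prior
box; each round simulates the full protocol suite per candidate, keeps
the `epsilon = 0.1` fraction closest to the observed features under a
Euclidean distance standardized by the round-1 feature spread, and
proposes the next round by Gaussian perturbation of the survivors
(per-dimension SD equal to the survivor spread) truncated to the prior
box. Final survivors are resampled to `n_posterior` draws (default
10 000). The simulator is an injectable callable with the same
`theta, seed -> features` contract, so a neural posterior-estimation
backend can be slotted in without touching the interface; no neural
density estimator is implemented in-repo.

The MAP estimate is the mode of a Silverman-bandwidth Gaussian KDE over
the draws, located by evaluating the density at the draws and refining
locally as the density-weighted centroid of the top-density 5% shell —
substantially more stable under sampling noise than the raw argmax.
Degenerate dimensions are held at their value; a singular draw
covariance falls back to the most frequent draw. Marginals are
normalized 1-D histograms and all 15 pairwise 2-D histograms.

Default prior bounds are illustrative and must be set explicitly for any
scientific run: stimulated proportion [0.05, 0.5], multiplicative noise
[0.02, 0.5]/s, additive noise [0, 0.02] pS/s, STDP timescale
[0.1, 5] ms, potentiation rate [0.001, 0.02] pS, relative depression
[0.0005, 0.01].

**Problem sizes.** Per-candidate simulations use a reduced population
(100 neurons × 100 inputs, 0.5 s, 20 ms noise interval); synthetic
observations in the closed-loop tests use 400 neurons so that
observation-side feature noise is small relative to candidate-side
noise. Closed-loop validation runs 3 rounds × 500 simulations; the
full-scale protocol suite (1000 × 100) runs for 10 s of simulated time.
These sizes are the package's validation defaults; all are configurable
upward. Under them, 90% credible intervals cover the generating values
of the two well-identified parameters (multiplicative noise strength and
stimulated proportion) in at least 8 of 10 seeded repetitions, and
re-simulation at the MAP reproduces the observed binned densities with
r² ≥ 0.9. The additive noise strength and the STDP parameters are only
weakly constrained by these features — the same behavior the inference
is expected to show on real data.

## Synthetic data generator

The generator emulates the *structure* of two spine datasets, not their
(unpublished) parameter values:

* **abGC layout** — 3 molecular layers × 3 cell ages (21/28/35 dpi) × 2
  hemispheres; 12/9, 18/18 and 30/24 cells per age (ipsi/contra) spread
  over 3, 6 and 5 animals; 60–105 spines per cell and layer. Head areas
  are i.i.d. `LogNormal(mu_c, sigma_c)` per condition with baseline
  `mu = -1.0`, `sigma = 0.5` (areas in µm²). Induced plasticity is
  emulated as multiplicative shifts of the log-moments on the stimulated
  hemisphere: `sigma × 1.15` in the MML (potentiation broadens) and
  `sigma × 0.85` in IML/OML (heterosynaptic depression narrows).
* **CA1 layout** — 2 groups (release-blocked vs control) × 3 culture
  ages with the published cell counts; spine types drawn with fixed
  proportions (22.85% mushroom, 23.73% thin, 51.16% stubby, 2.26%
  'other'); no group effect on the log-moments by default. Mushroom and
  thin spines are separated by a single head-area cutoff (≥ cutoff →
  mushroom), whose default is the lognormal quantile consistent with the
  mushroom/thin proportions so realized fractions match configured ones.
  'other' spines are generated but excluded from analysis, mirroring
  practice with real typed data.

What the generator does *not* emulate: within-cell correlation of spine
sizes, measurement/detection noise, non-lognormal contamination (e.g.
the overabundance of large spines seen in mature cells), or animal-level
random effects. Passing tests therefore demonstrate the correctness and
calibration of the pipeline on cleanly lognormal data, not the
biological conclusions one would draw from real microscopy tables.

## Known limitations

* The baseline log-moments and plasticity shift sizes of the generator
  are illustrative; per-condition values are not published.
* The default STDP timescale (0.5 ms) is short relative to classical
  STDP windows (~20 ms); it is exposed as a parameter and is itself an
  inference target.
* The depression branch never produces negative weights (`c_d < 1`), but
  additive noise can push weights to the zero floor, where the
  multiplicative dynamics cannot revive them except through scaling or
  potentiation.
* Rejection-ABC posteriors are approximate: with few survivors per round
  they can over-concentrate, which is why closed-loop validation checks
  interval coverage rather than point accuracy.
* Type-I error calibration is verified for the null designs used in the
  tests (n = 20 per group, 30 cells × 3 layers, 3 × 15); very small
  samples rely on the same asymptotics and will be more conservative.
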