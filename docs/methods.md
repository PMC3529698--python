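# Methods

## Model and scope

The workbench simulates well-mixed mass-action reaction networks as Markov
jump processes on integer state vectors. Propensities use the combinatorial
convention: a reaction consuming two identical molecules has propensity
k·x(x−1)/2, three identical molecules k·x(x−1)(x−2)/6 (this convention is
what makes the bistable Schlögl benchmark land on its reference conditional
means; the power-law alternative does not). Total molecularity per reaction
is capped at three. Rates are time-independent; volume enters only through
the rate constants and is not represented separately.

Species held constant by the environment ("buffered", like the A and B
pools of the Schlögl system) are folded into effective rate constants at
build time: the rate is multiplied by the falling-factorial count of the
buffered reactant, and the species disappears from the dynamic state. This
is exact for constant pools and keeps every downstream algorithm unchanged.

## Solvers

**SSA (Direct Method).** Two fresh uniforms per event — one exponential
waiting time from the total propensity a₀, one cumulative-sum search for
the reaction index. When a₀ = 0 the state is frozen until the horizon. The
inner loop is numba-compiled; replicate streams are spawned from the master
seed, so ensembles are reproducible and replicates independent.

**Fixed-step τ-leap methods.** All three fire Poisson counts per reaction
per step and require T to be an integer multiple of τ:

* *Euler (ETL)*: k_j ~ Poisson(a_j(X_n) τ); weak order 1.
* *Midpoint (MPTL)*: deterministic half-step predictor
  X′ = X_n + (τ/2) ν a(X_n), then k_j ~ Poisson(a_j(X′) τ) applied to X_n.
  X′ is kept real-valued — propensity formulas accept reals, and rounding
  would introduce an artificial O(1/x) bias.
* *θ-trapezoidal (TTTL)*: Poisson predictor over θτ, then a corrector over
  (1−θ)τ with rates max(α₁ a_j(X′) − α₂ a_j(X_n), 0), where
  α₁ = 1/(2(1−θ)θ) and α₂ = ((1−θ)² + θ²) α₁ (α₁ − α₂ = 1 identically);
  weak order 2. Default θ = 0.55.

Negative populations can occur inside a leap and are allowed to propagate;
propensities are clamped at zero before sampling so Poisson means stay
valid. In the intended leaping regime (tens to hundreds of firings per
channel per step) negativity is negligible; negativity-avoiding variants
(binomial leaping, implicit leaping) are out of scope. Because every update
is an integer combination of stoichiometric columns, conservation laws
(left null vectors of ν, extracted exactly over the rationals) hold exactly
along all trajectories, including negative excursions — this is used as a
structural test throughout.

Ensembles advance all S replicates as one vectorized batch from a single
PCG64 stream seeded by the protocol seed. This trades the "one stream per
replicate" picture for vectorization; replicate draws remain independent,
and a fixed seed gives bit-identical moments.

## Exact references for linear networks

When every reaction is zeroth- or first-order the propensity vector is
affine, a(x) = Cx + d, and with W = νC the moment equations close:

    dμ/dt = Wμ + νd,
    dS/dt = WS + SWᵀ + μ(νd)ᵀ + (νd)μᵀ + ν diag(Cμ) νᵀ + ν diag(d) νᵀ,

with S = E[xxᵀ]. Both are evaluated through one augmented matrix
exponential: the joint vector (μ, vec S, 1) evolves under a constant
matrix, so expm gives μ(T) and S(T) to machine precision (≈14 significant
digits; the contract is ≥10) with no quadrature or ODE-tolerance tuning. An
independent high-order ODE integration of the same system serves as a
cross-check in the tests, not as the implementation.

The Euler leap's infinite-replicate moments obey exact discrete recursions
(law of total expectation over the Poisson counts):

    μ_{m+1} = (I + τW) μ_m + τνd,
    S_{m+1} = (I+τW) S_m (I+τW)ᵀ + τ(μ_m bᵀ + b μ_mᵀ)
              + τ²(Wμ_m bᵀ + b μ_mᵀWᵀ + bbᵀ)
              + τ ν diag(Cμ_m) νᵀ + τ ν diag(d) νᵀ,      b = νd.

Iterating these gives E_∞ f(x_n^τ) — the estimator's value at infinite
replicates — which splits the measured weak error exactly into a
τ-dependent bias and a 1/√S Monte Carlo part. The leading-order bias of the
Euler-leap mean is e^{WT} (τT/2)(W²μ(0) + Wνd); the e^{WT} prefactor is
essential — without it the prediction does not match the exact bias (with
it, the decay system at τ = 0.05 gives 9.19 against the exact 9.21).

**CME solver.** For single-dynamic-species networks the CME is a sparse
linear ODE on a truncated lattice. Transitions that would leave the lattice
are switched off (probability is conserved exactly) and the solution is
propagated with a Krylov matrix-exponential action (`expm_multiply`); mass
in the outermost states is checked against 10⁻⁸ and a violation raises.
Default truncation is [0, 6·X(0)]. Multi-species CME is a non-goal (the
state space explodes; the solver exists to provide exact references for the
decay and Schlögl benchmarks).

## Extrapolation

Weights follow the general rule (p^k z_fine − z_coarse)/(p^k − 1); the
Romberg column produced from column c−1 uses exponent k + c − 1, where k is
the base method's weak order (ETL 1, MPTL/TTTL 2 by default, overridable).
An extrapolated estimate labeled τ combines stepsizes (τ, τ/2). Coarse and
fine ensembles use independent seeds derived from the master seed — no
coupling.

**Variance is extrapolated as its own functional**, with the same weights
applied to the per-stepsize sample variances. Deriving it instead from the
extrapolated mean and second moment is numerically treacherous: the mean's
surviving O(τ²) residual, multiplied by 2μ ≈ 7×10³ for the decay benchmark,
exceeds the true variance (≈2285) at τ = 0.8, making that derived quantity
negative even at infinite replicates. The moments-derived version remains
available (`variance_from_moments`) and warns when negative.

This residual also bounds distribution reconstruction: inverting
extrapolated (mean, variance) into Binomial(n, p) reproduces the decay
system's exact terminal law to total variation < 0.01 for the (0.4, 0.2)
pair at S = 10⁶, but the (0.8, 0.4) pair has a deterministic TV floor near
0.02 — a 2.5-molecule mean offset against a 48-molecule standard deviation.

**Multimodal systems.** Terminal states of each ensemble are partitioned at
chosen split points; conditional moments per peak are extrapolated
pairwise. A split outside the data range degenerates to global
extrapolation; a subset empty at only one stepsize is an error. The
suggested split points are the deepest gap points between
prominence-filtered modes of a Gaussian-smoothed histogram (≥1000 samples
required). For the Schlögl benchmark the CME's conditional means use the
convention low = states strictly below the split, high = at or above;
probability mass near X = 300 is so small that moving the split by ±1
changes the conditional means by < 0.5 molecules (tested).

## Benchmark values and their precision

The five fixtures carry reference values used across the tests. Three
precision caveats, all verified against exact computation here:

* The five-species chain's published mean vector (1971.3, 1996.7, 2025.1,
  2020.9, 1986.1) is attained by the exact solution at t = 10.4, not at the
  nominal horizon T = 16 (where the exact, still perfectly conserved mean
  is (1998.6, 1991.1, 1995.8, 2006.3, 2008.1)); the benchmark's horizon
  label is inconsistent with its own mean vector. Tests verify the oracle
  against the published vector at t = 10.4.
* The decay system's Euler-leap bias ladder is exact except the τ = 0.1
  entry, whose exact value 18.455 appears truncated (18.4) rather than
  rounded in the reference table; the extrapolated-pair error at τ = 0.8 is
  exactly 2.539 against a published 2.6 estimated from noisy ensembles.
* The re-parameterized enzyme-kinetics CV vector (0.05, 0.03, 0.1, 0.07) is
  printed to one significant figure (true CV of the complex ≈ 0.128); tests
  compare at printed precision.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so stochastic
checks sit comfortably above their Monte Carlo floors: τ-leap ensembles of
10⁵ (moment-vs-recursion checks, 4 SE) to 10⁶ (distribution
reconstruction), SSA ensembles of 400–1000 replicates (the Michaelis–Menten
reference mean has SE ≈ 2.3 molecules at 1000 replicates, checked within
4 SE), and the Schlögl CME on 1501 states. The original benchmark studies
used 10⁷–10⁸ replicates; at desk scale the published errors of the
higher-order and extrapolated methods are below the Monte Carlo floor and
are covered by exact-recursion and property tests instead of equality
checks.

## Known limitations

* Fixed stepsizes only — extrapolation requires them; adaptive τ selection
  is out of scope by design.
* No negativity guards; results in regimes with frequent near-zero
  populations (where a leap can overshoot) should be treated with care.
* The linear-network oracles require strictly zeroth/first-order reactions;
  nonlinear systems fall back to SSA ensembles as references, with the
  reference's own standard error propagated.
* The CME solver handles one dynamic species.
* Extrapolated variances can come out negative within Monte Carlo noise at
  small S; `binomial_reconstruct` refuses moments with variance ≥ mean.
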