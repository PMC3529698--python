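# tauleapx

A workbench for discrete stochastic chemical kinetics: fixed-step τ-leap
solvers whose weak order is raised by Richardson extrapolation of their
moment estimates, together with the exact reference machinery needed to
measure bias, Monte Carlo error, and convergence order.

## The problem

Well-mixed reaction networks with low copy numbers are Markov jump
processes: a state vector **X**(t) of molecule counts, a stoichiometric
matrix ν (N species × M reactions), and mass-action propensities a_j(**x**)
(a_j dt = probability that reaction j fires in [t, t+dt)). The probability
distribution over states obeys the chemical master equation (CME);
Gillespie's stochastic simulation algorithm (SSA) samples it exactly but
simulates every single reaction event, which is slow for realistic systems.

The τ-leap accelerates simulation by firing Poisson-distributed batches of
reactions over a fixed step τ — at the cost of a discretization bias. For a
functional f (a moment, say), a weak order-k fixed-step method admits a
global error expansion

    E f(X(T)) − E f(X_n^τ) = e_k τ^k + e_{k+1} τ^{k+1} + …,   T = nτ.

Richardson extrapolation combines estimates at stepsizes τ and τ/p with
weights (p^k z_{τ/p} − z_τ)/(p^k − 1), cancelling the leading term and
raising the weak order by one; repeating the combination column by column
builds a Romberg table of successively higher-order estimates. For the
Euler τ-leap (k = 1, p = 2) one extrapolation is simply 2 z_{τ/2} − z_τ.

`tauleapx` implements:

* **Solvers** — SSA Direct Method (numba-compiled); Euler (ETL), midpoint
  (MPTL), and θ-trapezoidal (TTTL) τ-leap with vectorized ensembles.
* **Extrapolation** — pairwise and Romberg extrapolation of mean, second
  moment, and variance; per-peak extrapolation for multimodal systems with
  histogram-based split-point suggestion; binomial reconstruction of the
  full terminal distribution from extrapolated mean and variance.
* **References** — for linear (zeroth/first-order) networks, exact μ(T) and
  E[**x x**ᵀ](T) via augmented matrix exponentials, and the exact
  infinite-replicate moment recursions of the Euler leap (separating bias
  from Monte Carlo error); a truncated CME solver for single-species
  networks; conservation-law extraction.
* **Error analysis** — weak errors against any reference, bias/MC
  decomposition, standard-error floors, and log-log convergence-order fits.
* **Fixtures** — five benchmark systems (`decay`, `chain5`,
  `michaelis_menten`, `two_enzyme`, `schlogl`) with their customary
  constants, plus a random linear-network generator and a YAML config
  schema.

## Worked example

Pure decay X →(k=0.1) ∅ from X(0) = 10⁴ at T = 10.4, where everything is
known in closed form:

```python
import tauleapx as tx

net, defaults = tx.load_system("decay")
oracle = tx.LinearMomentOracle.from_network(net)
mu_T = tx.analytic_mean_linear(oracle, 10.4)[0]

proto = tx.LeapProtocol(tau=0.8, T=10.4, S=100_000, seed=42)
plain = tx.run_ensemble(net, proto)
table = tx.extrapolated_run(net, proto, levels=1)
apex = table.apex
n, p = tx.binomial_reconstruct(apex.mean[0], apex.variance[0])
```

prints (via the obvious `print` statements):

```
exact mean          E(X(10.4))  = 3534.5
Euler tau-leap      tau=0.8     = 3382.7  (error 151.8)
extrapolated (xETL) tau=0.8/0.4 = 3537.6  (error 3.01)
reconstructed law   Binomial(n=10348, p=0.34186)
```

The plain Euler leap at the coarse step carries its full O(τ) bias (the
exact infinite-replicate bias at τ = 0.8 is 152.0 molecules); one
extrapolation cancels it, leaving a ~3-molecule error — a ~50-fold
improvement for twice the work. Because the terminal law of pure decay is
binomial, the extrapolated mean and variance reconstruct the entire
distribution.

The same machinery drives the command line:

```sh
tauleapx simulate --system michaelis_menten --method ssa --reps 1000 \
    --seed 1 --out mm_ssa.json
tauleapx extrapolate --system schlogl --tau 0.1 --reps 20000 --seed 8 \
    --split 300 --out schlogl_peaks.json
tauleapx cme --system schlogl --split 300 --out schlogl_cme.csv
tauleapx convergence --system decay --method etl --taus 0.1,0.2,0.4,0.8 \
    --reps 100000 --reference analytic --seed 3 --out decay_err.csv
```

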