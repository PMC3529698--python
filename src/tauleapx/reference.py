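"""Exact reference machinery: linear-network moments, SSA, and a CME solver.

For networks containing only zeroth- and first-order reactions the moment
equations close.  Writing the propensity vector as ``a(x) = C x + d`` and
``W = nu @ C``, the mean obeys ``dmu/dt = W mu + nu d`` with solution

    mu(t) = e^{Wt} mu(0) + e^{Wt} int_0^t e^{-Ws} nu d ds,

and the second-moment matrix ``S(t) = E[x x^T]`` obeys a linear matrix ODE
driven by ``mu(t)``.  Both are evaluated here through a single augmented
matrix exponential, exact to machine precision.

The Euler tau-leap evolves the same moments by discrete recursions
(one step of the mean: ``mu <- (I + tau W) mu + tau nu d``); iterating these
gives the infinite-replicate ("S = inf") value of the leap estimator, which
is what separates bias from Monte Carlo error.

The stochastic simulation algorithm (Direct Method) and a truncated
chemical-master-equation solver for single-species networks provide exact
references for nonlinear systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.linalg import expm
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import expm_multiply

from .networks import (
    LinearDecomposition,
    ReactionNetwork,
    linear_decomposition,
)

__all__ = [
    "LinearMomentOracle",
    "CMEDistribution",
    "analytic_mean_linear",
    "analytic_second_moment_linear",
    "etl_mean_recursion",
    "etl_second_moment_recursion",
    "leading_error_etl_linear",
    "ssa_simulate",
    "ssa_ensemble",
    "cme_solve",
]


# ---------------------------------------------------------------------------
# linear-network moment oracle


@dataclass(frozen=True)
class LinearMomentOracle:
    """Closed moment equations for a linear network.

    ``mu0`` is the initial mean and ``S0`` the initial second-moment matrix;
    for a deterministic start ``S0 = mu0 mu0^T``.
    """

    decomposition: LinearDecomposition
    mu0: np.ndarray
    S0: np.ndarray
    nu: np.ndarray

    @classmethod
    def from_network(cls, net: ReactionNetwork) -> "LinearMomentOracle":
        dec = linear_decomposition(net)
        mu0 = net.initial_state.astype(float)
        return cls(
            decomposition=dec,
            mu0=mu0,
            S0=np.outer(mu0, mu0),
            nu=net.stoich_matrix.astype(float),
        )


def _augmented_generator(oracle: LinearMomentOracle) -> np.ndarray:
    """Constant matrix generating the joint linear flow of (mu, vec S, 1).

    vec(S) is row-major.  dS/dt = W S + S W^T + mu (nu d)^T + (nu d) mu^T
    + nu diag(C mu) nu^T + nu diag(d) nu^T; every term is linear in (mu, S)
    or constant, so the joint system is autonomous linear.
    """
    dec = oracle.decomposition
    W, C, d, nu = dec.W, dec.C, dec.d, oracle.nu
    N = W.shape[0]
    I = np.eye(N)
    b = nu @ d  # forcing of the mean

    L = np.kron(W, I) + np.kron(I, W)  # S -> WS + SW^T, row-major vec
    G = np.zeros((N * N, N))  # mu-coupling
    g = (nu * d) @ nu.T  # nu diag(d) nu^T, constant forcing
    for i in range(N):
        for l in range(N):
            r = i * N + l
            G[r, i] += b[l]  # mu (nu d)^T
            G[r, l] += b[i]  # (nu d) mu^T
            # nu diag(C mu) nu^T : sum_j nu_ij nu_lj (C mu)_j
            G[r, :] += nu[i, :] * nu[l, :] @ C

    n = N + N * N + 1
    A = np.zeros((n, n))
    A[:N, :N] = W
    A[:N, -1] = b
    A[N:-1, :N] = G
    A[N:-1, N:-1] = L
    A[N:-1, -1] = g.ravel()
    return A


def _joint_moments(oracle: LinearMomentOracle, T: float):
    N = oracle.mu0.shape[0]
    A = _augmented_generator(oracle)
    y0 = np.concatenate([oracle.mu0, oracle.S0.ravel(), [1.0]])
    y = expm(A * T) @ y0
    mu = y[:N]
    S = y[N:-1].reshape(N, N)
    return mu, 0.5 * (S + S.T)


def analytic_mean_linear(oracle: LinearMomentOracle, T: float) -> np.ndarray:
    """Exact mean ``mu(T)`` via the augmented matrix exponential."""
    dec = oracle.decomposition
    W, b = dec.W, oracle.nu @ dec.d
    N = W.shape[0]
    A = np.zeros((N + 1, N + 1))
    A[:N, :N] = W
    A[:N, -1] = b
    y = expm(A * T) @ np.concatenate([oracle.mu0, [1.0]])
    return y[:N]


def analytic_second_moment_linear(
    oracle: LinearMomentOracle, T: float
) -> np.ndarray:
    """Exact second-moment matrix ``S(T) = E[x(T) x(T)^T]`` (symmetric)."""
    return _joint_moments(oracle, T)[1]


def etl_mean_recursion(
    oracle: LinearMomentOracle, tau: float, n: int
) -> np.ndarray:
    """Infinite-replicate Euler tau-leap mean after ``n`` steps of size tau."""
    if n < 0:
        raise ValueError("n must be >= 0")
    dec = oracle.decomposition
    A = np.eye(len(oracle.mu0)) + tau * dec.W
    b = tau * (oracle.nu @ dec.d)
    mu = oracle.mu0.copy()
    for _ in range(n):
        mu = A @ mu + b
    return mu


def etl_second_moment_recursion(
    oracle: LinearMomentOracle, tau: float, n: int
) -> np.ndarray:
    """Infinite-replicate Euler tau-leap second moment after ``n`` steps.

    Iterates the exact one-step map of ``S_m = E[x_m x_m^T]`` implied by the
    Poisson update, with ``B_m = diag(C mu_m)`` and ``D = diag(d)``:

        S_{m+1} = (I + tau W) S_m (I + tau W)^T
                  + tau (mu_m b^T + b mu_m^T) + tau^2 (W mu_m b^T + b mu_m^T W^T)
                  + tau^2 b b^T + tau nu B_m nu^T + tau nu D nu^T,

    where ``b = nu d``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    dec = oracle.decomposition
    W, C, d, nu = dec.W, dec.C, dec.d, oracle.nu
    I = np.eye(len(oracle.mu0))
    b = nu @ d
    nuDnu = (nu * d) @ nu.T
    mu = oracle.mu0.copy()
    S = oracle.S0.copy()
    for _ in range(n):
        S = (
            S
            + tau * (W @ S + S @ W.T + np.outer(mu, b) + np.outer(b, mu))
            + tau**2
            * (
                W @ S @ W.T
                + np.outer(W @ mu, b)
                + np.outer(b, W @ mu)
                + np.outer(b, b)
            )
            + tau * (nu * (C @ mu)) @ nu.T
            + tau * nuDnu
        )
        mu = (I + tau * W) @ mu + tau * b
    return 0.5 * (S + S.T)


def leading_error_etl_linear(
    oracle: LinearMomentOracle, tau: float, T: float
) -> np.ndarray:
    """Leading-order bias prediction of the Euler tau-leap mean at time T.

    The O(tau) term of ``mu(T) - E(x_n^tau)`` for a linear network is
    ``e^{WT} (tau T / 2) (W^2 mu(0) + W nu d)``.
    """
    dec = oracle.decomposition
    W, b = dec.W, oracle.nu @ dec.d
    return expm(W * T) @ (0.5 * tau * T * (W @ W @ oracle.mu0 + W @ b))


# ---------------------------------------------------------------------------
# stochastic simulation algorithm (Direct Method)


@njit(cache=True)
def _ssa_core(x0, nu, orders, rates, times, seed):  # pragma: no cover
    np.random.seed(seed)
    N, M = nu.shape
    x = x0.copy()
    a = np.empty(M)
    out = np.empty((len(times), N), dtype=np.int64)
    t = 0.0
    ti = 0
    while True:
        a0 = 0.0
        for j in range(M):
            aj = rates[j]
            for i in range(N):
                o = orders[i, j]
                if o > 0:
                    xi = float(x[i])
                    for q in range(o):
                        aj *= xi - q
                    if o == 2:
                        aj *= 0.5
                    elif o == 3:
                        aj /= 6.0
            if aj < 0.0:
                aj = 0.0
            a[j] = aj
            a0 += aj
        if a0 <= 0.0:
            t_next = np.inf
        else:
            r1 = np.random.random()
            t_next = t + (-np.log(r1) / a0)
        while ti < len(times) and times[ti] < t_next:
            out[ti] = x
            ti += 1
        if ti >= len(times):
            return out
        t = t_next
        r2 = np.random.random()
        thresh = a0 * r2
        c = 0.0
        jsel = M - 1
        for j in range(M):
            c += a[j]
            if thresh <= c:
                jsel = j
                break
        for i in range(N):
            x[i] += nu[i, jsel]


def _spawn_seeds(seed, n) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n).astype(np.int64)


def ssa_simulate(
    net: ReactionNetwork, T: float, seed: int, record_times=None
):
    """One statistically exact SSA (Direct Method) trajectory.

    Returns the state at time ``T`` as an integer vector, or, when
    ``record_times`` is given, the states at those times as an array of
    shape ``(len(record_times), N)``.  Two fresh uniforms drive each event:
    one for the waiting time, one for the reaction index.
    """
    if np.any(net.initial_state < 0):
        raise ValueError("initial state must be nonnegative")
    times = (
        np.array([float(T)])
        if record_times is None
        else np.asarray(record_times, dtype=float)
    )
    out = _ssa_core(
        net.initial_state,
        net.stoich_matrix,
        net.reactant_orders,
        net.rate_constants,
        times,
        _spawn_seeds(seed, 1)[0],
    )
    return out[-1] if record_times is None else out


def ssa_ensemble(net: ReactionNetwork, T: float, n_reps: int, seed: int):
    """Final states of ``n_reps`` independent SSA replicates, shape (S, N).

    Replicate streams are spawned from the master seed, so the ensemble is
    reproducible and each replicate independent.
    """
    seeds = _spawn_seeds(seed, n_reps)
    times = np.array([float(T)])
    out = np.empty((n_reps, net.n_species), dtype=np.int64)
    for s in range(n_reps):
        out[s] = _ssa_core(
            net.initial_state,
            net.stoich_matrix,
            net.reactant_orders,
            net.rate_constants,
            times,
            seeds[s],
        )[0]
    return out


# ---------------------------------------------------------------------------
# truncated CME solver (single dynamic species)


@dataclass(frozen=True)
class CMEDistribution:
    """Probability distribution over a truncated 1-D state lattice."""

    states: np.ndarray  # integer lattice state_lo..state_hi
    probs: np.ndarray
    time: float

    @property
    def state_lo(self) -> int:
        return int(self.states[0])

    @property
    def state_hi(self) -> int:
        return int(self.states[-1])

    def mean(self) -> float:
        return float(self.states @ self.probs)

    def second_moment(self) -> float:
        return float((self.states.astype(float) ** 2) @ self.probs)

    def variance(self) -> float:
        return self.second_moment() - self.mean() ** 2

    def conditional_moments(self, split: float) -> dict:
        """Per-peak conditional mean/second-moment/variance and weights.

        The low peak is states strictly below ``split``; the high peak is
        states at or above it.
        """
        out = {}
        x = self.states.astype(float)
        for label, mask in (
            ("low", x < split),
            ("high", x >= split),
        ):
            w = float(self.probs[mask].sum())
            if w <= 0.0:
                out[label] = {"weight": 0.0, "mean": np.nan,
                              "second_moment": np.nan, "variance": np.nan}
                continue
            m = float(x[mask] @ self.probs[mask]) / w
            s2 = float((x[mask] ** 2) @ self.probs[mask]) / w
            out[label] = {
                "weight": w,
                "mean": m,
                "second_moment": s2,
                "variance": s2 - m * m,
            }
        return out


def cme_solve(
    net: ReactionNetwork,
    T: float,
    state_lo: int = 0,
    state_hi: int | None = None,
    boundary_tol: float = 1e-8,
) -> CMEDistribution:
    """Solve the chemical master equation on a truncated lattice.

    Only single-dynamic-species networks are supported (the CME is then a
    sparse linear ODE on ``state_hi - state_lo + 1`` states, propagated with
    a Krylov matrix-exponential action).  Transitions that would leave the
    lattice are switched off, so probability is conserved exactly; the mass
    accumulated in the two outermost states is checked against
    ``boundary_tol`` and a violation raises.
    """
    if net.n_species != 1:
        raise ValueError("CME solver supports exactly one dynamic species")
    if state_hi is None:
        state_hi = 6 * max(int(net.initial_state[0]), 1)
    states = np.arange(state_lo, state_hi + 1, dtype=np.int64)
    n = len(states)
    x0 = int(net.initial_state[0])
    if not state_lo <= x0 <= state_hi:
        raise ValueError("initial state outside truncation bounds")

    from .networks import propensities as _prop

    a = _prop(net, states[:, None].astype(float))  # (n, M)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for j in range(net.n_reactions):
        v = int(net.stoich_matrix[0, j])
        src = np.arange(n)
        dst = src + v
        ok = (dst >= 0) & (dst < n)
        rows.append(dst[ok])
        cols.append(src[ok])
        vals.append(a[ok, j])
        np.add.at(diag, src[ok], -a[ok, j])
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )

    p0 = np.zeros(n)
    p0[x0 - state_lo] = 1.0
    p = expm_multiply(A * T, p0) if T > 0 else p0
    p = np.clip(p, 0.0, None)
    p /= p.sum()

    edge_mass = p[0] * (state_lo > 0) + p[-1]
    if edge_mass > boundary_tol:
        raise ValueError(
            f"boundary mass {edge_mass:.3e} exceeds {boundary_tol:.1e}; "
            "widen the truncation"
        )
    return CMEDistribution(states=states, probs=p, time=float(T))
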