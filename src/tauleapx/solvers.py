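"""Fixed-step tau-leap solvers and the ensemble moment estimator.

Three fixed-step methods are provided, all firing Poisson-distributed
reaction counts over a step ``tau``:

* **ETL** — Euler tau-leap: ``k_j ~ Poisson(a_j(X_n) tau)``, weak order 1.
* **MPTL** — midpoint tau-leap: propensities evaluated at the deterministic
  half-step predictor ``X' = X_n + (tau/2) nu a(X_n)``.
* **TTTL** — theta-trapezoidal tau-leap: a Poisson predictor over ``theta
  tau`` followed by a corrector over ``(1-theta) tau`` with rates
  ``max(alpha1 a(X') - alpha2 a(X_n), 0)``, where ``alpha1 =
  1/(2 (1-theta) theta)`` and ``alpha2 = ((1-theta)^2 + theta^2) * alpha1``;
  weak order 2.

Populations may go (and stay) negative inside a leap; propensities are
clamped at zero before sampling, so Poisson means remain valid.  The
predictor state ``X'`` is kept real-valued.

Ensembles advance all ``S`` replicates as one vectorized batch from a
single PCG64 stream seeded by the protocol seed, so results are
bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .networks import ReactionNetwork, propensities

__all__ = [
    "LeapProtocol",
    "EnsembleMomentEstimate",
    "MeanFieldSampler",
    "tttl_alphas",
    "etl_step",
    "mptl_step",
    "tttl_step",
    "run_ensemble",
]

METHODS = ("etl", "mptl", "tttl")
DEFAULT_THETA = 0.55


@dataclass(frozen=True)
class LeapProtocol:
    """A fixed-step simulation protocol: ``n_steps * tau == T`` exactly."""

    tau: float
    T: float
    method: str = "etl"
    S: int = 1
    seed: int = 0
    theta: float = DEFAULT_THETA
    keep_states: bool = False

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.S < 1:
            raise ValueError("replicate count S must be >= 1")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")
        n = self.T / self.tau
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ValueError(
                f"T={self.T} is not an integer multiple of tau={self.tau}"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.tau))

    def with_tau(self, tau: float, seed=None) -> "LeapProtocol":
        return LeapProtocol(
            tau=tau,
            T=self.T,
            method=self.method,
            S=self.S,
            seed=self.seed if seed is None else seed,
            theta=self.theta,
            keep_states=self.keep_states,
        )


@dataclass
class EnsembleMomentEstimate:
    """Sample moments of the terminal state over S replicates.

    ``mean`` is the per-species sample mean, ``second_moment`` the full
    ``E_S[x x^T]`` matrix, ``variance`` its diagonal minus ``mean**2``.
    Standard errors are sample SD / sqrt(S).
    """

    mean: np.ndarray
    second_moment: np.ndarray
    variance: np.ndarray
    std_err_mean: np.ndarray
    std_err_second: np.ndarray
    tau: float
    T: float
    S: int
    method: str
    seed: int
    final_states: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_states(
        cls, states, *, tau, T, method, seed, keep_states=False, **meta
    ) -> "EnsembleMomentEstimate":
        x = np.asarray(states, dtype=float)
        S = x.shape[0]
        mean = x.mean(axis=0)
        second = (x.T @ x) / S
        var = np.diag(second) - mean**2
        sd = np.sqrt(np.clip(var, 0.0, None))
        x2 = x**2
        sd2 = x2.std(axis=0)
        return cls(
            mean=mean,
            second_moment=second,
            variance=var,
            std_err_mean=sd / np.sqrt(S),
            std_err_second=sd2 / np.sqrt(S),
            tau=float(tau),
            T=float(T),
            S=S,
            method=method,
            seed=seed,
            final_states=np.asarray(states) if keep_states else None,
            meta=dict(meta),
        )


class MeanFieldSampler:
    """Test hook: a 'Poisson sampler' that returns the mean exactly.

    Substituting it for the RNG turns the ETL into the explicit Euler method
    on the deterministic reaction-rate equations.
    """

    def poisson(self, lam, size=None):
        lam = np.asarray(lam, dtype=float)
        return lam if size is None else np.broadcast_to(lam, size).copy()


def tttl_alphas(theta: float):
    """Trapezoidal corrector coefficients; ``alpha1 - alpha2 == 1`` always."""
    a1 = 1.0 / (2.0 * (1.0 - theta) * theta)
    a2 = ((1.0 - theta) ** 2 + theta**2) * a1
    return a1, a2


def etl_step(net: ReactionNetwork, state, tau: float, rng):
    """One Euler tau-leap step; ``state`` may be a batch ``(..., N)``."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    a = propensities(net, state)
    k = rng.poisson(a * tau)
    return np.asarray(state) + k @ net.stoich_matrix.T


def mptl_step(net: ReactionNetwork, state, tau: float, rng):
    """One midpoint tau-leap step (deterministic half-step predictor)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    x = np.asarray(state)
    a = propensities(net, x)
    x_mid = x + 0.5 * tau * (a @ net.stoich_matrix.T)
    k = rng.poisson(propensities(net, x_mid) * tau)
    return x + k @ net.stoich_matrix.T


def tttl_step(net: ReactionNetwork, state, tau: float, theta: float, rng):
    """One theta-trapezoidal tau-leap step (predictor + clamped corrector)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    a1, a2 = tttl_alphas(theta)
    x = np.asarray(state)
    a_n = propensities(net, x)
    k_pred = rng.poisson(a_n * (theta * tau))
    x_pred = x + k_pred @ net.stoich_matrix.T
    l = np.clip(a1 * propensities(net, x_pred) - a2 * a_n, 0.0, None)
    k = rng.poisson(l * ((1.0 - theta) * tau))
    return x_pred + k @ net.stoich_matrix.T


def _advance(net, states, protocol: LeapProtocol, rng):
    step = protocol.method
    for _ in range(protocol.n_steps):
        if step == "etl":
            states = etl_step(net, states, protocol.tau, rng)
        elif step == "mptl":
            states = mptl_step(net, states, protocol.tau, rng)
        else:
            states = tttl_step(net, states, protocol.tau, protocol.theta, rng)
    return states


def run_ensemble(
    net: ReactionNetwork, protocol: LeapProtocol, rng=None
) -> EnsembleMomentEstimate:
    """Run S independent replicates of a fixed-step method to time T.

    Returns the terminal-state sample moments.  Pass a custom ``rng`` (e.g.
    :class:`MeanFieldSampler`) to replace the Poisson sampler; by default a
    fresh ``numpy.random.Generator`` is seeded from ``protocol.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    states = np.broadcast_to(
        net.initial_state.astype(np.int64), (protocol.S, net.n_species)
    ).copy()
    states = _advance(net, states, protocol, rng)
    return EnsembleMomentEstimate.from_states(
        states,
        tau=protocol.tau,
        T=protocol.T,
        method=protocol.method,
        seed=protocol.seed,
        keep_states=protocol.keep_states,
        theta=protocol.theta if protocol.method == "tttl" else None,
    )
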