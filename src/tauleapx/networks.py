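"""Reaction networks, mass-action propensities, and linear structure.

A well-mixed chemical system with N species and M reactions is described by
an integer state vector ``x`` of molecule counts, a stoichiometric matrix
``nu`` (N x M, net change of each species per firing) and mass-action
propensity functions ``a_j(x)``.  Propensities use Gillespie's combinatorial
convention: a reaction consuming two identical molecules has propensity
``k * x * (x - 1) / 2``, three identical molecules ``k * x(x-1)(x-2) / 6``.

Species whose populations are held fixed by the environment (``buffered``)
are folded into effective rate constants at build time and do not appear in
the dynamic state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReactionNetwork",
    "LinearDecomposition",
    "NonlinearNetworkError",
    "build_network",
    "propensities",
    "linear_decomposition",
    "conservation_laws",
]

MAX_MOLECULARITY = 3


class NonlinearNetworkError(ValueError):
    """Raised when a linear-only operation meets a bimolecular+ reaction."""


@dataclass(frozen=True)
class ReactionNetwork:
    """A mass-action reaction network over the dynamic (non-buffered) species.

    Attributes
    ----------
    species_names : tuple of str
        Names of the N dynamic species.
    initial_state : ndarray of int64, shape (N,)
        Initial molecule counts.
    stoich_matrix : ndarray of int64, shape (N, M)
        Net change ``nu[i, j]`` of species i when reaction j fires.
    reactant_orders : ndarray of int64, shape (N, M)
        Molecularity of species i as a reactant of reaction j.
    rate_constants : ndarray of float, shape (M,)
        Effective rate constants (buffered-species factors folded in).
    buffered : dict
        Buffered species name -> held count (informational; already folded).
    """

    species_names: tuple
    initial_state: np.ndarray
    stoich_matrix: np.ndarray
    reactant_orders: np.ndarray
    rate_constants: np.ndarray
    buffered: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return self.stoich_matrix.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.stoich_matrix.shape[1]

    def is_linear(self) -> bool:
        """True when every reaction is zeroth- or first-order."""
        return bool(self.reactant_orders.sum(axis=0).max(initial=0) <= 1)

    def __eq__(self, other):
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return (
            self.species_names == other.species_names
            and np.array_equal(self.initial_state, other.initial_state)
            and np.array_equal(self.stoich_matrix, other.stoich_matrix)
            and np.array_equal(self.reactant_orders, other.reactant_orders)
            and np.allclose(self.rate_constants, other.rate_constants)
            and self.buffered == other.buffered
        )


@dataclass(frozen=True)
class LinearDecomposition:
    """Affine propensity structure ``a(x) = C x + d`` with ``W = nu @ C``."""

    C: np.ndarray  # (M, N)
    d: np.ndarray  # (M,)
    W: np.ndarray  # (N, N)


def _falling_factorial_over_factorial(x, order):
    """``x (x-1) ... (x-order+1) / order!`` elementwise; order 0 gives 1."""
    out = np.ones_like(x, dtype=float)
    for q in range(order):
        out = out * (x - q)
    return out / math.factorial(order)


def build_network(spec: dict) -> ReactionNetwork:
    """Build and validate a :class:`ReactionNetwork` from a structured spec.

    Parameters
    ----------
    spec : dict
        ``{"species": [{"name", "initial", "buffered"?}, ...],
        "reactions": [{"reactants": {name: molecularity},
        "products": {name: count}, "rate": k}, ...]}``.

    Buffered species are removed from the dynamic state; their (constant)
    combinatorial count factor multiplies the rate constant of every
    reaction consuming them, and their appearance as products is dropped.
    """
    species = spec["species"]
    reactions = spec["reactions"]
    if not species or not reactions:
        raise ValueError("network needs at least one species and one reaction")

    counts = {}
    buffered = {}
    dynamic = []
    for s in species:
        name = s["name"]
        if name in counts:
            raise ValueError(f"duplicate species {name!r}")
        init = int(s["initial"])
        if init < 0:
            raise ValueError(f"negative initial count for {name!r}")
        counts[name] = init
        if s.get("buffered", False):
            buffered[name] = init
        else:
            dynamic.append(name)

    N, M = len(dynamic), len(reactions)
    if N < 1:
        raise ValueError("at least one dynamic (non-buffered) species required")
    index = {name: i for i, name in enumerate(dynamic)}
    nu = np.zeros((N, M), dtype=np.int64)
    orders = np.zeros((N, M), dtype=np.int64)
    rates = np.empty(M, dtype=float)

    for j, rxn in enumerate(reactions):
        k = float(rxn["rate"])
        if k < 0:
            raise ValueError(f"reaction {j}: negative rate constant")
        reactants = rxn.get("reactants", {}) or {}
        products = rxn.get("products", {}) or {}
        total_order = sum(int(o) for o in reactants.values())
        if total_order > MAX_MOLECULARITY:
            raise ValueError(f"reaction {j}: total molecularity {total_order} > 3")
        for name, o in reactants.items():
            o = int(o)
            if o < 0:
                raise ValueError(f"reaction {j}: negative molecularity for {name!r}")
            if name in buffered:
                k *= _falling_factorial_over_factorial(
                    np.float64(buffered[name]), o
                )
            elif name in index:
                orders[index[name], j] = o
                nu[index[name], j] -= o
            else:
                raise ValueError(f"reaction {j}: unknown species {name!r}")
        for name, c in products.items():
            c = int(c)
            if name in buffered:
                continue
            if name not in index:
                raise ValueError(f"reaction {j}: unknown species {name!r}")
            nu[index[name], j] += c
        rates[j] = k
        if not np.any(nu[:, j]) and not np.any(orders[:, j]):
            raise ValueError(f"reaction {j}: touches no dynamic species")

    x0 = np.array([counts[name] for name in dynamic], dtype=np.int64)
    return ReactionNetwork(
        species_names=tuple(dynamic),
        initial_state=x0,
        stoich_matrix=nu,
        reactant_orders=orders,
        rate_constants=rates,
        buffered=dict(buffered),
    )


def propensities(net: ReactionNetwork, state) -> np.ndarray:
    """Mass-action propensities ``a(state)``, clamped at zero.

    ``state`` may have any leading batch shape ``(..., N)``; the result has
    shape ``(..., M)``.  Counts may be non-integer or negative (both occur
    inside leap steps); any negative formula value is clamped to 0 so Poisson
    means stay valid.
    """
    x = np.asarray(state, dtype=float)
    if x.shape[-1] != net.n_species:
        raise ValueError(
            f"state length {x.shape[-1]} != number of species {net.n_species}"
        )
    a = np.broadcast_to(
        net.rate_constants, x.shape[:-1] + (net.n_reactions,)
    ).copy()
    for j in range(net.n_reactions):
        for i in np.nonzero(net.reactant_orders[:, j])[0]:
            o = int(net.reactant_orders[i, j])
            a[..., j] *= _falling_factorial_over_factorial(x[..., i], o)
    return np.clip(a, 0.0, None, out=a)


def linear_decomposition(net: ReactionNetwork) -> LinearDecomposition:
    """Extract ``a(x) = C x + d`` and ``W = nu @ C`` for a linear network.

    Raises
    ------
    NonlinearNetworkError
        If any reaction is bimolecular or higher.
    """
    if not net.is_linear():
        raise NonlinearNetworkError(
            "network contains a reaction of order >= 2; no affine "
            "propensity decomposition exists"
        )
    M, N = net.n_reactions, net.n_species
    C = np.zeros((M, N))
    d = np.zeros(M)
    for j in range(M):
        nz = np.nonzero(net.reactant_orders[:, j])[0]
        if nz.size == 0:
            d[j] = net.rate_constants[j]
        else:
            C[j, nz[0]] = net.rate_constants[j]
    W = net.stoich_matrix @ C
    return LinearDecomposition(C=C, d=d, W=W)


def conservation_laws(net: ReactionNetwork) -> list:
    """Integer basis of the left null space of the stoichiometric matrix.

    Each returned vector ``c`` satisfies ``c @ nu == 0`` exactly, so
    ``c @ x`` is invariant along every SSA or tau-leap trajectory.
    """
    import sympy

    nu_t = sympy.Matrix(net.stoich_matrix.T.tolist())
    basis = []
    for v in nu_t.nullspace():
        denoms = [sympy.fraction(sympy.nsimplify(e))[1] for e in v]
        scale = sympy.lcm([sympy.Integer(d) for d in denoms]) if denoms else 1
        vi = np.array([int(e * scale) for e in v], dtype=np.int64)
        g = np.gcd.reduce(np.abs(vi[vi != 0])) if np.any(vi) else 1
        vi //= max(int(g), 1)
        if vi[vi != 0].size and vi[vi != 0][0] < 0:
            vi = -vi
        basis.append(vi)
    return basis
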