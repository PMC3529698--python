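"""Benchmark system fixtures, network config IO, and random linear networks.

Five classic test systems are built in, each with its customary constants,
initial counts, horizon T and stepsize ladder:

* ``decay`` — pure particle decay X -> 0, k = 0.1, X(0) = 1e4, T = 10.4.
* ``chain5`` — closed five-species chain X1 -> X2 -> ... -> X5 -> X1,
  all rates 0.3, T = 16; total population is conserved.
* ``michaelis_menten`` — enzyme-substrate kinetics, four species and three
  reactions, T = 16.
* ``two_enzyme`` — two-enzyme mutual inhibition, eight species and twelve
  reactions, bistable in the two products, T = 3.2.
* ``schlogl`` — the bimodal Schlogl system; the A and B pools are buffered
  at 1e5 and 2e5, leaving a single dynamic species, T = 5.

Configs round-trip through a small versioned YAML schema.
"""

from __future__ import annotations

import copy
import os

import numpy as np
import yaml

from .networks import ReactionNetwork, build_network

__all__ = [
    "FIXTURES",
    "SCHEMA",
    "load_system",
    "system_spec",
    "save_system",
    "generate_random_linear_network",
]

SCHEMA = "tauleapx-network/1"


def _geometric_ladder(coarsest: float, n: int = 5):
    return [coarsest / 2**i for i in range(n)][::-1]


FIXTURES: dict = {
    "decay": {
        "schema": SCHEMA,
        "species": [{"name": "X", "initial": 10_000}],
        "reactions": [{"reactants": {"X": 1}, "products": {}, "rate": 0.1}],
        "defaults": {"T": 10.4, "taus": _geometric_ladder(0.8)},
    },
    "chain5": {
        "schema": SCHEMA,
        "species": [
            {"name": "X1", "initial": 2500},
            {"name": "X2", "initial": 1875},
            {"name": "X3", "initial": 1875},
            {"name": "X4", "initial": 1875},
            {"name": "X5", "initial": 1875},
        ],
        "reactions": [
            {"reactants": {f"X{j}": 1}, "products": {f"X{j % 5 + 1}": 1}, "rate": 0.3}
            for j in range(1, 6)
        ],
        "defaults": {"T": 16.0, "taus": _geometric_ladder(1.6)},
    },
    "michaelis_menten": {
        "schema": SCHEMA,
        "species": [
            {"name": "X1", "initial": 10_000},
            {"name": "X2", "initial": 2000},
            {"name": "X3", "initial": 20_000},
            {"name": "X4", "initial": 0},
        ],
        "reactions": [
            {"reactants": {"X1": 1, "X2": 1}, "products": {"X3": 1}, "rate": 1e-5},
            {"reactants": {"X3": 1}, "products": {"X1": 1, "X2": 1}, "rate": 0.2},
            {"reactants": {"X3": 1}, "products": {"X2": 1, "X4": 1}, "rate": 0.2},
        ],
        "defaults": {"T": 16.0, "taus": _geometric_ladder(1.6)},
    },
    "two_enzyme": {
        "schema": SCHEMA,
        "species": [
            {"name": "A", "initial": 20_000},
            {"name": "B", "initial": 15_000},
            {"name": "EA", "initial": 9500},
            {"name": "EB", "initial": 9500},
            {"name": "EAB", "initial": 2000},
            {"name": "EAB2", "initial": 500},
            {"name": "EBA", "initial": 2000},
            {"name": "EBA2", "initial": 500},
        ],
        "reactions": [
            {"reactants": {"EA": 1}, "products": {"EA": 1, "A": 1}, "rate": 15.0},
            {"reactants": {"EB": 1}, "products": {"EB": 1, "B": 1}, "rate": 15.0},
            {"reactants": {"EA": 1, "B": 1}, "products": {"EAB": 1}, "rate": 5e-4},
            {"reactants": {"EAB": 1}, "products": {"EA": 1, "B": 1}, "rate": 2.0},
            {"reactants": {"EAB": 1, "B": 1}, "products": {"EAB2": 1}, "rate": 1e-3},
            {"reactants": {"EAB2": 1}, "products": {"EAB": 1, "B": 1}, "rate": 6.0},
            {"reactants": {"A": 1}, "products": {}, "rate": 5.0},
            {"reactants": {"EB": 1, "A": 1}, "products": {"EBA": 1}, "rate": 5e-4},
            {"reactants": {"EBA": 1}, "products": {"EB": 1, "A": 1}, "rate": 2.0},
            {"reactants": {"EBA": 1, "A": 1}, "products": {"EBA2": 1}, "rate": 1e-3},
            {"reactants": {"EBA2": 1}, "products": {"EBA": 1, "A": 1}, "rate": 6.0},
            {"reactants": {"B": 1}, "products": {}, "rate": 5.0},
        ],
        "defaults": {"T": 3.2, "taus": _geometric_ladder(0.08)},
    },
    "schlogl": {
        "schema": SCHEMA,
        "species": [
            {"name": "X", "initial": 250},
            {"name": "A", "initial": 100_000, "buffered": True},
            {"name": "B", "initial": 200_000, "buffered": True},
        ],
        "reactions": [
            {"reactants": {"A": 1, "X": 2}, "products": {"X": 3}, "rate": 3e-7},
            {"reactants": {"X": 3}, "products": {"A": 1, "X": 2}, "rate": 1e-4},
            {"reactants": {"B": 1}, "products": {"X": 1}, "rate": 1e-3},
            {"reactants": {"X": 1}, "products": {"B": 1}, "rate": 3.5},
        ],
        "defaults": {
            "T": 5.0,
            "taus": _geometric_ladder(0.2),
            "split_points": [300.0],
            "cme_bounds": [0, 1500],
        },
    },
}


def _validate_spec(spec: dict, source: str) -> None:
    if not isinstance(spec, dict):
        raise ValueError(f"{source}: config must be a mapping")
    if spec.get("schema") != SCHEMA:
        raise ValueError(
            f"{source}: field 'schema' must be {SCHEMA!r}, got "
            f"{spec.get('schema')!r}"
        )
    for fld in ("species", "reactions"):
        if fld not in spec or not isinstance(spec[fld], list) or not spec[fld]:
            raise ValueError(f"{source}: field {fld!r} missing or empty")
    for i, s in enumerate(spec["species"]):
        if "name" not in s or "initial" not in s:
            raise ValueError(f"{source}: species[{i}] needs 'name' and 'initial'")
    for i, r in enumerate(spec["reactions"]):
        if "rate" not in r:
            raise ValueError(f"{source}: reactions[{i}] needs 'rate'")


def system_spec(name_or_path: str) -> dict:
    """The raw config dict for a fixture name or a YAML file path."""
    if name_or_path in FIXTURES:
        return copy.deepcopy(FIXTURES[name_or_path])
    if os.path.exists(name_or_path):
        with open(name_or_path) as fh:
            spec = yaml.safe_load(fh)
        _validate_spec(spec, name_or_path)
        return spec
    raise ValueError(
        f"unknown system {name_or_path!r}; built-in fixtures are "
        f"{sorted(FIXTURES)}"
    )


def load_system(name_or_path: str):
    """Build a network plus its default protocol from a fixture or file.

    Returns ``(net, defaults)`` where ``defaults`` carries the customary
    horizon ``T``, stepsize ladder ``taus`` and, where relevant, split
    points and CME truncation bounds.
    """
    spec = system_spec(name_or_path)
    net = build_network(spec)
    return net, dict(spec.get("defaults", {}))


def save_system(spec_or_name, path: str) -> None:
    """Serialize a config dict (or fixture name) to YAML."""
    spec = (
        system_spec(spec_or_name) if isinstance(spec_or_name, str) else spec_or_name
    )
    with open(path, "w") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)


def generate_random_linear_network(
    N: int,
    M: int,
    seed: int,
    rate_range=(0.05, 0.5),
    x0_range=(50, 5000),
) -> ReactionNetwork:
    """A random network of decay, conversion and production reactions.

    Every reaction is zeroth- or first-order, so the closed moment
    recursions apply; intended as a property-test fixture for the linear
    oracles.  Reproducible for a given seed.
    """
    if N < 1 or M < 1:
        raise ValueError("need N >= 1 species and M >= 1 reactions")
    rng = np.random.default_rng(seed)
    names = [f"S{i}" for i in range(N)]
    species = [
        {"name": n, "initial": int(rng.integers(*x0_range))} for n in names
    ]
    reactions = []
    for _ in range(M):
        kind = rng.choice(["decay", "conversion", "production"])
        k = float(rng.uniform(*rate_range))
        if kind == "production":
            tgt = names[rng.integers(N)]
            reactions.append({"reactants": {}, "products": {tgt: 1}, "rate": k})
        elif kind == "decay" or N == 1:
            src = names[rng.integers(N)]
            reactions.append({"reactants": {src: 1}, "products": {}, "rate": k})
        else:
            src, tgt = rng.choice(N, size=2, replace=False)
            reactions.append(
                {
                    "reactants": {names[src]: 1},
                    "products": {names[tgt]: 1},
                    "rate": k,
                }
            )
    return build_network(
        {"schema": SCHEMA, "species": species, "reactions": reactions}
    )
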