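"""Richardson/Romberg extrapolation of weak moment estimates.

A fixed-step method of weak order ``k`` has a global error expansion in its
stepsize, ``E f(x(T)) - E f(x_n^tau) = e_k tau^k + e_{k+1} tau^{k+1} + ...``.
Combining estimates at stepsizes ``tau`` and ``tau/p`` with weights

    (p^k * z_fine - z_coarse) / (p^k - 1)

cancels the leading term and yields an order ``k+1`` estimate; repeating the
combination column by column builds the familiar Romberg table.  For the
Euler tau-leap ``k = 1`` and ``p = 2`` this is simply ``2 z_{tau/2} -
z_tau``.

Multimodal systems are handled by partitioning the terminal states of each
ensemble at chosen split points and extrapolating the conditional moments of
each peak separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .networks import ReactionNetwork
from .solvers import EnsembleMomentEstimate, LeapProtocol, run_ensemble

__all__ = [
    "MomentRecord",
    "RombergTable",
    "PeakPartition",
    "BASE_ORDER",
    "extrapolate_pair",
    "romberg_extrapolate",
    "extrapolated_run",
    "multimodal_extrapolate",
    "suggest_split_points",
    "binomial_reconstruct",
]

#: default weak order of each base method, used to pick extrapolation weights
BASE_ORDER = {"etl": 1, "mptl": 2, "tttl": 2}


@dataclass(frozen=True)
class MomentRecord:
    """A (mean, second-moment, variance) triple with provenance metadata.

    ``variance`` is tracked as a functional in its own right: extrapolation
    combines the per-stepsize variances with the same weights as the other
    moments.  (Deriving it from the extrapolated mean and second moment
    instead is numerically treacherous — the mean's higher-order residual,
    multiplied by ``2 mu ~ 1e3``, can exceed the variance itself at coarse
    stepsizes; that derived quantity is still available as
    :attr:`variance_from_moments`.)
    """

    mean: np.ndarray
    second_moment: np.ndarray
    tau: float
    T: float
    order: int
    method: str = ""
    variance: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.variance is None:
            v = (np.diag(np.atleast_2d(self.second_moment))
                 - np.asarray(self.mean) ** 2)
            object.__setattr__(self, "variance", v)

    @property
    def variance_from_moments(self) -> np.ndarray:
        v = np.diag(np.atleast_2d(self.second_moment)) - np.asarray(self.mean) ** 2
        if np.any(v < 0):
            warnings.warn(
                "moments-derived variance is negative; reported as-is",
                stacklevel=2,
            )
        return v

    @classmethod
    def from_estimate(cls, est, order: int) -> "MomentRecord":
        var = getattr(est, "variance", None)
        return cls(
            mean=np.asarray(est.mean, dtype=float),
            second_moment=np.atleast_2d(np.asarray(est.second_moment, float)),
            tau=float(est.tau),
            T=float(est.T),
            order=int(order),
            method=getattr(est, "method", ""),
            variance=None if var is None else np.atleast_1d(np.asarray(var, float)),
            meta=dict(getattr(est, "meta", {}) or {}),
        )


def _as_record(est, order: int) -> MomentRecord:
    if isinstance(est, MomentRecord):
        return est
    return MomentRecord.from_estimate(est, order)


def extrapolate_pair(coarse, fine, k: int | None = None, p: int = 2) -> MomentRecord:
    """Cancel the leading ``tau^k`` bias of two estimates at ``tau`` and ``tau/p``.

    ``coarse`` and ``fine`` may be :class:`EnsembleMomentEstimate` or
    :class:`MomentRecord`; they must share the system horizon ``T`` and
    method, and satisfy ``coarse.tau == p * fine.tau``.  The weights
    ``p^k/(p^k-1)`` and ``-1/(p^k-1)`` sum to one, so identical inputs pass
    through unchanged.
    """
    if k is None:
        k = BASE_ORDER.get(getattr(coarse, "method", ""), 1)
    rc = _as_record(coarse, k)
    rf = _as_record(fine, k)
    if abs(rf.tau * p - rc.tau) > 1e-9 * rc.tau:
        raise ValueError(
            f"stepsize ratio mismatch: coarse tau={rc.tau}, fine tau={rf.tau}, p={p}"
        )
    if abs(rc.T - rf.T) > 1e-12 * max(1.0, abs(rc.T)):
        raise ValueError("estimates have different time horizons")
    if rc.method and rf.method and rc.method != rf.method:
        raise ValueError("estimates come from different methods")
    w = float(p**k)
    mean = (w * rf.mean - rc.mean) / (w - 1.0)
    second = (w * rf.second_moment - rc.second_moment) / (w - 1.0)
    var = (w * rf.variance - rc.variance) / (w - 1.0)
    return MomentRecord(
        mean=mean,
        second_moment=second,
        tau=rc.tau,
        T=rc.T,
        order=k + 1,
        method=rc.method,
        variance=var,
        meta={"extrapolated_from": (rc.tau, rf.tau), "p": p, "k": k},
    )


@dataclass(frozen=True)
class RombergTable:
    """Triangular grid of repeatedly extrapolated moment records.

    ``columns[0]`` holds the raw estimates (coarsest stepsize first);
    ``columns[c]`` holds estimates of effective order ``base_order + c`` and
    has one fewer entry than ``columns[c-1]``.
    """

    base_order: int
    ratio: int
    columns: list

    @property
    def apex(self) -> MomentRecord:
        return self.columns[-1][0]

    def entry(self, column: int, q: int) -> MomentRecord:
        return self.columns[column][q]


def romberg_extrapolate(estimates, base_order: int = 1, p: int = 2) -> RombergTable:
    """Build the full Romberg table from estimates on a geometric tau ladder.

    ``estimates`` are ordered coarsest to finest with stepsize ratio ``p``;
    column ``c`` is produced from column ``c-1`` with weight exponent
    ``base_order + c - 1`` (the order being annihilated).
    """
    ests = [_as_record(e, base_order) for e in estimates]
    if len(ests) < 2:
        raise ValueError("need at least two estimates to extrapolate")
    for a, b in zip(ests, ests[1:]):
        if abs(b.tau * p - a.tau) > 1e-9 * a.tau:
            raise ValueError(
                "stepsizes are not a geometric ladder with integer ratio "
                f"{p}: {[e.tau for e in ests]}"
            )
    columns = [ests]
    while len(columns[-1]) > 1:
        prev = columns[-1]
        k_eff = base_order + len(columns) - 1
        columns.append(
            [
                extrapolate_pair(prev[q], prev[q + 1], k=k_eff, p=p)
                for q in range(len(prev) - 1)
            ]
        )
    return RombergTable(base_order=base_order, ratio=p, columns=columns)


def extrapolated_run(
    net: ReactionNetwork,
    protocol: LeapProtocol,
    levels: int = 1,
    base_order: int | None = None,
) -> RombergTable:
    """Run ``levels + 1`` ensembles at tau, tau/2, ... and extrapolate.

    Each stepsize gets an independent seed derived from the protocol seed
    (no coupling between the coarse and fine ensembles).  Returns the full
    Romberg table; its ``apex`` is the highest-order moment record.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if base_order is None:
        base_order = BASE_ORDER[protocol.method]
    seeds = np.random.SeedSequence(protocol.seed).generate_state(levels + 1)
    ests = [
        run_ensemble(
            net, protocol.with_tau(protocol.tau / 2**lev, seed=int(seeds[lev]))
        )
        for lev in range(levels + 1)
    ]
    return romberg_extrapolate(ests, base_order=base_order, p=2)


@dataclass(frozen=True)
class PeakPartition:
    """Conditional moments of the replicate subsets around each mode."""

    split_points: tuple
    subset_sizes: tuple
    estimates: list  # one EnsembleMomentEstimate per peak


def _partition(
    est: EnsembleMomentEstimate, split_points, species: int,
    allow_empty: bool = False,
):
    if est.final_states is None:
        raise ValueError("final states were not retained; rerun with keep_states")
    edges = [-np.inf, *sorted(float(s) for s in split_points), np.inf]
    x = est.final_states[:, species].astype(float)
    subsets, sizes = [], []
    for lo, hi in zip(edges, edges[1:]):
        mask = (x >= lo) & (x < hi)
        if not mask.any():
            if allow_empty:
                subsets.append(None)
                sizes.append(0)
                continue
            raise ValueError(
                f"empty replicate subset in [{lo}, {hi}) at tau={est.tau}"
            )
        sub = EnsembleMomentEstimate.from_states(
            est.final_states[mask],
            tau=est.tau,
            T=est.T,
            method=est.method,
            seed=est.seed,
            peak_window=(lo, hi),
        )
        subsets.append(sub)
        sizes.append(int(mask.sum()))
    return PeakPartition(
        split_points=tuple(sorted(float(s) for s in split_points)),
        subset_sizes=tuple(sizes),
        estimates=subsets,
    )


def multimodal_extrapolate(
    coarse: EnsembleMomentEstimate,
    fine: EnsembleMomentEstimate,
    split_points,
    k: int | None = None,
    p: int = 2,
    species: int = 0,
) -> list:
    """Per-peak extrapolation for multimodal terminal distributions.

    The replicates of each ensemble are partitioned at ``split_points`` on
    the given species; conditional moments are formed per peak and the
    coarse/fine pair of each peak is extrapolated.  With no split points —
    or splits outside the data range — the result is the ordinary global
    extrapolation.  A subset empty at only one of the two stepsizes is an
    error (the peak pairing would be meaningless).
    """
    parts_c = _partition(coarse, split_points, species, allow_empty=True)
    parts_f = _partition(fine, split_points, species, allow_empty=True)
    out = []
    for pc, pf in zip(parts_c.estimates, parts_f.estimates):
        if pc is None and pf is None:
            continue
        if pc is None or pf is None:
            bad = coarse if pc is None else fine
            raise ValueError(
                f"empty replicate subset at tau={bad.tau} only; "
                "choose split points supported at both stepsizes"
            )
        rec = extrapolate_pair(pc, pf, k=k, p=p)
        rec = replace(
            rec,
            meta={
                **rec.meta,
                "peak_window": pc.meta.get("peak_window"),
                "subset_sizes": (pc.S, pf.S),
            },
        )
        out.append(rec)
    return out


def suggest_split_points(final_states, bins: int = 60, smooth: float = 2.0):
    """Candidate mode-separating thresholds from a smoothed histogram.

    Returns one threshold per gap between prominent modes of a
    Gaussian-smoothed histogram (the deepest point of each gap); empty for
    unimodal data.  Requires at least 1000 samples for the histogram to be
    trustworthy.
    """
    from scipy.ndimage import gaussian_filter1d
    from scipy.signal import find_peaks

    x = np.asarray(final_states, dtype=float).ravel()
    if x.size < 1000:
        raise ValueError("need at least 1000 terminal states")
    hist, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    h = gaussian_filter1d(hist.astype(float), smooth)
    modes, _ = find_peaks(h, prominence=0.05 * h.max())
    if len(modes) < 2:
        return []
    splits = []
    for lo, hi in zip(modes, modes[1:]):
        best = lo + 1 + int(np.argmin(h[lo + 1 : hi]))
        splits.append(float(centers[best]))
    return splits


def binomial_reconstruct(mean: float, variance: float):
    """Invert binomial moments: ``n = round(mean^2 / (mean - variance))``.

    When the terminal distribution is known to be binomial (e.g. pure decay
    from a deterministic start), the extrapolated mean and variance fix the
    whole distribution.  Raises when ``variance >= mean`` (no binomial with
    those moments) or when either is nonpositive.
    """
    if mean <= 0 or variance <= 0:
        raise ValueError("mean and variance must be positive")
    if variance >= mean:
        raise ValueError(
            "variance >= mean: no binomial distribution has these moments"
        )
    n = int(round(mean * mean / (mean - variance)))
    return n, mean / n
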