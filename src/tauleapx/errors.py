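"""Weak-error measurement, bias/Monte-Carlo decomposition, and order fits.

The weak error of an ensemble estimator is ``|E f(x(T)) - E_S f(x_n^tau)|``
for the mean and second moment.  For linear networks it splits exactly into

    bias = E f(x(T)) - E_inf f(x_n^tau)   (stepsize truncation error)
    mc   = E_inf f(x_n^tau) - E_S f(...)  (finite-sample error, ~ C/sqrt(S))

where the infinite-replicate value comes from the closed moment recursions.
Convergence orders are estimated as least-squares slopes of log error
against log tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ErrorReport",
    "weak_error",
    "split_error",
    "mc_floor",
    "convergence_order",
    "coefficient_of_variation",
]


def _mean_of(rec) -> np.ndarray:
    return np.atleast_1d(np.asarray(rec.mean, dtype=float))


def _second_of(rec) -> np.ndarray:
    return np.atleast_2d(np.asarray(rec.second_moment, dtype=float))


@dataclass
class ErrorReport:
    """Per-stepsize weak errors with optional fitted slopes."""

    taus: list = field(default_factory=list)
    mean_errors: list = field(default_factory=list)  # per-species vectors
    second_errors: list = field(default_factory=list)  # per-species diagonals
    reference: str = ""
    meta: dict = field(default_factory=dict)

    def add(self, tau: float, entry: dict):
        self.taus.append(float(tau))
        self.mean_errors.append(entry["mean_error"])
        self.second_errors.append(np.diag(entry["second_error"]))

    def slopes(self, species: int = 0):
        """Fitted (mean, second-moment) convergence orders for one species."""
        taus = np.asarray(self.taus)
        me = np.array([e[species] for e in self.mean_errors])
        se = np.array([e[species] for e in self.second_errors])
        return (
            convergence_order(taus, me),
            convergence_order(taus, se),
        )


def weak_error(reference, estimate) -> dict:
    """Elementwise absolute weak errors of mean and second moment.

    Both arguments need ``mean`` and ``second_moment`` attributes of
    matching shapes (analytic records, recursion records, ensemble
    estimates, or extrapolated records).
    """
    m_ref, m_est = _mean_of(reference), _mean_of(estimate)
    s_ref, s_est = _second_of(reference), _second_of(estimate)
    if m_ref.shape != m_est.shape or s_ref.shape != s_est.shape:
        raise ValueError("reference and estimate moment shapes differ")
    return {
        "mean_error": np.abs(m_ref - m_est),
        "second_error": np.abs(s_ref - s_est),
    }


def split_error(analytic, infinite_S, ensemble) -> tuple:
    """Signed bias and Monte Carlo components of the total weak error.

    ``bias = analytic - infinite_S`` depends only on tau; ``mc = infinite_S
    - ensemble`` depends only on the replicate count.  The two components
    sum exactly to the total signed error ``analytic - ensemble``.
    """
    bias = {
        "mean": _mean_of(analytic) - _mean_of(infinite_S),
        "second": _second_of(analytic) - _second_of(infinite_S),
    }
    mc = {
        "mean": _mean_of(infinite_S) - _mean_of(ensemble),
        "second": _second_of(infinite_S) - _second_of(ensemble),
    }
    return bias, mc


def mc_floor(ensemble) -> dict:
    """Monte Carlo standard errors (sample SD / sqrt(S)) per moment.

    The Monte Carlo error of an S-replicate estimator scales as C/sqrt(S);
    the reported floor is one standard error, by definition — not a bound
    multiplier.
    """
    if ensemble.S < 2:
        raise ValueError("need at least two replicates for a standard error")
    return {
        "mean": np.asarray(ensemble.std_err_mean, dtype=float),
        "second": np.asarray(ensemble.std_err_second, dtype=float),
    }


def convergence_order(taus, errors) -> float:
    """Least-squares slope of log(error) against log(tau).

    Nonpositive errors (possible when an extrapolated estimate sits at the
    Monte Carlo floor) are dropped with a warning rather than failing.
    """
    taus = np.asarray(taus, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if taus.shape != errors.shape:
        raise ValueError("taus and errors must have the same length")
    ok = errors > 0
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} nonpositive error value(s) "
            "from the log-log fit",
            stacklevel=2,
        )
    if ok.sum() < 2:
        raise ValueError("need at least two positive errors to fit a slope")
    slope, _ = np.polyfit(np.log(taus[ok]), np.log(errors[ok]), 1)
    return float(slope)


def coefficient_of_variation(ensemble) -> np.ndarray:
    """Per-species CV: sample standard deviation divided by sample mean."""
    mean = _mean_of(ensemble)
    if np.any(mean == 0):
        raise ValueError("CV undefined for zero mean")
    sd = np.sqrt(np.clip(np.asarray(ensemble.variance, dtype=float), 0.0, None))
    return sd / np.abs(mean)
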