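"""Per-family error-rate (PFER) calculus for stability selection.

Three upper bounds on the expected number of falsely selected variables
are provided, from loosest to tightest:

* ``none`` — the worst-case bound ``q^2 / ((2*pi_thr - 1) * p)``;
* ``unimodal`` — assumes unimodal simultaneous selection probabilities;
* ``r_concave`` — assumes r-concave simultaneous (r = -1/2) and marginal
  (r = -1/4) selection probabilities; evaluated by numeric maximization of
  the tail probability over extremal r-concave distributions.

Given any two of (q, pi_thr, PFER_max) the third is resolved on the
frequency grid of multiples of ``1/(2B)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "ASSUMPTIONS",
    "BoundQuery",
    "CutoffSolution",
    "InfeasibleBoundError",
    "pfer_bound",
    "d_value",
    "solve_cutoff",
    "solve_q",
    "pcer_equivalent",
]

ASSUMPTIONS = ("none", "unimodal", "r_concave")


class InfeasibleBoundError(ValueError):
    """No parameter choice satisfies the requested error bound."""


@dataclass(frozen=True)
class BoundQuery:
    """Inputs of one PFER bound evaluation."""

    q: int
    p: int
    pi_thr: float
    B: int = 50
    assumption: str = "none"

    def __post_init__(self):
        if not (1 <= self.q <= self.p):
            raise ValueError(f"q={self.q} must lie in [1, p={self.p}]")
        if not (0.5 < self.pi_thr <= 1.0):
            raise ValueError(
                f"pi_thr={self.pi_thr} must lie in (0.5, 1]"
            )
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.assumption not in ASSUMPTIONS:
            raise ValueError(
                f"assumption must be one of {ASSUMPTIONS}, got {self.assumption!r}"
            )

    @property
    def theta(self) -> float:
        """Per-fit selection fraction q/p."""
        return self.q / self.p


def _worst_case(q: int, p: int, tau: float) -> float:
    if tau <= 0.5:
        raise ValueError("pi_thr must exceed 0.5 for the worst-case bound")
    return q * q / ((2.0 * tau - 1.0) * p)


def _unimodal(q: int, p: int, tau: float, B: int) -> float:
    """Unimodal complementary-pairs bound, capped by the worst case.

    For thresholds below the assumption's validity limit the worst-case
    bound is returned (conservative fallback).
    """
    theta = q / p
    worst = _worst_case(q, p, tau)
    if tau > 0.75:
        um = (1.0 + 1.0 / B) / (4.0 * (1.0 - tau + 1.0 / (2.0 * B)))
        return min(worst, q * q / p / um)
    valid_from = 0.5 + min(theta**2, 1.0 / (2.0 * B) + 0.75 * theta**2)
    denom = 2.0 * (2.0 * tau - 1.0 - 1.0 / (2.0 * B))
    if tau < valid_from or denom <= 0:
        return worst
    return min(worst, q * q / p / denom)


# ---------------------------------------------------------------------------
# r-concave tail probability


@lru_cache(maxsize=4096)
def _d_value_cached(theta: float, which: int, gridB: int, r: float) -> float:
    s = 1.0 / r  # negative exponent
    thetaB = theta * gridB
    k_start = int(math.ceil(2.0 * thetaB)) + 1
    if which < k_start:
        # below the extremal construction's regime; the Markov bound still
        # dominates every feasible distribution
        return float(min(1.0, thetaB / which))

    def mean_gap(a: float, k: int) -> float:
        w = (a + np.arange(k + 1)) ** s
        return float((np.arange(k + 1) * w).sum() / w.sum()) - thetaB

    def tail(a: float, t: int, k: int) -> float:
        # tail mass P(X >= t/gridB) of the extremal family member; at the
        # bracket endpoints this is the tail of p_i ~ (a + i)^s on {0..k}.
        # The numerator deliberately sums over i = 0..t-1 even when t-1 > k.
        i = np.arange(k + 1)
        num = (k + 1 - thetaB) * ((a + np.arange(t)) ** s).sum()
        denom = ((k + 1 - i) * (a + i) ** s).sum()
        return 1.0 - num / denom

    lo_a = 1e-5
    a_vec: dict[int, float] = {k_start - 1: 1e5}
    for k in range(k_start, gridB + 1):
        a_vec[k] = brentq(
            mean_gap, lo_a, a_vec[k - 1], args=(k,), xtol=1e-14, rtol=1e-14
        )

    best = 0.0
    for k in range(k_start, gridB):
        lo, hi = a_vec[k + 1], a_vec[k]
        res = minimize_scalar(
            lambda a: -tail(a, which, k),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        best = max(best, -res.fun, tail(lo, which, k), tail(hi, which, k))
    best = max(best, tail(a_vec[gridB], which, gridB))
    return float(min(1.0, best))


def d_value(theta: float, tau: float, gridB: int, r: float) -> float:
    """Maximal tail probability ``P(X >= tau)`` over r-concave random
    variables on the grid ``{0, 1/gridB, ..., 1}`` with mean at most
    ``theta``.

    Parameters
    ----------
    theta:
        Upper bound on the mean, in (0, 1).
    tau:
        Tail point in [0, 1].
    gridB:
        Support resolution (number of grid steps).
    r:
        Concavity order, must be negative (``(p_k)^r`` convex).
    """
    if r >= 0:
        raise ValueError("r must be negative")
    if gridB < 1:
        raise ValueError("gridB must be >= 1")
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in (0, 1)")
    if not (0.0 <= tau <= 1.0):
        raise ValueError("tau must lie in [0, 1]")
    if tau == 0.0:
        return 1.0
    which = int(math.ceil(round(tau * gridB, 9)))
    k_start = int(math.ceil(2.0 * theta * gridB)) + 1
    if k_start > gridB:
        # extremal construction infeasible (theta too large for the grid);
        # fall back to the Markov bound, which every feasible distribution
        # obeys
        return float(min(1.0, theta / tau))
    return _d_value_cached(float(theta), which, int(gridB), float(r))


def _r_concave(q: int, p: int, tau: float, B: int) -> float:
    theta = q / p
    tail = min(
        1.0,
        d_value(theta**2, 2.0 * tau - 1.0, B, -0.5),
        d_value(theta, tau, 2 * B, -0.25),
    )
    # r-concavity implies unimodality, so the unimodal bound remains valid
    return min(tail * p, _unimodal(q, p, tau, B))


def pfer_bound(query: BoundQuery) -> float:
    """Upper bound on the per-family error rate for the given parameters."""
    q, p, tau, B = query.q, query.p, query.pi_thr, query.B
    if query.assumption == "none":
        return _worst_case(q, p, tau)
    if query.assumption == "unimodal":
        return _unimodal(q, p, tau, B)
    return _r_concave(q, p, tau, B)


@dataclass(frozen=True)
class CutoffSolution:
    pi_thr: float
    realized_bound: float
    attainable: bool


def _grid(B: int) -> np.ndarray:
    ks = np.arange(B + 1, 2 * B + 1)
    return ks / (2.0 * B)


def solve_cutoff(
    q: int, p: int, pfer_max: float, B: int = 50, assumption: str = "none"
) -> CutoffSolution:
    """Smallest threshold on the ``1/(2B)`` grid meeting the error bound.

    If no grid threshold in (0.5, 1] attains ``pfer_max``, the threshold is
    capped at 1 and flagged as not attainable.
    """
    if pfer_max <= 0:
        raise ValueError("PFER_max must be > 0")
    if q > p:
        raise ValueError(f"q={q} exceeds the number of base-learners p={p}")
    tol = 1e-9 * max(1.0, pfer_max)  # guard grid points hit exactly
    for tau in _grid(B):
        bound = pfer_bound(BoundQuery(q, p, float(tau), B, assumption))
        if bound <= pfer_max + tol:
            return CutoffSolution(float(tau), bound, True)
    bound_at_one = pfer_bound(BoundQuery(q, p, 1.0, B, assumption))
    return CutoffSolution(1.0, bound_at_one, False)


def solve_q(
    pi_thr: float, p: int, pfer_max: float, B: int = 50, assumption: str = "none"
) -> int:
    """Largest q in [1, p] whose bound stays within ``pfer_max``."""
    if not (0.5 < pi_thr <= 1.0):
        raise ValueError("pi_thr must lie in (0.5, 1]")
    if pfer_max <= 0:
        raise ValueError("PFER_max must be > 0")
    best = 0
    tol = 1e-9 * max(1.0, pfer_max)
    for q in range(1, p + 1):
        if pfer_bound(BoundQuery(q, p, pi_thr, B, assumption)) <= pfer_max + tol:
            best = q
        else:
            break
    if best == 0:
        raise InfeasibleBoundError(
            f"even q=1 violates PFER_max={pfer_max} at pi_thr={pi_thr} "
            f"(assumption={assumption})"
        )
    return best


def pcer_equivalent(pfer_max: float, p: int) -> float:
    """Per-comparison error rate equivalent: PFER spread over p learners."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return pfer_max / p
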