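"""Driver mutations and their effect on per-level rates.

A driver of strength ``s`` increases a progenitor cell's self-renewal rate
by ``s * A_k`` per copy, which lowers its washout by the same amount:
``W_hat(d) = W_k - d*s*A_k``.  The critical driver count at a level is the
smallest ``d`` with ``W_hat(d) <= 0``, i.e. ``ceil(pi_k / s)``.

Drivers occur with probability ``mu`` in each daughter cell at every
division.  Two modes are supported: ``proliferative`` (each driver acts as
above) and ``neutral_until_critical`` (cells keep wild-type rates while
``d < d_crit``; the ``d_crit``-th driver still makes the clone
supercritical).

The terminal level is unaffected by drivers, and stem cells record drivers
without changing their rates (the expansion of mutant stem-cell pools is
neglected; see the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .hierarchy import Hierarchy

__all__ = ["DriverSpec", "MutantRates", "d_crit", "mutant_rates", "ceil_with_tol"]

#: relative tolerance used so analytically integer ratios (e.g. 1/(0.1*1) = 10)
#: do not creep above the next integer through floating-point rounding
CEIL_RTOL = 1e-9


@dataclass(frozen=True)
class DriverSpec:
    """Driver strength ``s``, per-daughter driver probability ``mu``, and mode."""

    s: float
    mu: float
    mode: str = "proliferative"

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError("driver strength s must be > 0")
        if not 0 <= self.mu <= 1:
            raise ValueError("mu must lie in [0, 1]")
        if self.mode not in ("proliferative", "neutral_until_critical"):
            raise ValueError(f"unknown driver mode {self.mode!r}")


@dataclass(frozen=True)
class MutantRates:
    """Effective rates of a progenitor cell carrying ``d`` drivers."""

    k: int
    d: int
    washout: float       # W_hat_k(d, s)
    activity: float      # A_hat_k(d, s)
    amplification: float # gamma_hat_k(d, s); inf at criticality
    sym_renewal: float   # r_hat_renewal(d, s)


def ceil_with_tol(x: float, rtol: float = CEIL_RTOL) -> int:
    """Ceiling with a relative guard against floating-point overshoot.

    Values within ``rtol`` of an integer are treated as that integer, so
    exact analytic boundaries round to themselves.
    """
    r = round(x)
    if abs(x - r) <= rtol * max(1.0, abs(x)):
        return int(r)
    return int(math.ceil(x))


def d_crit(s: float, gamma: float, epsilon: float = 0.0) -> int:
    """Critical driver count ``ceil(pi / s)`` with ``pi = (1 - epsilon)/(gamma - 1)``.

    This is the smallest number of drivers of strength ``s`` that makes the
    effective washout of a progenitor clone non-positive, at which point the
    clone grows without bound.
    """
    if gamma <= 1:
        raise ValueError("require gamma > 1")
    if s <= 0:
        raise ValueError("require s > 0")
    pi = (1.0 - epsilon) / (gamma - 1.0)
    return max(ceil_with_tol(pi / s), 0)


def mutant_rates(H: Hierarchy, k: int, d: int, spec: DriverSpec) -> MutantRates:
    """Effective rates of a cell with ``d`` drivers at progenitor level ``k``.

    In ``proliferative`` mode each driver adds ``s * A_k`` to the
    self-renewal rate, so ``W_hat = W_k - d s A_k`` and
    ``A_hat = A_k (1 + d s)``; the mutant amplification factor
    ``gamma_hat = (A_hat + W_hat)/W_hat = (pi_k + 1)/(pi_k - d s)`` diverges
    as ``d`` approaches the critical count.  In ``neutral_until_critical``
    mode subcritical mutants keep wild-type rates.
    """
    if not 0 < k < H.n:
        raise ValueError("mutant rates are defined for progenitor levels 0 < k < n")
    pi = float(H.pi_k[k])
    dc = ceil_with_tol(pi / spec.s)
    if d < 0 or d > dc:
        raise ValueError(f"driver count {d} outside the modeled range 0..{dc}")
    A = float(H.A_k[k])
    W = float(H.W_k[k])
    r_renew = H.rates[k].sym_renewal
    if spec.mode == "neutral_until_critical" and d < dc:
        eff = 0.0
    else:
        eff = d * spec.s
    W_hat = W - eff * A
    A_hat = A * (1.0 + eff)
    # at the critical count W_hat is analytically <= 0; guard against float
    # residue so the divergence of gamma_hat is reported as such
    critical = W_hat <= 1e-12 * A
    gamma_hat = math.inf if critical else (A_hat + W_hat) / W_hat
    return MutantRates(k=k, d=d, washout=W_hat, activity=A_hat,
                       amplification=gamma_hat, sym_renewal=r_renew + eff * A)
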