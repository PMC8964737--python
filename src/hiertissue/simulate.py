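"""Exact event-driven simulation of a differentiation hierarchy with drivers.

The simulator is the ground truth against which the analytic risk solver is
validated.  All cells in a (level, driver-count) class are statistically
exchangeable, so the state is the matrix of class occupancies and the
simulation is an exact Gillespie process over the total event propensity:
inter-event times are exponential, events are chosen proportionally to
per-class propensities, and every daughter cell independently acquires a
driver with probability ``mu``.

A replicate ends when a supercritical progenitor cell is created (a cell at
level ``0 < k < n`` whose driver count makes its effective washout
non-positive) — recorded as a cancer event, clone extinction after
criticality being neglected — or at ``t_life``.  Terminally differentiated
daughters are discarded (they neither divide nor matter for risk).  Stem
cells record drivers at divisions but keep wild-type rates; their driver
count is capped at the largest progenitor ``d_crit`` (any further driver
cannot change the outcome of their offspring).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .drivers import DriverSpec, ceil_with_tol
from .hierarchy import Hierarchy

__all__ = ["SimConfig", "SimResult", "simulate_replicate", "estimate_cancer_probability"]

# event column order in the per-class rate table
_SYM_DIFF, _ASYM, _RENEW, _DEATH = 0, 1, 2, 3

# replicate outcome codes
OUTCOME_NONE, OUTCOME_CANCER, OUTCOME_ABORTED = 0, 1, -1


@njit(cache=True)
def _run_replicate(seed, n, counts0, rates, dcrit, dcap, mu, t_life, cap):
    """One exact stochastic replicate; returns (outcome, t, level, d, counts)."""
    np.random.seed(seed)
    counts = counts0.copy()
    rate_tot = np.zeros((n, dcap + 1))
    for k in range(n):
        for d in range(dcap + 1):
            rate_tot[k, d] = (rates[k, d, 0] + rates[k, d, 1]
                              + rates[k, d, 2] + rates[k, d, 3])
    total = 0.0
    ncells = 0
    for k in range(n):
        for d in range(dcap + 1):
            total += counts[k, d] * rate_tot[k, d]
            ncells += counts[k, d]
    t = 0.0
    steps = 0
    while True:
        if total <= 0.0:
            return OUTCOME_NONE, t_life, -1, -1, counts
        t += np.random.exponential(1.0 / total)
        if t >= t_life:
            return OUTCOME_NONE, t_life, -1, -1, counts
        steps += 1
        if steps % 4096 == 0:  # refresh against float drift
            total = 0.0
            for k in range(n):
                for d in range(dcap + 1):
                    total += counts[k, d] * rate_tot[k, d]
        # pick the (level, driver) class
        u = np.random.random() * total
        acc = 0.0
        ki = n - 1
        di = dcap
        done = False
        for k in range(n):
            for d in range(dcap + 1):
                c = counts[k, d]
                if c > 0:
                    acc += c * rate_tot[k, d]
                    if u < acc:
                        ki, di = k, d
                        done = True
                        break
            if done:
                break
        # pick the event type within the class
        v = np.random.random() * rate_tot[ki, di]
        ev = _DEATH
        acc2 = 0.0
        for e in range(4):
            acc2 += rates[ki, di, e]
            if v < acc2:
                ev = e
                break
        # parent leaves its class in every event type
        counts[ki, di] -= 1
        total -= rate_tot[ki, di]
        ncells -= 1
        if ev == _DEATH:
            continue
        n_up = 2 if ev == _SYM_DIFF else (1 if ev == _ASYM else 0)
        n_same = 2 - n_up
        for _ in range(n_same):
            d2 = di + (1 if np.random.random() < mu else 0)
            if ki == 0:
                if d2 > dcap:
                    d2 = dcap
            elif d2 >= dcrit[ki]:
                return OUTCOME_CANCER, t, ki, d2, counts
            counts[ki, d2] += 1
            total += rate_tot[ki, d2]
            ncells += 1
        if ki + 1 < n:
            for _ in range(n_up):
                d2 = di + (1 if np.random.random() < mu else 0)
                if d2 >= dcrit[ki + 1]:
                    return OUTCOME_CANCER, t, ki + 1, d2, counts
                counts[ki + 1, d2] += 1
                total += rate_tot[ki + 1, d2]
                ncells += 1
        if ncells > cap:
            return OUTCOME_ABORTED, t, -1, -1, counts


def _class_tables(H: Hierarchy, spec: DriverSpec):
    """Per-(level, d) event rates, per-level d_crit and the d-axis cap."""
    n = H.n
    if n < 2:
        raise ValueError("simulation requires at least one progenitor level")
    dcrit = np.empty(n, dtype=np.int64)
    dcrit[0] = np.iinfo(np.int64).max  # stem cells are never supercritical
    for k in range(1, n):
        dcrit[k] = ceil_with_tol(float(H.pi_k[k]) / spec.s)
    dcap = int(dcrit[1:].max())
    rates = np.zeros((n, dcap + 1, 4))
    for k in range(n):
        r = H.rates[k]
        for d in range(dcap + 1):
            if k > 0 and d >= dcrit[k]:
                continue  # class never occupied
            eff = 0.0
            if k > 0 and spec.mode == "proliferative":
                eff = d * spec.s * float(H.A_k[k])
            rates[k, d] = (r.sym_diff, r.asym_diff, r.sym_renewal + eff, r.death)
    return rates, dcrit, dcap


def _integer_counts(H: Hierarchy) -> np.ndarray:
    counts = np.zeros(H.n, dtype=np.int64)
    for k, N in enumerate(H.cell_numbers):
        c = round(N)
        if abs(N - c) > 1e-9 * max(1.0, N):
            raise ValueError(
                f"simulation needs integer homeostatic cell numbers, got N_{k}={N}")
        counts[k] = c
    return counts


@dataclass(frozen=True)
class SimConfig:
    """Simulation setup: hierarchy, driver model, seeding and stop conditions."""

    hierarchy: Hierarchy
    driver: DriverSpec
    seed: int
    replicates: int = 10_000
    cell_cap_factor: float = 50.0   # abort guard, multiple of the initial count
    initial_counts: np.ndarray | None = None  # override (levels 0..n-1, d=0)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass(frozen=True)
class SimResult:
    """Aggregate cancer frequency with binomial standard error."""

    frequency: float
    se: float
    n_cancer: int
    n_aborted: int
    replicates: int
    seed: int
    outcomes: pd.DataFrame = field(repr=False)


def _prepare(config: SimConfig):
    H, spec = config.hierarchy, config.driver
    rates, dcrit, dcap = _class_tables(H, spec)
    base = (config.initial_counts if config.initial_counts is not None
            else _integer_counts(H))
    counts0 = np.zeros((H.n, dcap + 1), dtype=np.int64)
    counts0[:, 0] = np.asarray(base, dtype=np.int64)
    cap = int(config.cell_cap_factor * max(counts0.sum(), 1)) + 1000
    return rates, dcrit, dcap, counts0, cap


def simulate_replicate(config: SimConfig, seed: int | None = None):
    """Run a single replicate; returns (outcome, time, level, d, final_counts).

    ``outcome`` is 1 for a cancer event (first supercritical progenitor
    created), 0 for none by ``t_life``, -1 if the population guard tripped.
    Identical seeds give identical outcomes.
    """
    H = config.hierarchy
    rates, dcrit, dcap, counts0, cap = _prepare(config)
    s = config.seed if seed is None else seed
    return _run_replicate(np.int64(s % (2 ** 31)), H.n, counts0, rates, dcrit,
                          dcap, config.driver.mu, H.t_life, cap)


def estimate_cancer_probability(config: SimConfig) -> SimResult:
    """Empirical lifetime cancer frequency over independent replicates.

    Each replicate gets its own counter-derived seed (order-insensitive);
    the aggregate is bitwise reproducible for a fixed (seed, replicates).
    """
    H = config.hierarchy
    rates, dcrit, dcap, counts0, cap = _prepare(config)
    seeds = np.random.SeedSequence(config.seed).generate_state(config.replicates)
    rows = []
    for i in range(config.replicates):
        out, t, lvl, d, _ = _run_replicate(
            np.int64(int(seeds[i]) % (2 ** 31)), H.n, counts0, rates, dcrit,
            dcap, config.driver.mu, H.t_life, cap)
        rows.append((out, t, lvl, d))
    df = pd.DataFrame(rows, columns=["outcome", "time", "level", "drivers"])
    n_cancer = int((df["outcome"] == OUTCOME_CANCER).sum())
    n_aborted = int((df["outcome"] == OUTCOME_ABORTED).sum())
    p = n_cancer / config.replicates
    se = float(np.sqrt(p * (1.0 - p) / config.replicates))
    return SimResult(frequency=p, se=se, n_cancer=n_cancer, n_aborted=n_aborted,
                     replicates=config.replicates, seed=config.seed, outcomes=df)
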