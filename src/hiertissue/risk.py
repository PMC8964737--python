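"""Lifetime cancer risk of a differentiation hierarchy.

The probability that a tissue accumulates the critical number of driver
mutations during its lifetime is computed in three stages:

1. ``q_table`` — for every progenitor level ``k``, driver count ``d`` and
   time ``t``, the probability ``Q_k(d, t)`` that a single cell appearing at
   level ``k`` with ``d`` drivers gives rise to a sublineage that reaches
   ``d_crit`` drivers before being washed out or the tissue dies.  The table
   is filled by a backward recursion over ``(k, d)`` from the boundary
   conditions ``Q_k(d_crit, t) = 1`` (a supercritical cell is cancer by
   definition) and ``Q_n(d, t) = 0`` (terminal cells cannot proliferate).
   The recursion multiplies expected descendant counts, which overestimates
   the true probability when entries are not small; since ``Q`` is a
   probability every entry is saturated at 1 (the linear recursion is exact
   in the small-``Q`` regime and the saturation is exact in the
   guaranteed-criticality regime of nearly critical mutants).

2. ``stem_dynamics`` — a linear ODE system for the expected number
   ``N_0(d, t)`` of stem cells carrying ``d`` drivers whose progenitor
   offspring have not yet reached criticality.  Stem cells keep wild-type
   rates regardless of ``d``; states with ``d >= d_crit`` are absorbed into
   one bucket whose differentiated offspring are supercritical with
   certainty.

3. ``cancer_probability`` — the lifetime risk is the hazard accumulated by
   the stem lineages plus the contribution of the progenitor cells already
   present when the tissue is fully developed:
   ``P = sum_d int_0^T r0_up q0(d,t) N_0(d,t) dt + sum_k N_k Q_k(0, 0)``.
   The first term is an expectation-style accumulation and is reported raw
   (it can exceed 1 for extreme parameters); a capped value is provided for
   convenience.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

from .drivers import DriverSpec, ceil_with_tol
from .hierarchy import Hierarchy

__all__ = [
    "TimeGrid",
    "QTable",
    "StemTrajectory",
    "RiskResult",
    "survival_weight",
    "expected_descendants",
    "q_table",
    "stem_dynamics",
    "cancer_probability",
]

#: default number of grid intervals on [0, t_life]
DEFAULT_GRID_M = 2000

#: below this value of W_hat * (t_life - t) the exponential in the survival
#: weight is replaced by its series to avoid catastrophic cancellation
_SERIES_SWITCH = 1e-6


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing times covering ``[0, t_life]``."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("grid must be strictly increasing and start at 0")
        object.__setattr__(self, "times", t)

    @classmethod
    def uniform(cls, t_life: float, M: int = DEFAULT_GRID_M) -> "TimeGrid":
        """Uniform grid with ``M`` intervals (``M + 1`` points)."""
        return cls(np.linspace(0.0, t_life, M + 1))

    @property
    def t_life(self) -> float:
        return float(self.times[-1])

    @property
    def M(self) -> int:
        return self.times.size - 1


def survival_weight(W_hat, t, t_life):
    """Expected exposure and survival of a cell appearing at time ``t``.

    A cell (together with its same-level descendants) appearing at time
    ``t`` on a level with effective washout ``W_hat > 0`` decays as
    ``exp(-W_hat (t' - t))``.  Returns the pair ``(tau_hat, P_hat)`` where
    ``tau_hat = (1 - exp(-W_hat (t_life - t))) / W_hat`` is the expected
    time-integrated exposure and ``P_hat = W_hat * tau_hat`` the probability
    of not being washed out before ``t_life``.  ``W_hat = 0`` is handled as
    the limit ``tau_hat = t_life - t``.
    """
    W = np.asarray(W_hat, dtype=float)
    if np.any(W < 0):
        raise ValueError("survival_weight requires W_hat >= 0 (subcritical cells)")
    dt = np.asarray(t_life, dtype=float) - np.asarray(t, dtype=float)
    if np.any(dt < -1e-12 * max(1.0, abs(t_life))):
        raise ValueError("require t <= t_life")
    dt = np.maximum(dt, 0.0)
    x = W * dt
    small = x < _SERIES_SWITCH
    W_safe = np.where(small, 1.0, W)
    tau = np.where(
        small,
        dt * (1.0 - x / 2.0 + x * x / 6.0),
        -np.expm1(-x) / W_safe,
    )
    P = W * tau
    if np.ndim(W_hat) == 0 and np.ndim(t) == 0:
        return float(tau), float(P)
    return tau, P


def expected_descendants(gamma_hat, P_hat):
    """Expected differentiated and same-level birth events of a cell.

    ``m_up = gamma_hat * P_hat`` counts descendants placed one level up and
    ``m_same = (gamma_hat - 2) * P_hat`` same-level descendants, both over
    the cell's remaining exposure to the level.
    """
    m_up = gamma_hat * P_hat
    m_same = (gamma_hat - 2.0) * P_hat
    return m_up, m_same


def _uniform_pi(H: Hierarchy) -> float:
    """Common progenitor proliferative disadvantage; errors if non-uniform."""
    pis = H.pi_k[1:]
    if pis.size == 0:
        raise ValueError("hierarchy has no progenitor levels")
    if not np.allclose(pis, pis[0], rtol=1e-9):
        raise ValueError("risk computation requires uniform amplification "
                         f"(pi_k not constant: {pis})")
    return float(pis[0])


def _resolve_d_crit(H: Hierarchy, spec: DriverSpec, gamma: float | None) -> int:
    if H.n > 1:
        return ceil_with_tol(_uniform_pi(H) / spec.s)
    if gamma is None:
        raise ValueError("a hierarchy with n = 1 has no progenitor level; pass "
                         "gamma to define the prospective critical driver count")
    return ceil_with_tol((1.0 / (gamma - 1.0)) / spec.s)


@dataclass(frozen=True)
class QTable:
    """``Q[k, d, i]`` over levels ``0..n``, drivers ``0..d_crit`` and grid times.

    Row ``k = 0`` is unused (stem lineages are handled by the ODE system),
    row ``k = n`` is identically zero, and the ``d = d_crit`` slice is one at
    every progenitor level.
    """

    values: np.ndarray
    grid: TimeGrid
    d_crit: int

    def at_t0(self) -> np.ndarray:
        """``Q_k(d, t=0)`` as an ``(n+1, d_crit+1)`` array."""
        return self.values[:, :, 0].copy()


@dataclass(frozen=True)
class StemTrajectory:
    """Expected stem-cell counts ``N_0(d, t)`` and the stem composite rates."""

    counts: np.ndarray   # shape (d_crit + 1, len(grid))
    q0: np.ndarray       # progenitor-sublineage criticality probability per d
    grid: TimeGrid
    r0_same: float       # 2 r_renewal + r_asym at the stem level
    r0_up: float         # 2 r_sym_diff + r_asym at the stem level
    cumulative_hazard: np.ndarray  # int_0^t sum_d r0_up q0(d,u) N_0(d,u) du


@dataclass(frozen=True)
class RiskResult:
    """Lifetime cancer probability and its two components."""

    p_cancer: float           # raw total (expectation-style; may exceed 1)
    stem_lineage_term: float  # accumulation along stem lineages after development
    development_term: float   # contribution of cells present at t = 0
    d_crit: int
    qtable: QTable
    stem: StemTrajectory

    @property
    def p_cancer_capped(self) -> float:
        return min(self.p_cancer, 1.0)


def q_table(H: Hierarchy, spec: DriverSpec, grid: TimeGrid,
            gamma: float | None = None) -> QTable:
    """Fill the sublineage-criticality table by backward recursion.

    Entries are filled in order ``d = d_crit - 1 .. 0`` and, within each
    ``d``, ``k = n - 1 .. 1``, so every entry depends only on already-filled
    ones.  Under ``neutral_until_critical`` mode subcritical mutants use
    wild-type rates, otherwise each driver adds ``s * A_k`` to self-renewal.
    """
    n, mu, s = H.n, spec.mu, spec.s
    tgrid = grid.times
    if not math.isclose(grid.t_life, H.t_life, rel_tol=1e-12):
        raise ValueError("grid must span the hierarchy lifetime")
    dc = _resolve_d_crit(H, spec, gamma)
    T = tgrid.size
    Q = np.zeros((n + 1, dc + 1, T))
    if dc == 0:
        # degenerate: wild-type progenitors are already critical
        Q[1:n, 0, :] = 1.0
        return QTable(values=Q, grid=grid, d_crit=0)
    Q[1:n, dc, :] = 1.0
    A, W = H.A_k, H.W_k
    for d in range(dc - 1, -1, -1):
        eff = 0.0 if spec.mode == "neutral_until_critical" else d * s
        for k in range(n - 1, 0, -1):
            W_hat = W[k] - eff * A[k]
            A_hat = A[k] * (1.0 + eff)
            tau, _ = survival_weight(W_hat, tgrid, H.t_life)
            m_up = (A_hat + W_hat) * tau
            m_same = (A_hat - W_hat) * tau
            raw = (m_up * ((1.0 - mu) * Q[k + 1, d] + mu * Q[k + 1, d + 1])
                   + m_same * mu * Q[k, d + 1])
            # Q is a probability: the linear recursion counts expected
            # criticality events and must saturate at 1.  Without the cap the
            # geometric growth of expected descendant numbers (m_up > 1 at
            # every subcritical class) makes near-critical entries explode.
            Q[k, d] = np.minimum(raw, 1.0)
    return QTable(values=Q, grid=grid, d_crit=dc)


def stem_dynamics(H: Hierarchy, spec: DriverSpec, qtable: QTable,
                  grid: TimeGrid,
                  rtol: float = 1e-8, atol_scale: float = 1e-12) -> StemTrajectory:
    """Integrate the stem-compartment mutation-accumulation ODE system.

    ``N_0(d, t)`` loses mass to ``d + 1`` by mutation at same-level births
    (rate ``r0_same * mu``) and to the cancer sink at differentiated births
    (rate ``r0_up * q0(d, t)``), where ``q0`` is the probability that the
    progenitor sublineage seeded by one differentiated daughter reaches
    criticality.  States ``d >= d_crit`` are absorbed into the top bucket
    with ``q0 = 1``.
    """
    if qtable.grid is not grid and not np.array_equal(qtable.grid.times, grid.times):
        raise ValueError("qtable and stem dynamics must share one grid")
    n, mu = H.n, spec.mu
    dc = qtable.d_crit
    tgrid = grid.times
    Q = qtable.values
    q0 = np.zeros((dc + 1, tgrid.size))
    if dc > 0 and n > 1:
        q0[:dc] = (1.0 - mu) * Q[1, :dc] + mu * Q[1, 1:dc + 1]
    q0[dc] = 1.0

    r0 = H.rates[0]
    r0_same, r0_up = r0.same_level_output, r0.diff_output
    N0 = float(H.cell_numbers[0])

    q0_of_t = interp1d(tgrid, q0, axis=1, assume_sorted=True, copy=False)
    mut = r0_same * mu

    # the last state accumulates the cancer hazard sum_d r0_up q0(d,t) N_0(d,t);
    # integrating it inside the solver resolves boundary layers (the d_crit
    # bucket can empty within a tiny fraction of a grid step when stem rates
    # are large) that fixed-grid quadrature would miss entirely
    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        q = q0_of_t(t)
        N = y[:-1]
        sink = r0_up * q * N
        dy = np.empty_like(y)
        dy[:-1] = -mut * N - sink
        dy[dc] = -sink[dc]               # bucket: mutation does not leave it
        dy[1:dc + 1] += mut * N[:-1]
        dy[-1] = sink.sum()
        return dy

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        q = q0_of_t(t)
        J = np.zeros((dc + 2, dc + 2))
        J[:dc + 1, :dc + 1] = np.diag(-(mut + r0_up * q))
        J[dc, dc] = -r0_up
        idx = np.arange(1, dc + 1)
        J[idx, idx - 1] += mut
        J[-1, :dc + 1] = r0_up * q
        return J

    y0 = np.zeros(dc + 2)
    y0[0] = N0
    atol = np.full(dc + 2, atol_scale * N0)
    atol[-1] = 1e-4 * atol_scale * N0    # hazard state: tighter floor
    sol = solve_ivp(rhs, (0.0, grid.t_life), y0, method="LSODA",
                    t_eval=tgrid, rtol=rtol, atol=atol, jac=jac)
    if not sol.success:                  # stiff corner cases: retry with BDF
        sol = solve_ivp(rhs, (0.0, grid.t_life), y0, method="BDF",
                        t_eval=tgrid, rtol=rtol, atol=atol, jac=jac)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(
            f"stem ODE integration failed: {sol.message} "
            f"(grid M={grid.M}, d_crit={dc}, r0_up={r0_up:g}, mu={mu:g})")
    counts = np.clip(sol.y[:-1], 0.0, None)
    return StemTrajectory(counts=counts, q0=q0, grid=grid,
                          r0_same=r0_same, r0_up=r0_up,
                          cumulative_hazard=np.clip(sol.y[-1], 0.0, None))


def cancer_probability(H: Hierarchy, spec: DriverSpec,
                       grid: TimeGrid | None = None,
                       gamma: float | None = None) -> RiskResult:
    """Lifetime probability of accumulating the critical number of drivers.

    The stem-lineage term integrates the hazard ``r0_up * q0(d, t) *
    N_0(d, t)`` over the lifetime, accumulated as an auxiliary state of the
    stem ODE system so that fast transients are resolved adaptively; the
    development term ``sum_k N_k Q_k(0, 0)`` accounts for the progenitor
    cells already present when the fully developed tissue starts its
    homeostatic lifetime.
    """
    if grid is None:
        grid = TimeGrid.uniform(H.t_life)
    qt = q_table(H, spec, grid, gamma=gamma)
    stem = stem_dynamics(H, spec, qt, grid)
    term1 = float(stem.cumulative_hazard[-1])
    Nk = H.N_k
    term2 = float(sum(Nk[k] * qt.values[k, 0, 0] for k in range(1, H.n)))
    return RiskResult(p_cancer=term1 + term2, stem_lineage_term=term1,
                      development_term=term2, d_crit=qt.d_crit,
                      qtable=qt, stem=stem)
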