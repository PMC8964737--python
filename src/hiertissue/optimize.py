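"""Least complex tissue keeping lifetime cancer risk below a drift-barrier.

The drift-barrier hypothesis holds that selection cannot reduce lifetime
cancer risk below a tissue-specific threshold: further improvement confers
too small a fitness gain to overcome genetic drift.  Given the externally
fixed stem-cell count ``N0`` and lifetime terminal output ``N``, the least
complex tissue is found by the loop: starting at ``n = 1``, minimize the
lifetime risk over the uniform amplification factor ``gamma``; if the
minimum exceeds the threshold, increase ``n`` by one, otherwise stop.  The
result is the minimal level count ``n_drift`` and the risk-minimizing
``gamma_drift`` at that ``n``.

The ``gamma`` scan covers the trade-off interval ``[2, gamma*(n)]`` between
maximal washing out (``gamma = 2``) and minimal divisional load
(``gamma*(n) = (N/N0)**(1/n)``).  ``gamma*`` is also the boundary of the
model's domain of validity: beyond it the progenitor washout time
``1/W_k`` exceeds ``t_life`` (``W_k t_life = (N/N0)/gamma**n < 1``), the
standing populations are relics of development rather than of homeostatic
turnover, and the computed lifetime risk is no longer meaningful.  Within a
``d_crit`` segment the risk is smooth, but it jumps at every breakpoint
``gamma = 1 + 1/(m s)`` where the critical driver count steps, so the scan
evaluates a log-spaced base grid, straddles every breakpoint, and refines
locally inside the best segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .drivers import DriverSpec, d_crit
from .hierarchy import TissueSpec, build_hierarchy, gamma_star
from .risk import DEFAULT_GRID_M, TimeGrid, cancer_probability

__all__ = [
    "Optimum",
    "InfeasibleError",
    "minimize_risk_over_gamma",
    "find_minimal_hierarchy",
    "scan_parameter_grid",
    "scan_ratio",
]

#: offset used to straddle d_crit breakpoints in the gamma scan
_BREAKPOINT_EPS = 1e-6

#: log-spaced base-grid resolution of the gamma scan
_BASE_GRID = 64


class InfeasibleError(RuntimeError):
    """No hierarchy within the level cap keeps the risk below threshold."""


@dataclass(frozen=True)
class Optimum:
    """Least complex hierarchy meeting a lifetime-risk threshold."""

    n_drift: int
    gamma_drift: float
    d_crit: int
    stem_division_time: float  # 1 / A_0, in the t_life time unit
    achieved_risk: float
    threshold: float


class _RiskCache:
    """Memoizes risk evaluations across gamma scans and (s, mu) grids."""

    def __init__(self, grid_M: int = DEFAULT_GRID_M) -> None:
        self.grid_M = grid_M
        self._store: dict[tuple, float] = {}

    def risk(self, N0: float, N: float, n: int, gamma: float,
             spec: DriverSpec, t_life: float) -> float:
        key = (N0, N, n, round(float(gamma), 12), spec.s, spec.mu, spec.mode,
               t_life, self.grid_M)
        if key not in self._store:
            H = build_hierarchy(TissueSpec(N0=N0, N=N, n=n, gamma=max(gamma, 2.0),
                                           t_life=t_life))
            grid = TimeGrid.uniform(t_life, self.grid_M)
            self._store[key] = cancer_probability(
                H, spec, grid=grid, gamma=max(gamma, 2.0)).p_cancer
        return self._store[key]


def _breakpoints(s: float, lo: float, hi: float) -> list[float]:
    """d_crit step locations ``1 + 1/(m s)`` inside ``(lo, hi)``."""
    out = []
    m = 1
    while True:
        b = 1.0 + 1.0 / (m * s)
        if b <= lo:
            break
        if b < hi:
            out.append(b)
        m += 1
    return out


def minimize_risk_over_gamma(N0: float, N: float, n: int, spec: DriverSpec,
                             t_life: float = 80.0, *,
                             cache: _RiskCache | None = None,
                             refine_above: float = math.inf,
                             ) -> tuple[float, float]:
    """Risk-minimizing uniform amplification factor at fixed level count.

    Scans ``gamma`` over ``[2, gamma*(n)]`` (see module docstring), with
    every ``d_crit`` breakpoint straddled so the discontinuities are seen
    from both sides, then golden-section refines within the bracket of the
    best grid point.  Returns ``(gamma_min, risk_min)``.  When the coarse
    minimum already exceeds ``refine_above`` the refinement is skipped (the
    local polish never changes the value by orders of magnitude).
    """
    cache = cache or _RiskCache()
    if n == 1:
        # no progenitor levels: gamma enters only through the prospective
        # critical driver count, which is maximal (risk minimal) at gamma = 2
        return 2.0, cache.risk(N0, N, n, 2.0, spec, t_life)
    hi = max(gamma_star(N, N0, n), 2.0)
    cand = {2.0, hi}
    cand.update(np.geomspace(2.0, hi, _BASE_GRID))
    for b in _breakpoints(spec.s, 2.0, hi):
        cand.update(g for g in (b - _BREAKPOINT_EPS, b, b + _BREAKPOINT_EPS)
                    if 2.0 <= g <= hi)
    cand = sorted(cand)
    vals = [cache.risk(N0, N, n, g, spec, t_life) for g in cand]
    i = int(np.argmin(vals))
    best_g, best_r = cand[i], vals[i]
    if best_r <= refine_above and len(cand) > 2:
        # refine inside the d_crit segment of the best point, bracketed by
        # its grid neighbours
        dc0 = d_crit(spec.s, best_g)
        seg_lo = 1.0 + 1.0 / (dc0 * spec.s)          # gamma above this has d_crit <= dc0
        seg_hi = 1.0 + 1.0 / ((dc0 - 1) * spec.s) if dc0 > 1 else hi
        lo = max(2.0, cand[max(i - 1, 0)], seg_lo + _BREAKPOINT_EPS)
        up = min(hi, cand[min(i + 1, len(cand) - 1)], seg_hi - _BREAKPOINT_EPS)
        if up > lo:
            res = minimize_scalar(
                lambda g: cache.risk(N0, N, n, float(g), spec, t_life),
                bounds=(lo, up), method="bounded",
                options={"xatol": 1e-3, "maxiter": 40})
            if res.fun < best_r:
                best_g, best_r = float(res.x), float(res.fun)
    return best_g, best_r


def find_minimal_hierarchy(N0: float, N: float, spec: DriverSpec,
                           threshold: float, t_life: float = 80.0, *,
                           n_cap: int = 60,
                           cache: _RiskCache | None = None) -> Optimum:
    """Smallest ``n`` whose gamma-minimized lifetime risk meets the threshold.

    Implements the drift-barrier search: ``n`` grows from 1 until the
    minimum over ``gamma`` of the lifetime cancer probability drops to or
    below ``threshold``.  Raises :class:`InfeasibleError` if no ``n`` up to
    ``n_cap`` succeeds.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    cache = cache or _RiskCache()
    for n in range(1, n_cap + 1):
        g, r = minimize_risk_over_gamma(
            N0, N, n, spec, t_life, cache=cache,
            refine_above=1e3 * threshold)
        if r <= threshold:
            H = build_hierarchy(TissueSpec(N0=N0, N=N, n=n, gamma=max(g, 2.0),
                                           t_life=t_life))
            return Optimum(n_drift=n, gamma_drift=g,
                           d_crit=d_crit(spec.s, g),
                           stem_division_time=float(1.0 / H.A_k[0]),
                           achieved_risk=r, threshold=threshold)
    raise InfeasibleError(
        f"no hierarchy with n <= {n_cap} keeps risk below {threshold}")


def scan_parameter_grid(N0: float, N: float, s_values, mu_values,
                        threshold: float, t_life: float = 80.0,
                        mode: str = "proliferative") -> pd.DataFrame:
    """Least complex tissue for every (s, mu) combination.

    One row per cell with columns ``(s, mu, n_drift, gamma_drift, d_crit,
    stem_division_time, achieved_risk, feasible)``; infeasible cells are
    flagged rather than fatal.
    """
    cache = _RiskCache()
    rows = []
    for s in s_values:
        for mu in mu_values:
            spec = DriverSpec(s=float(s), mu=float(mu), mode=mode)
            row = dict(s=float(s), mu=float(mu), threshold=threshold)
            try:
                opt = find_minimal_hierarchy(N0, N, spec, threshold, t_life,
                                             cache=cache)
                row.update(n_drift=opt.n_drift, gamma_drift=opt.gamma_drift,
                           d_crit=opt.d_crit,
                           stem_division_time=opt.stem_division_time,
                           achieved_risk=opt.achieved_risk, feasible=True)
            except InfeasibleError:
                row.update(n_drift=np.nan, gamma_drift=np.nan, d_crit=np.nan,
                           stem_division_time=np.nan, achieved_risk=np.nan,
                           feasible=False)
            rows.append(row)
    return pd.DataFrame(rows)


def scan_ratio(N: float, mu: float, threshold: float, ratio_values,
               s: float, t_life: float = 80.0,
               mode: str = "proliferative") -> pd.DataFrame:
    """Least complex tissue as a function of ``N/N0`` at fixed output ``N``."""
    spec = DriverSpec(s=s, mu=mu, mode=mode)
    rows = []
    for ratio in ratio_values:
        if ratio < 1:
            raise ValueError("N/N0 ratios must be >= 1")
        N0 = N / float(ratio)
        row = dict(ratio=float(ratio), N0=N0, s=s, mu=mu, threshold=threshold)
        try:
            opt = find_minimal_hierarchy(N0, N, spec, threshold, t_life)
            row.update(n_drift=opt.n_drift, gamma_drift=opt.gamma_drift,
                       d_crit=opt.d_crit,
                       stem_division_time=opt.stem_division_time,
                       achieved_risk=opt.achieved_risk, feasible=True)
        except InfeasibleError:
            row.update(n_drift=np.nan, gamma_drift=np.nan, d_crit=np.nan,
                       stem_division_time=np.nan, achieved_risk=np.nan,
                       feasible=False)
        rows.append(row)
    return pd.DataFrame(rows)
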