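"""Tissue data model for hierarchically differentiating, self-renewing tissues.

A tissue is organized into ``n + 1`` levels: level 0 holds the ``N0``
tissue-specific stem cells, levels ``0 < k < n`` progressively more
differentiated progenitors, and level ``n`` the terminally differentiated
cells, which do not divide.  Each non-terminal level is characterized by the
per-cell rates of four microscopic events: symmetric differentiation
(``sym_diff``, both daughters move one level up), asymmetric division
(``asym_diff``, one daughter stays, one moves up), symmetric self-renewal
(``sym_renewal``, both daughters stay), and cell death.

From these rates the module derives, per level: the divisional activity
``A_k``, net cell production ``R_k``, washout ``W_k`` (the net per-cell rate
at which a level's cells plus their same-level descendants are depleted),
differentiation output ``delta_k``, amplification factor
``gamma_k = delta_k / delta_{k-1}``, proliferative disadvantage
``pi_k = W_k / A_k`` and death-to-birth ratio ``eps_k``.  Homeostasis pins
``delta_{k-1} = N_k * W_k`` at every progenitor level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LevelRates",
    "Hierarchy",
    "TissueSpec",
    "build_hierarchy",
    "derived_quantities",
    "gamma_star",
    "n_opt",
]

#: relative tolerance of the homeostasis identity delta_{k-1} = N_k W_k
HOMEOSTASIS_RTOL = 1e-10


@dataclass(frozen=True)
class LevelRates:
    """Per-cell rates of the four microscopic events at one level.

    All rates are per cell per unit time and must be non-negative.  At the
    terminal level every division rate is zero (terminal cells only wear
    away).
    """

    sym_diff: float = 0.0
    asym_diff: float = 0.0
    sym_renewal: float = 0.0
    death: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sym_diff", "asym_diff", "sym_renewal", "death"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")

    @property
    def activity(self) -> float:
        """Total division rate ``A = r_sym_diff + r_asym + r_renewal``."""
        return self.sym_diff + self.asym_diff + self.sym_renewal

    @property
    def net_production(self) -> float:
        """Net per-cell production ``R = A - r_death``."""
        return self.activity - self.death

    @property
    def washout(self) -> float:
        """Net depletion rate ``W = r_sym_diff - r_renewal + r_death``."""
        return self.sym_diff - self.sym_renewal + self.death

    @property
    def diff_output(self) -> float:
        """Per-cell rate of producing next-level cells, ``2 r_sym_diff + r_asym``."""
        return 2.0 * self.sym_diff + self.asym_diff

    @property
    def same_level_output(self) -> float:
        """Per-cell rate of producing same-level daughters, ``2 r_renewal + r_asym``."""
        return 2.0 * self.sym_renewal + self.asym_diff


@dataclass(frozen=True)
class TissueSpec:
    """High-level description of a tissue used to construct a hierarchy.

    Parameters
    ----------
    N0 : number of stem cells.
    N : number of terminally differentiated cells produced over ``t_life``.
    n : number of non-terminal levels (the tissue has ``n + 1`` levels).
    gamma : uniform amplification factor for the progenitor levels (>= 2).
    t_life : tissue lifetime; the default time unit is years.
    cell_number_rule : only ``"geometric"`` (``N_k = N0 * gamma**k``) is
        implemented; it makes the dimensionless washout ``W_k * t_life``
        identical across progenitor levels.
    asym_fraction : fraction of each level's differentiation output produced
        by asymmetric divisions.  Feasible at progenitors only for
        ``asym_fraction <= 1 - 2/gamma``; gamma = 2 forces purely symmetric
        differentiation.
    stem_asym_fraction : same mix for the stem level only; ``None`` inherits
        ``asym_fraction``.  The stem composite rates (and hence every risk
        quantity) are independent of this mix; setting it to 1 makes the
        stem pool exactly constant in the stochastic simulator, matching the
        regulated stem compartment the risk equations assume.
    """

    N0: float
    N: float
    n: int
    gamma: float
    t_life: float = 80.0
    cell_number_rule: str = "geometric"
    asym_fraction: float = 0.0
    stem_asym_fraction: float | None = None

    def __post_init__(self) -> None:
        if not (self.N >= self.N0 >= 1):
            raise ValueError("require N >= N0 >= 1")
        if self.n < 1:
            raise ValueError("require n >= 1")
        if self.gamma < 2:
            raise ValueError("require gamma >= 2")
        if self.t_life <= 0:
            raise ValueError("require t_life > 0")
        if not 0 <= self.asym_fraction <= 1:
            raise ValueError("require 0 <= asym_fraction <= 1")
        if self.stem_asym_fraction is not None and not 0 <= self.stem_asym_fraction <= 1:
            raise ValueError("require 0 <= stem_asym_fraction <= 1")
        if self.cell_number_rule != "geometric":
            raise ValueError(f"unknown cell_number_rule {self.cell_number_rule!r}")


@dataclass(frozen=True)
class Hierarchy:
    """A fully specified differentiation hierarchy.

    ``cell_numbers`` holds the homeostatic occupancies of levels
    ``0 .. n-1`` (the terminal level is not tracked: terminal cells neither
    divide nor mutate the dynamics).  ``rates`` holds one :class:`LevelRates`
    per non-terminal level.
    """

    n: int
    cell_numbers: tuple[float, ...]
    rates: tuple[LevelRates, ...]
    t_life: float
    _df: pd.DataFrame = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.cell_numbers) != self.n or len(self.rates) != self.n:
            raise ValueError("need cell_numbers and rates for levels 0..n-1")
        if any(N <= 0 for N in self.cell_numbers):
            raise ValueError("cell numbers must be positive")
        object.__setattr__(self, "_df", _derive(self))
        self.validate()

    # -- per-level derived quantities, as numpy arrays over levels 0..n-1 --
    @property
    def N_k(self) -> np.ndarray:
        return self._df["N_k"].to_numpy()

    @property
    def A_k(self) -> np.ndarray:
        return self._df["A_k"].to_numpy()

    @property
    def R_k(self) -> np.ndarray:
        return self._df["R_k"].to_numpy()

    @property
    def W_k(self) -> np.ndarray:
        return self._df["W_k"].to_numpy()

    @property
    def delta_k(self) -> np.ndarray:
        return self._df["delta_k"].to_numpy()

    @property
    def gamma_k(self) -> np.ndarray:
        return self._df["gamma_k"].to_numpy()

    @property
    def pi_k(self) -> np.ndarray:
        return self._df["pi_k"].to_numpy()

    @property
    def eps_k(self) -> np.ndarray:
        return self._df["eps_k"].to_numpy()

    @property
    def lifetime_output(self) -> float:
        """Terminal cells produced over the lifetime, ``delta_{n-1} * t_life``."""
        return float(self.delta_k[-1] * self.t_life)

    def validate(self) -> None:
        """Check the homeostasis identity and sign constraints."""
        W = self.W_k
        if abs(W[0]) > 0:
            raise ValueError("stem level must have zero washout (W_0 = 0)")
        delta = self.delta_k
        for k in range(1, self.n):
            if W[k] <= 0:
                raise ValueError(f"progenitor level {k} must have W_k > 0")
            lhs, rhs = delta[k - 1], self.cell_numbers[k] * W[k]
            if abs(lhs - rhs) > HOMEOSTASIS_RTOL * abs(lhs):
                raise ValueError(
                    f"homeostasis violated at level {k}: "
                    f"delta_{k - 1}={lhs!r} != N_{k} W_{k}={rhs!r}"
                )


def _derive(H: Hierarchy) -> pd.DataFrame:
    rows = []
    delta_prev = None
    for k, (N, r) in enumerate(zip(H.cell_numbers, H.rates)):
        A, R, W = r.activity, r.net_production, r.washout
        delta = N * r.diff_output
        if k == 0:
            gamma = math.nan  # amplification is defined for progenitor levels
            pi = 0.0
        else:
            if A == 0:
                raise ValueError(f"degenerate hierarchy: A_k = 0 at progenitor level {k}")
            gamma = delta / delta_prev
            pi = W / A
        eps = r.death / A if A > 0 else 0.0
        rows.append(
            dict(k=k, N_k=N, A_k=A, R_k=R, W_k=W, delta_k=delta,
                 gamma_k=gamma, pi_k=pi, eps_k=eps,
                 sym_diff=r.sym_diff, asym_diff=r.asym_diff,
                 sym_renewal=r.sym_renewal, death=r.death)
        )
        delta_prev = delta
    return pd.DataFrame(rows).set_index("k")


def derived_quantities(H: Hierarchy) -> pd.DataFrame:
    """Per-level table of (N_k, A_k, R_k, W_k, delta_k, gamma_k, pi_k, eps_k)."""
    return H._df.copy()


def _solve_level_rates(output: float, washout: float, asym_fraction: float) -> LevelRates:
    """Solve the four per-cell rates from the differentiation output rate
    ``2 r_sym_diff + r_asym``, the washout ``W`` and the asymmetric fraction.

    Death is fixed to zero: cell death only adds divisional burden, so the
    risk analysis omits it (the derived quantities still support it).
    """
    r_asym = asym_fraction * output
    r_sym_diff = 0.5 * (1.0 - asym_fraction) * output
    r_renew = r_sym_diff - washout
    if not (math.isfinite(r_renew) and r_renew >= -1e-15 * max(1.0, output)):
        raise ValueError(
            "invalid spec: solved self-renewal rate is negative "
            f"(asym_fraction too large for this gamma): {r_renew}"
        )
    return LevelRates(sym_diff=r_sym_diff, asym_diff=r_asym,
                      sym_renewal=max(r_renew, 0.0), death=0.0)


def build_hierarchy(spec: TissueSpec) -> Hierarchy:
    """Construct the concrete hierarchy realizing a :class:`TissueSpec`.

    Under the geometric cell-number rule ``N_k = N0 * gamma**k`` the
    construction is fixed by three requirements: the lifetime terminal
    output ``delta_{n-1} * t_life = N``, uniform amplification
    ``gamma_k = gamma`` at every progenitor level, and homeostasis
    ``delta_{k-1} = N_k W_k``.  The stem level carries no washout
    (``W_0 = 0``) and emits differentiated cells at
    ``delta_0 = (N / t_life) / gamma**(n-1)``.
    """
    n, g = spec.n, spec.gamma
    delta0 = (spec.N / spec.t_life) / g ** (n - 1)
    cell_numbers = [spec.N0 * g ** k for k in range(n)]
    rates: list[LevelRates] = []
    # stem level: W_0 = 0, output delta0 = N0 * (2 r_sym_diff + r_asym)
    out0 = delta0 / spec.N0
    a0 = spec.asym_fraction if spec.stem_asym_fraction is None else spec.stem_asym_fraction
    r_asym0 = a0 * out0
    r_sym0 = 0.5 * (1.0 - a0) * out0
    rates.append(LevelRates(sym_diff=r_sym0, asym_diff=r_asym0,
                            sym_renewal=r_sym0, death=0.0))
    delta_prev = delta0
    for k in range(1, n):
        delta_k = delta_prev * g
        W = delta_prev / cell_numbers[k]
        output = delta_k / cell_numbers[k]  # = (R_k + W_k) per cell
        rates.append(_solve_level_rates(output, W, spec.asym_fraction))
        delta_prev = delta_k
    return Hierarchy(n=n, cell_numbers=tuple(cell_numbers),
                     rates=tuple(rates), t_life=spec.t_life)


def gamma_star(N: float, N0: float, n: int) -> float:
    """Amplification factor minimizing lifetime divisional load, ``(N/N0)**(1/n)``."""
    if not (N >= N0 >= 1 and n >= 1):
        raise ValueError("require N >= N0 >= 1 and n >= 1")
    return (N / N0) ** (1.0 / n)


def n_opt(N: float, N0: float) -> float:
    """Number of levels of the fully optimal hierarchy, ``log2(N/N0)``.

    Returned as a real number; round or floor to taste when quoting an
    integer level count.
    """
    if not N >= N0 >= 1:
        raise ValueError("require N >= N0 >= 1")
    return math.log2(N / N0)
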