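# Methods

## Model

A self-renewing tissue is arranged into `n + 1` differentiation levels:
`N0` stem cells at level 0, progenitors at levels `0 < k < n`, and
terminally differentiated cells at level `n`, which do not divide. Each
non-terminal level is described by per-cell rates of four events: symmetric
differentiation `r↑↑` (both daughters move one level up), asymmetric
division `r∘↑`, symmetric self-renewal `r∘∘`, and death `r×`. Derived
per-level quantities:

- divisional activity `A_k = r↑↑ + r∘↑ + r∘∘`, net production `R_k = A_k − r×`;
- washout `W_k = r↑↑ − r∘∘ + r×`: the net per-cell rate at which a level's
  cells plus their same-level descendants are depleted;
- differentiation output `δ_k = N_k (2 r↑↑ + r∘↑)`; homeostasis pins
  `δ_{k−1} = N_k W_k` at every progenitor level and `W_0 = 0`;
- amplification factor `γ_k = δ_k / δ_{k−1} = (R_k + W_k)/W_k ≥ 2`;
- proliferative disadvantage `π_k = W_k / A_k = (1 − ε_k)/(γ_k − 1)` with
  the death-to-birth ratio `ε_k = r× / A_k`.

The builder constructs hierarchies with uniform `γ`, geometric cell numbers
`N_k = N0 γ^k`, no cell death, and lifetime output `δ_{n−1} t_life = N`.
Under this rule the dimensionless washout `W_k t_life = (N/N0)/γ^n` is one
number for all progenitor levels and every risk quantity depends on tissue
size only through `N/N0` (plus `N0` as a prefactor of the stem term). The
division-type mix defaults to purely symmetric events (`asym_fraction = 0`);
at a progenitor level an asymmetric fraction is feasible only up to
`1 − 2/γ`. Time unit: years; default lifetime 80 y.

Drivers of strength `s` arrive with probability `mu` in each daughter cell
at every division and raise self-renewal by `s·A_k` per copy, so a cell with
`d` drivers has `Ŵ = W − d s A` and `Â = A(1 + d s)`. The critical count is
`d_crit = ⌈π/s⌉` (ceiling computed with a 1e-9 relative guard so analytic
integer boundaries stay put). The terminal level is unaffected, and stem
cells record drivers without a rate change (mutant stem-pool expansion is
neglected; drivers acting on stem rates would shift the optimum to larger
`γ` but leave the trade-off intact, and are out of scope). A second driver
mode, `neutral_until_critical`, keeps wild-type rates below `d_crit`.

## Lifetime risk

The probability `Q_k(d, t)` that one cell appearing at level `k` at time `t`
with `d` drivers founds a sublineage reaching `d_crit` is filled by a
backward recursion over `(k, d)` from the boundaries `Q_k(d_crit, ·) = 1`
and `Q_n(·, ·) = 0`, using the expected differentiated and same-level birth
counts `m↑ = (Â + Ŵ) τ̂` and `m∘ = (Â − Ŵ) τ̂`, where
`τ̂ = (1 − e^{−Ŵ(t_life − t)})/Ŵ`. Because the recursion multiplies
expected descendant counts, it overestimates the true probability whenever
entries are not small; `m↑ = (1 + π̂)/(π̂ − d s) > 1` at every subcritical
class, so near-critical entries would otherwise grow geometrically across
levels (by many orders of magnitude at tissue scale). Each entry is
therefore saturated at 1: the linear recursion is exact in the small-`Q`
regime and the cap is exact in the guaranteed-criticality regime; only the
crossover region is approximated.

Stem lineages follow a linear ODE system for `N0(d, t)`, the expected
number of stem cells with `d` drivers whose progenitor offspring have not
yet reached criticality: mutation moves mass up the `d` axis at rate
`r0∘·mu` and differentiated births remove it into the cancer sink at rate
`r0↑·q0(d, t)`, with `q0 = (1−mu)Q_1(d, t) + mu Q_1(d+1, t)` and `q0 = 1`
for `d ≥ d_crit` (those states are absorbed into one bucket). The lifetime
risk is the accumulated sink hazard plus the contribution of the progenitor
cells already present at `t = 0`:

    P = Σ_d ∫ r0↑ q0(d,t) N0(d,t) dt  +  Σ_{k=1}^{n−1} N_k Q_k(0, 0).

`P` is an expectation-style accumulation and is reported raw (it may exceed
1; a capped value is provided). Numerics: uniform time grid with `M = 2000`
intervals shared by the table and the ODE (`q0` interpolated linearly);
LSODA with relative tolerance 1e-8 and absolute tolerance `1e-12·N0`
(BDF fallback); the sink hazard is integrated as an auxiliary ODE state
because early in the optimizer's level loop stem rates reach `1e9`/yr and
the `d_crit` bucket empties inside a fraction of one grid step — fixed-grid
quadrature misses that boundary layer entirely. The survival weight
switches to a 3-term series when `Ŵ(t_life − t) < 1e-6`. Doubling `M`
moves tissue-scale risks by well under 0.5% (tested).

## Drift-barrier optimization

Starting at `n = 1`, the lifetime risk is minimized over the uniform `γ`;
if the minimum exceeds the threshold (2% blood, 4% colon), `n` is increased
by one. The `γ` scan covers the trade-off interval `[2, γ*(n)]`,
`γ* = (N/N0)^{1/n}`, between maximal washing out and minimal divisional
load. `γ*` is also the boundary of the model's validity: beyond it
`W t_life < 1`, progenitor washout outlasts the lifetime, the standing
populations are relics of development (whose divisional history the risk
expression does not model), and the computed risk becomes an artefact
floor with minima pinned to `d_crit` breakpoints. The scan uses a 64-point
log grid plus both sides of every breakpoint `γ = 1 + 1/(m s)` (the risk is
discontinuous there), then golden-section refinement inside the best
segment; refinement is skipped while the coarse minimum exceeds 1000× the
threshold, since a local polish never recovers three orders of magnitude.
At `n = 1` there is no progenitor level and the scan degenerates to
`γ = 2` (risk depends on `γ` only through the prospective `d_crit`,
maximal there). Risk evaluations are cached across the level loop and
(s, mu) scan grids.

Representative parameter points for reproducing the published organization
ranges: blood `N0 = 1e4`, `N = 1e15`, `mu = 2.5e-6` (≈2500 driver targets ×
1e-9 per-bp rate), `s = 0.1`; colon `N0 = 1e8`, `N = 1e14`, `mu = 1e-5`,
`s = 0.1`. With these the package finds blood `n_drift = 18`,
`γ_drift = 4.08 = γ*(18)`, `d_crit = 4`; colon `n_drift = 7`,
`γ_drift = 2.03`, `d_crit = 10` — colon stem cells divide ~3000× faster
than blood's at matched `(mu, s)`. The colon minimum is interior but lies
1.5% from the maximal-washing-out boundary `γ = 2`; it is reported at the
refinement's resolution rather than snapped to the boundary.

## Stochastic validation

The simulator is an exact Gillespie process over (level, driver-count)
class occupancies — exchangeability within a class makes this aggregation
lossless. Each daughter mutates independently with probability `mu`;
a replicate ends at the first creation of a supercritical progenitor
(`d ≥ d_crit` at `0 < k < n`) or at `t_life`. Replicates use
counter-derived per-replicate seeds, so results are deterministic and
order-insensitive; the inner loop is numba-compiled.

The fixture generator samples tissues on which 1e4 replicates are cheap and
the analytic solver's linearization is valid, since the comparison is only
meaningful inside the solver's stated regime:

- `n ∈ [2, 4]`, integer `N0 ∈ [1, 20]` and integer `γ ∈ [2, 6]` (exact
  integer occupancies), `s ∈ [0.3, 1]` with `d_crit ≤ 3`;
- the most-mutated subcritical class keeps `Ŵ(d_crit−1) ≥ 0.25 W`
  (not almost-critical) and `mu` is capped so `2 mu (γ̂(d_crit−1) − 1) ≤ 0.2`
  (sublineage driver arrivals stay rare), `mu ∈ [1e-3, 1e-1]` log-uniform
  otherwise;
- every table entry satisfies `Q ≤ 0.02`, and the lifetime output `N` is
  calibrated so the analytic risk sits near 0.03 (`N ≤ 4000` keeps a
  replicate at a few thousand events; `W t_life ≥ 2` keeps washout resolved
  within the lifetime);
- stem divisions are purely asymmetric (`stem_asym_fraction = 1`): the
  analytic equations see only the composite rates `r0↑`, `r0∘`, which are
  invariant to the stem division mix, but a symmetric-division stem pool is
  a critical branching process that in tissues of 1–20 stem cells goes
  extinct in most replicates, which the regulated-pool ODE deliberately
  does not describe.

Against these fixtures the analytic risk agrees with the simulated
frequency within 4 binomial standard errors at 1e4 replicates. What this
does and does not show: the fixtures exercise the full pipeline (multi-level
hierarchies, asymmetric divisions, multiple drivers, both terms of the risk
sum) but at driver rates ~1e3-fold above and tissue sizes ~1e11-fold below
the physiological regime, where the linear recursion needs no cap; the
tissue-scale predictions additionally rely on the saturation behaviour
documented above, which the desk-scale oracle cannot probe.

## Known limitations

- The developmental growth phase enters only as the `t = 0` standing
  population with wild-type `Q`; mutations acquired during development are
  not modeled, which is why the optimizer does not scan `γ > γ*(n)`.
- Cell death is carried by the data model (`ε_k` in full generality) but
  fixed to zero by the builder; death only adds divisional load.
- Drivers reducing `r↑↑` (possible only for `γ > 2`) and drivers acting on
  stem rates are not modeled; heterogeneous driver strengths and passenger
  mutations are out of scope.
- Stochastic extinction of a freshly supercritical clone is neglected on
  both the analytic and the simulated side (a marginally critical clone at
  a high level may in reality die out).
- The colon/blood predictions inherit the geometric `N_k` reconstruction;
  other homeostatic cell-number profiles consistent with uniform `γ` would
  shift the quantitative optima.
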