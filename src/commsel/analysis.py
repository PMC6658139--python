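"""Deterministic ODE-level analyses of the Helper–Manufacturer community.

These analyses interpret the selection dynamics: the community-function
landscape over (cost, Newborn composition) and its optimum, the
steady-state species composition and the iterated cycle map that converges
to it, the Manufacturer-monoculture optimum, the analytic approximation to
the optimal cost, and the fluctuation statistics of pipetted Newborns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics_core import ChemState, deterministic_trajectory, multigroup_trajectory
from .params import DEFAULT_FIXED, PREADAPTED_GROWTH, FixedParams, GrowthParams

__all__ = [
    "LandscapeResult",
    "community_function_landscape",
    "steady_state_phiM",
    "cycle_map_phiM",
    "monoculture_optimum",
    "optimal_fP_approx",
    "optimal_fP_exact",
    "newborn_fluctuation_stats",
    "growth_parameter_deviation_effect",
]


@dataclass
class LandscapeResult:
    """P(T) over the (f_P, phi_M(0)) grid and its global maximum."""

    f_P: np.ndarray  # grid values along axis 0
    phi_M0: np.ndarray  # grid values along axis 1
    P_T: np.ndarray  # (len(f_P), len(phi_M0)); NaN where not evaluated
    f_P_star: float
    phi_M0_star: float
    P_star: float


def _landscape_point(f_P, phi_M0, growth, fixed, BM0, R0, T, rtol, atol):
    traj = deterministic_trajectory(
        (BM0 * (1.0 - phi_M0), BM0 * phi_M0, ChemState(R=R0)),
        growth, fixed, f_P, T, rtol=rtol, atol=atol,
    )
    return float(traj.P[-1])


def community_function_landscape(
    growth: GrowthParams = PREADAPTED_GROWTH,
    fixed: FixedParams = DEFAULT_FIXED,
    *,
    BM0: float = 100.0,
    R0: float = 1.0,
    T: float = 17.0,
    resolution: float = 0.01,
    coarse_refine: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> LandscapeResult:
    """Deterministic community function over the full composition grid.

    Evaluates P(T) for ``f_P = resolution*i`` and ``phi_M(0) = resolution*j``
    over the open unit square and returns the grid with its unique argmax.
    With ``coarse_refine=True`` a 0.05-resolution pre-scan is followed by
    a local 0.01 refinement around the coarse optimum (the unevaluated grid
    cells remain NaN); both routes return the same argmax.
    """
    f_vals = np.round(np.arange(resolution, 1.0 - resolution / 2, resolution), 10)
    p_vals = f_vals.copy()
    P = np.full((len(f_vals), len(p_vals)), np.nan)

    def point(i, j):
        if np.isnan(P[i, j]):
            P[i, j] = _landscape_point(f_vals[i], p_vals[j], growth, fixed,
                                       BM0, R0, T, rtol, atol)
        return P[i, j]

    if coarse_refine:
        stride = max(1, int(round(0.05 / resolution)))
        coarse = [(i, j) for i in range(0, len(f_vals), stride)
                  for j in range(0, len(p_vals), stride)]
        best = max(coarse, key=lambda ij: point(*ij))
        for _ in range(50):  # hill-climb the refinement window until stable
            i0, j0 = best
            lo_i, hi_i = max(0, i0 - stride), min(len(f_vals), i0 + stride + 1)
            lo_j, hi_j = max(0, j0 - stride), min(len(p_vals), j0 + stride + 1)
            cells = [(i, j) for i in range(lo_i, hi_i) for j in range(lo_j, hi_j)]
            new_best = max(cells, key=lambda ij: point(*ij))
            if new_best == best:
                break
            best = new_best
        i_star, j_star = best
    else:
        for i in range(len(f_vals)):
            for j in range(len(p_vals)):
                point(i, j)
        i_star, j_star = np.unravel_index(np.nanargmax(P), P.shape)

    return LandscapeResult(
        f_P=f_vals, phi_M0=p_vals, P_T=P,
        f_P_star=float(f_vals[i_star]),
        phi_M0_star=float(p_vals[j_star]),
        P_star=float(P[i_star, j_star]),
    )


def steady_state_phiM(f_P: float, c_BM: float = 1.0 / 3.0) -> float:
    """Closed-form steady-state Manufacturer biomass fraction.

    ``(1-f_P) / (1-f_P + c_BM)`` — valid when the Byproduct is driven to
    ~0 within a cycle, which holds for costs below roughly 0.4.
    """
    return (1.0 - f_P) / (1.0 - f_P + c_BM)


def cycle_map_phiM(
    f_P: float,
    growth: GrowthParams = PREADAPTED_GROWTH,
    fixed: FixedParams = DEFAULT_FIXED,
    *,
    phi_M0: float = 0.5,
    n_cycles: int = 30,
    BM_target: float = 100.0,
    R0: float = 1.0,
    T: float = 17.0,
):
    """Iterate the deterministic within-cycle map of the species fraction.

    Each cycle integrates the coupled equations for time T, then resets
    total biomass to ``BM_target`` and the chemicals to fresh conditions
    while keeping the species fraction.  Returns ``(phis, extinct)`` where
    ``phis[k]`` is phi_M(T) of cycle k and ``extinct`` flags the fraction
    dropping below ``1/BM_target`` (Manufacturer lost from a Newborn).
    """
    phis = []
    phi = phi_M0
    extinct = False
    for _ in range(n_cycles):
        traj = deterministic_trajectory(
            (BM_target * (1.0 - phi), BM_target * phi, ChemState(R=R0)),
            growth, fixed, f_P, T,
        )
        phi = float(traj.phi_M[-1])
        phis.append(phi)
        if phi < 1.0 / BM_target or phi > 1.0 - 1.0 / BM_target:
            extinct = True
            break
    return np.array(phis), extinct


def monoculture_optimum(
    growth: GrowthParams = PREADAPTED_GROWTH,
    fixed: FixedParams = DEFAULT_FIXED,
    *,
    R0: float = 1.0,
    T: float = 17.0,
    resolution: float = 0.01,
):
    """Cost maximizing P(T) of a single-founder Manufacturer group.

    The group starts from one cell of biomass 1 with saturating Byproduct
    (growth follows the Monod limit in Resource only).  Returns
    ``(f_P_star, P_star)`` from a grid search at the given resolution.
    """
    best = (float("nan"), -np.inf)
    for f_P in np.round(np.arange(resolution, 1.0 - resolution / 2, resolution), 10):
        traj = deterministic_trajectory(
            (0.0, 1.0, ChemState(R=R0)), growth, fixed, float(f_P), T,
            excess_B=True,
        )
        P = float(traj.P[-1])
        if P > best[1]:
            best = (float(f_P), P)
    return best


def optimal_fP_approx(gM_integral: float) -> float:
    """Leading-order optimal cost ``1 / int g_M dt`` (valid when >> 1)."""
    if gM_integral <= 0:
        raise ValueError("gM_integral must be > 0")
    return 1.0 / gM_integral


def optimal_fP_exact(gM_integral: float) -> float:
    """Exact optimizer of the closed-form P(T): root of fP(1-fP) = 1/int g."""
    if gM_integral <= 4.0:
        raise ValueError("closed-form optimum requires int g_M dt > 4")
    return 0.5 * (1.0 - np.sqrt(1.0 - 4.0 / gM_integral))


def newborn_fluctuation_stats(BM_target: float, phi_M: float,
                              mean_cell_length: float = 1.5):
    """Pipetting fluctuation statistics of Newborn composition.

    Under Poissonian cell sampling the Newborn total biomass has standard
    deviation ``sqrt(BM_target * L_bar)`` and the biomass ratio M(0)/H(0)
    has variance ``phi_M / (1-phi_M)^3 * L_bar / BM_target``.
    """
    if not 0 < phi_M < 1:
        raise ValueError("phi_M must lie strictly between 0 and 1 for the "
                         "ratio variance")
    sd_BM = float(np.sqrt(BM_target * mean_cell_length))
    var_ratio = phi_M / (1.0 - phi_M) ** 3 * mean_cell_length / BM_target
    return sd_BM, float(var_ratio)


def growth_parameter_deviation_effect(
    param: str,
    *,
    f_P: float,
    factor: float = 0.9,
    growth: GrowthParams = PREADAPTED_GROWTH,
    fixed: FixedParams = DEFAULT_FIXED,
    phi_M0: float | None = None,
    BM0: float = 100.0,
    R0: float = 1.0,
    T: float = 17.0,
):
    """Effect of lowering one growth parameter below its upper bound.

    Runs (a) the uniform community with the parameter reduced by the given
    factor, versus the preadapted baseline, and (b) a within-community
    competition where 10% of the affected species carries the reduced
    parameter.  Returns ``(dP_rel, dfreq_rel)``: the relative change in
    community function and the relative change of the mutant's
    within-species frequency over one maturation.  Negative values mean the
    deviation is disfavored at both levels of selection.
    """
    if phi_M0 is None:
        phi_M0 = steady_state_phiM(f_P, fixed.c_BM)
    base = deterministic_trajectory(
        (BM0 * (1 - phi_M0), BM0 * phi_M0, ChemState(R=R0)),
        growth, fixed, f_P, T)
    lowered = growth.replace(**{param: getattr(growth, param) * factor})
    alt = deterministic_trajectory(
        (BM0 * (1 - phi_M0), BM0 * phi_M0, ChemState(R=R0)),
        lowered, fixed, f_P, T)
    dP_rel = (float(alt.P[-1]) - float(base.P[-1])) / float(base.P[-1])

    h_of = param in ("g_Hmax", "aff_HR")
    H0, M0 = BM0 * (1 - phi_M0), BM0 * phi_M0
    if h_of:
        h_groups = [(0.9 * H0, growth.g_Hmax, growth.aff_HR),
                    (0.1 * H0, lowered.g_Hmax, lowered.aff_HR)]
        m_groups = [(M0, growth.g_Mmax, growth.aff_MR, growth.aff_MB, f_P)]
    else:
        h_groups = [(H0, growth.g_Hmax, growth.aff_HR)]
        m_groups = [(0.9 * M0, growth.g_Mmax, growth.aff_MR, growth.aff_MB, f_P),
                    (0.1 * M0, lowered.g_Mmax, lowered.aff_MR, lowered.aff_MB, f_P)]
    traj = multigroup_trajectory(h_groups, m_groups, ChemState(R=R0), fixed, T)
    pops = traj.H if h_of else traj.M
    freq0 = 0.1
    freqT = float(pops[1, -1] / (pops[0, -1] + pops[1, -1]))
    dfreq_rel = (freqT - freq0) / freq0
    return dP_rel, dfreq_rel
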