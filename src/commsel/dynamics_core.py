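"""Growth-rate laws and chemical dynamics of the Helper–Manufacturer community.

Two integration paths are provided on purpose:

* :func:`integrate_chem_step` — the operator-splitting step used by the
  agent simulation: biomasses are frozen for one short interval, only
  Resource and Byproduct evolve, and the per-phenotype-group growth
  integrals are accumulated as augmented ODE states.
* :func:`deterministic_trajectory` — the fully coupled continuous-biomass
  equations, solved with an adaptive stiff-capable solver.  This is the
  engine behind the landscape/steady-state analyses and serves as an
  independent oracle for the agent layer.

All quantities are scaled: Resource in units of the Newborn supply R(0),
Byproduct in units of the release per Helper biomass grown, Product in units
of the make per Manufacturer biomass of cost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .params import FixedParams, GrowthParams

__all__ = [
    "ChemState",
    "monod_rate",
    "mankad_bungay_rate",
    "h_inhibition_factor",
    "integrate_chem_step",
    "deterministic_trajectory",
    "multigroup_trajectory",
    "Trajectory",
    "SolverError",
]


class SolverError(RuntimeError):
    """Chemical/trajectory integration failed; carries the offending state."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class ChemState:
    """Extracellular chemical amounts of one community (scaled units)."""

    R: float = 1.0
    B: float = 0.0
    P: float = 0.0

    def __post_init__(self):
        if self.R < 0 or self.B < 0 or self.P < 0:
            raise ValueError(f"chemical amounts must be >= 0, got {self}")

    def replace(self, **kw) -> "ChemState":
        return replace(self, **kw)


def monod_rate(R, g_max, aff):
    """Monod growth rate ``g_max * R / (R + 1/aff)``.

    ``aff`` is the affinity 1/K; a null affinity (0) means K -> infinity and
    hence zero growth at any finite substrate level.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0) or g_max < 0 or aff < 0:
        raise ValueError("monod_rate requires non-negative arguments")
    if aff == 0:
        return np.zeros_like(R)[()] if R.ndim == 0 else np.zeros_like(R)
    out = g_max * R / (R + 1.0 / aff)
    return float(out) if out.ndim == 0 else out


def mankad_bungay_rate(R, B, g_max, aff_MR, aff_MB):
    """Dual-substrate growth rate of the Manufacturer.

    With scaled substrate levels ``R_M = R*aff_MR`` and ``B_M = B*aff_MB``::

        g = g_max * R_M*B_M/(R_M+B_M) * (1/(R_M+1) + 1/(B_M+1))

    When either substrate (or affinity) is zero the rate is zero; when one
    substrate is saturating the monosubstrate Monod form is recovered.
    """
    R = np.asarray(R, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(R < 0) or np.any(B < 0) or g_max < 0 or aff_MR < 0 or aff_MB < 0:
        raise ValueError("mankad_bungay_rate requires non-negative arguments")
    RM = R * aff_MR
    BM = B * aff_MB
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            (RM > 0) & (BM > 0),
            g_max * (RM * BM / (RM + BM)) * (1.0 / (RM + 1.0) + 1.0 / (BM + 1.0)),
            0.0,
        )
    return float(out) if out.ndim == 0 else out


def h_inhibition_factor(B, B0=None):
    """Byproduct inhibition of Helper growth, ``exp(-B/B0)``.

    ``B0 is None`` selects the commensal model (no inhibition, factor 1).
    """
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise ValueError("B must be >= 0")
    if B0 is None:
        return 1.0 if B.ndim == 0 else np.ones_like(B)
    if B0 <= 0:
        raise ValueError("B0 must be > 0 or None")
    out = np.exp(-B / B0)
    return float(out) if out.ndim == 0 else out


def integrate_chem_step(
    chem: ChemState,
    h_groups,
    m_groups,
    dtau: float,
    fixed: FixedParams = FixedParams(),
    *,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    excess_B: bool = False,
):
    """Advance Resource and Byproduct over one interval with frozen biomasses.

    Parameters
    ----------
    h_groups
        ``(biomass, g_Hmax, aff_HR)`` arrays, one entry per Helper phenotype
        group (biomass frozen at its start-of-step value).
    m_groups
        ``(biomass, g_Mmax, aff_MR, aff_MB)`` arrays per Manufacturer group.
    excess_B
        Treat Byproduct as saturating (monoculture groups): Manufacturer
        growth follows the Monod limit in Resource only and Byproduct is not
        consumed.

    Returns
    -------
    (ChemState, IH, IM)
        Updated chemicals (Product unchanged — it is bookkept from biomass
        deltas in the agent layer) and per-group growth integrals
        ``int g dt`` over the step.
    """
    if dtau <= 0:
        raise ValueError("dtau must be > 0")
    Hb, Hg, Ha = (np.atleast_1d(np.asarray(a, dtype=float)) for a in h_groups)
    Mb, Mg, Mar, Mab = (np.atleast_1d(np.asarray(a, dtype=float)) for a in m_groups)
    y = _kernels.chem_step(
        chem.R, chem.B, Hb, Hg, Ha, Mb, Mg, Mar, Mab,
        fixed.c_RM, fixed.c_RH, fixed.c_BM, fixed.b0_inv, excess_B,
        dtau, rtol, atol,
    )
    if not np.all(np.isfinite(y)):
        raise SolverError("chemical step produced non-finite state", state=y)
    nH = len(Hb)
    new = ChemState(R=max(y[0], 0.0), B=max(y[1], 0.0), P=chem.P)
    IH = np.where(Hb > 0, y[2 : 2 + nH], 0.0)  # empty groups grow nothing
    IM = np.where(Mb > 0, y[2 + nH :], 0.0)
    return new, IH, IM


@dataclass
class Trajectory:
    """Deterministic time series of a community (continuous biomass)."""

    t: np.ndarray
    H: np.ndarray  # (n_t,) or (n_h_groups, n_t)
    M: np.ndarray
    P: np.ndarray
    R: np.ndarray
    B: np.ndarray

    @property
    def H_total(self):
        return self.H if self.H.ndim == 1 else self.H.sum(axis=0)

    @property
    def M_total(self):
        return self.M if self.M.ndim == 1 else self.M.sum(axis=0)

    @property
    def BM(self):
        return self.H_total + self.M_total

    @property
    def phi_M(self):
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.M_total / self.BM


def multigroup_trajectory(
    h_groups: Sequence[tuple],
    m_groups: Sequence[tuple],
    chem: ChemState,
    fixed: FixedParams,
    T: float,
    *,
    excess_B: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    t_eval=None,
) -> Trajectory:
    """Integrate the coupled equations for arbitrary phenotype groups.

    ``h_groups`` entries are ``(H0, g_Hmax, aff_HR)``; ``m_groups`` entries
    are ``(M0, g_Mmax, aff_MR, aff_MB, f_P)``.  Used both for the standard
    one-group-per-species analyses and for within-community competition
    experiments between phenotypes.
    """
    nH = len(h_groups)
    nM = len(m_groups)
    Hg = np.array([g[1] for g in h_groups], dtype=float)
    Ha = np.array([g[2] for g in h_groups], dtype=float)
    Mg = np.array([g[1] for g in m_groups], dtype=float)
    Mar = np.array([g[2] for g in m_groups], dtype=float)
    Mab = np.array([g[3] for g in m_groups], dtype=float)
    MfP = np.array([g[4] for g in m_groups], dtype=float)
    y0 = np.concatenate(
        [
            [g[0] for g in h_groups],
            [g[0] for g in m_groups],
            [chem.P, chem.R, chem.B],
        ]
    ).astype(float)
    args = (Hg, Ha, Mg, Mar, Mab, MfP, fixed.c_RM, fixed.c_RH, fixed.c_BM,
            fixed.delta_M, fixed.delta_H, fixed.b0_inv, excess_B)

    def rhs(t, y):
        return _kernels.coupled_rhs(t, y, *args)

    sol = solve_ivp(rhs, (0.0, T), y0, method="LSODA", rtol=rtol, atol=atol,
                    t_eval=t_eval)
    if not sol.success:
        raise SolverError(f"trajectory integration failed: {sol.message}",
                          state=y0)
    y = np.clip(sol.y, 0.0, None)
    return Trajectory(
        t=sol.t,
        H=y[:nH] if nH != 1 else y[0],
        M=y[nH : nH + nM] if nM != 1 else y[nH],
        P=y[nH + nM],
        R=y[nH + nM + 1],
        B=y[nH + nM + 2],
    )


def deterministic_trajectory(
    init,
    growth: GrowthParams,
    fixed: FixedParams,
    f_P: float,
    T: float,
    *,
    excess_B: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    t_eval=None,
) -> Trajectory:
    """Coupled continuous-biomass dynamics with a uniform Manufacturer cost.

    ``init`` is ``(H0, M0, ChemState)``.  Death terms are always included.
    """
    H0, M0, chem = init
    if H0 < 0 or M0 < 0:
        raise ValueError("initial biomasses must be >= 0")
    if not 0 <= f_P <= 1:
        raise ValueError("f_P must lie in [0, 1]")
    return multigroup_trajectory(
        [(H0, growth.g_Hmax, growth.aff_HR)],
        [(M0, growth.g_Mmax, growth.aff_MR, growth.aff_MB, f_P)],
        chem,
        fixed,
        T,
        excess_B=excess_B,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
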