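"""Individual-cell layer: one community maturing from Newborn to Adult.

A community is stored as a structure of arrays (species, length, phenotype
columns) plus its chemical state.  Maturation repeats, per time step:
chemical integration with frozen biomasses, deterministic biomass growth
with Product bookkeeping, stochastic death, division at length 2, and
mutation of freshly divided cells.

Two engines implement the same step sequence: ``engine="fast"`` runs the
whole maturation inside a compiled kernel (used by selection runs), and
``engine="reference"`` composes the public numpy operations below step by
step.  With stochasticity disabled the two agree to floating-point
round-off; with stochasticity enabled each is exactly reproducible from its
seed (the two engines draw from different generators and are compared
statistically, not draw for draw).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from . import _kernels
from .dynamics_core import ChemState, integrate_chem_step
from .mutation import MutationModel, mutate_cells
from .params import DEFAULT_BOUNDS, FixedParams, GrowthParams, PhenotypeBounds

__all__ = ["Cell", "Community", "PhenotypeGroups", "apply_growth",
           "apply_death", "apply_division", "mature"]

H = 0
M = 1


@dataclass(frozen=True)
class Cell:
    """One cell: species, biomass (length) and heritable phenotypes."""

    species: int  # 0 = Helper, 1 = Manufacturer
    L: float
    g_max: float
    aff_R: float
    aff_B: float = 0.0  # Manufacturer only
    f_P: float = 0.0  # Manufacturer only

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("cell length must be > 0")
        if not 0 <= self.f_P <= 1:
            raise ValueError("f_P must lie in [0, 1]")


@dataclass
class Community:
    """One culture: a cell population, its chemicals and its logged seed."""

    species: np.ndarray
    L: np.ndarray
    g_max: np.ndarray
    aff_R: np.ndarray
    aff_B: np.ndarray
    f_P: np.ndarray
    chem: ChemState = field(default_factory=ChemState)
    seed: int | None = None
    lineage_id: int | None = None
    extinct: bool = False

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_cells(cls, cells: Iterable[Cell], chem: ChemState = ChemState(),
                   **kw) -> "Community":
        cells = list(cells)
        return cls(
            species=np.array([c.species for c in cells], dtype=np.int8),
            L=np.array([c.L for c in cells], dtype=float),
            g_max=np.array([c.g_max for c in cells], dtype=float),
            aff_R=np.array([c.aff_R for c in cells], dtype=float),
            aff_B=np.array([c.aff_B for c in cells], dtype=float),
            f_P=np.array([c.f_P for c in cells], dtype=float),
            chem=chem,
            **kw,
        )

    @classmethod
    def from_counts(cls, n_H: int, n_M: int, growth: GrowthParams, f_P: float,
                    chem: ChemState = ChemState(), L: float = 1.0, **kw) -> "Community":
        """Monomorphic community of ``n_H`` Helpers and ``n_M`` Manufacturers."""
        n = n_H + n_M
        species = np.concatenate(
            [np.zeros(n_H, dtype=np.int8), np.ones(n_M, dtype=np.int8)]
        )
        g = np.where(species == H, growth.g_Hmax, growth.g_Mmax).astype(float)
        aR = np.where(species == H, growth.aff_HR, growth.aff_MR).astype(float)
        aB = np.where(species == H, 0.0, growth.aff_MB).astype(float)
        fP = np.where(species == H, 0.0, f_P).astype(float)
        return cls(species=species, L=np.full(n, float(L)), g_max=g,
                   aff_R=aR, aff_B=aB, f_P=fP, chem=chem, **kw)

    # -- summaries ----------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.L)

    @property
    def biomass(self) -> float:
        return float(self.L.sum())

    @property
    def M_biomass(self) -> float:
        return float(self.L[self.species == M].sum())

    @property
    def H_biomass(self) -> float:
        return float(self.L[self.species == H].sum())

    @property
    def I_M(self) -> int:
        return int((self.species == M).sum())

    @property
    def I_H(self) -> int:
        return int((self.species == H).sum())

    @property
    def phi_M(self) -> float:
        """Fraction of community biomass belonging to the Manufacturer."""
        bm = self.biomass
        return self.M_biomass / bm if bm > 0 else float("nan")

    @property
    def phi_M_cells(self) -> float:
        """Fraction of cells (not biomass) that are Manufacturers."""
        n = self.n_cells
        return self.I_M / n if n > 0 else float("nan")

    def mean_f_P(self) -> float:
        m = self.species == M
        return float(self.f_P[m].mean()) if m.any() else float("nan")

    def mean_growth_params(self) -> dict:
        h = self.species == H
        m = self.species == M
        nan = float("nan")
        return {
            "g_Hmax": float(self.g_max[h].mean()) if h.any() else nan,
            "aff_HR": float(self.aff_R[h].mean()) if h.any() else nan,
            "g_Mmax": float(self.g_max[m].mean()) if m.any() else nan,
            "aff_MR": float(self.aff_R[m].mean()) if m.any() else nan,
            "aff_MB": float(self.aff_B[m].mean()) if m.any() else nan,
        }

    # -- structural helpers -------------------------------------------------

    def cells(self) -> Iterator[Cell]:
        for i in range(self.n_cells):
            yield Cell(int(self.species[i]), float(self.L[i]), float(self.g_max[i]),
                       float(self.aff_R[i]), float(self.aff_B[i]), float(self.f_P[i]))

    def subset(self, idx, chem: ChemState | None = None, **kw) -> "Community":
        idx = np.asarray(idx)
        return Community(
            species=self.species[idx].copy(), L=self.L[idx].copy(),
            g_max=self.g_max[idx].copy(), aff_R=self.aff_R[idx].copy(),
            aff_B=self.aff_B[idx].copy(), f_P=self.f_P[idx].copy(),
            chem=chem if chem is not None else self.chem, **kw,
        )

    def copy(self) -> "Community":
        return self.subset(np.arange(self.n_cells), seed=self.seed,
                           lineage_id=self.lineage_id)


@dataclass
class PhenotypeGroups:
    """Exact (bitwise) phenotype grouping used for the chemical solve."""

    h_params: np.ndarray  # (nH, 2): g_Hmax, aff_HR
    m_params: np.ndarray  # (nM, 3): g_Mmax, aff_MR, aff_MB
    gidx: np.ndarray  # per cell, index into its species' table
    h_biomass: np.ndarray
    m_biomass: np.ndarray

    @classmethod
    def build(cls, comm: Community) -> "PhenotypeGroups":
        gidx = np.zeros(comm.n_cells, dtype=np.int64)
        h_mask = comm.species == H
        key_h = np.stack([comm.g_max, comm.aff_R], axis=1)
        key_m = np.stack([comm.g_max, comm.aff_R, comm.aff_B], axis=1)
        hp, hinv = np.unique(key_h[h_mask], axis=0, return_inverse=True) \
            if h_mask.any() else (np.empty((0, 2)), np.empty(0, dtype=np.int64))
        mp, minv = np.unique(key_m[~h_mask], axis=0, return_inverse=True) \
            if (~h_mask).any() else (np.empty((0, 3)), np.empty(0, dtype=np.int64))
        gidx[h_mask] = hinv
        gidx[~h_mask] = minv
        hb = np.bincount(hinv, weights=comm.L[h_mask], minlength=len(hp)) \
            if h_mask.any() else np.empty(0)
        mb = np.bincount(minv, weights=comm.L[~h_mask], minlength=len(mp)) \
            if (~h_mask).any() else np.empty(0)
        return cls(hp, mp, gidx, hb, mb)


def apply_growth(comm: Community, integrals, groups: PhenotypeGroups,
                 dtau: float | None = None) -> Community:
    """Deterministic biomass growth and Product bookkeeping for one step.

    ``integrals`` is the ``(IH, IM)`` pair of per-group growth integrals
    returned by :func:`commsel.dynamics_core.integrate_chem_step` for the
    same step.  Helper lengths scale by ``exp(I)``, Manufacturer lengths by
    ``exp((1-f_P) I)``, and each Manufacturer adds ``f_P/(1-f_P) * dL`` to
    the extracellular Product (the analytic limit ``L*I`` at ``f_P == 1``,
    where biomass does not grow at all).
    """
    IH, IM = integrals
    out = comm.copy()
    h = comm.species == H
    m = ~h
    if h.any():
        out.L[h] = comm.L[h] * np.exp(np.asarray(IH)[groups.gidx[h]])
    dP = 0.0
    if m.any():
        integ = np.asarray(IM)[groups.gidx[m]]
        fP = comm.f_P[m]
        full = fP >= 1.0
        lnew = comm.L[m] * np.exp((1.0 - fP) * integ)
        lnew[full] = comm.L[m][full]
        with np.errstate(divide="ignore", invalid="ignore"):
            dp = np.where(full, comm.L[m] * integ,
                          np.where(fP > 0, fP / (1.0 - fP), 0.0)
                          * (lnew - comm.L[m]))
        dP = float(dp.sum())
        out.L[m] = lnew
    out.chem = out.chem.replace(P=out.chem.P + dP)
    return out


def apply_death(comm: Community, dtau: float, rng: np.random.Generator,
                fixed: FixedParams = FixedParams()) -> Community:
    """Remove each cell independently with its species' death probability."""
    p = np.where(comm.species == H, fixed.delta_H * dtau, fixed.delta_M * dtau)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("death probability per step must lie in [0, 1]")
    keep = rng.random(comm.n_cells) >= p
    out = comm.subset(np.flatnonzero(keep), seed=comm.seed,
                      lineage_id=comm.lineage_id)
    out.extinct = comm.extinct or out.n_cells == 0
    return out


def apply_division(comm: Community):
    """Split every cell with length >= 2 into two cells of half the length.

    Daughters are appended after all existing cells, in mother order, so
    that replay is deterministic.  Returns ``(community, pairs)`` with
    ``pairs`` the ``(mother_index, daughter_index)`` array for the mutation
    step.  Total biomass is conserved exactly.
    """
    div = np.flatnonzero(comm.L >= 2.0)
    out = comm.subset(np.arange(comm.n_cells), seed=comm.seed,
                      lineage_id=comm.lineage_id)
    out.extinct = comm.extinct
    if len(div) == 0:
        return out, np.empty((0, 2), dtype=np.int64)
    out.L[div] *= 0.5
    n0 = out.n_cells
    for col in ("species", "L", "g_max", "aff_R", "aff_B", "f_P"):
        arr = getattr(out, col)
        setattr(out, col, np.concatenate([arr, arr[div]]))
    pairs = np.stack([div, n0 + np.arange(len(div))], axis=1)
    return out, pairs


def mature(
    newborn: Community,
    *,
    T: float,
    dtau: float = 0.05,
    fixed: FixedParams = FixedParams(),
    mut: MutationModel | None = None,
    bounds: PhenotypeBounds = DEFAULT_BOUNDS,
    seed: int | None = None,
    excess_B: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    engine: str = "fast",
) -> Community:
    """Advance a Newborn community to the Adult state at time ``T``.

    The per-step sequence is chemistry -> growth -> death -> division ->
    mutation of divided pairs.  ``seed`` overrides ``newborn.seed``; one of
    the two must be set unless the run is fully deterministic.  An extinct
    community (no cells) continues through chemistry only and is flagged.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    mut = mut if mut is not None else MutationModel(P_mut=0.0)
    seed = seed if seed is not None else newborn.seed
    if seed is None:
        seed = 0
    nsteps = int(round(T / dtau))
    if abs(nsteps * dtau - T) > 1e-9 * max(T, 1.0):
        raise ValueError("T must be an integer multiple of dtau")
    if engine == "fast":
        out = _kernels.mature_kernel(
            np.ascontiguousarray(newborn.species, dtype=np.int8),
            np.ascontiguousarray(newborn.L, dtype=float),
            np.ascontiguousarray(newborn.g_max, dtype=float),
            np.ascontiguousarray(newborn.aff_R, dtype=float),
            np.ascontiguousarray(newborn.aff_B, dtype=float),
            np.ascontiguousarray(newborn.f_P, dtype=float),
            newborn.chem.R, newborn.chem.B, newborn.chem.P,
            fixed.c_RM, fixed.c_RH, fixed.c_BM, fixed.delta_M, fixed.delta_H,
            fixed.b0_inv, excess_B,
            float(nsteps * dtau), dtau, rtol, atol,
            mut.P_mut, mut.p_null, mut.s_plus, mut.s_minus,
            float(mut.epistasis_g or 0.0), mut.fP_init,
            mut.mutable_flags(), bounds.as_array(), np.uint32(seed),
        )
        sp, L, g, aR, aB, fP, R, B, P, ext = out
        return Community(species=sp, L=L, g_max=g, aff_R=aR, aff_B=aB, f_P=fP,
                         chem=ChemState(R=R, B=B, P=P), seed=seed,
                         lineage_id=newborn.lineage_id, extinct=bool(ext))
    if engine != "reference":
        raise ValueError(f"unknown engine {engine!r}")
    rng = np.random.default_rng(seed)
    comm = newborn.copy()
    comm.seed = seed
    for _ in range(nsteps):
        if comm.n_cells == 0:
            comm.extinct = True
            continue  # chemicals are inert without cells
        groups = PhenotypeGroups.build(comm)
        chem, IH, IM = integrate_chem_step(
            comm.chem,
            (groups.h_biomass, groups.h_params[:, 0], groups.h_params[:, 1]),
            (groups.m_biomass, groups.m_params[:, 0], groups.m_params[:, 1],
             groups.m_params[:, 2]),
            dtau, fixed, rtol=rtol, atol=atol, excess_B=excess_B,
        )
        comm.chem = chem
        comm = apply_growth(comm, (IH, IM), groups)
        comm = apply_death(comm, dtau, rng, fixed)
        comm, pairs = apply_division(comm)
        if mut.P_mut > 0 and len(pairs):
            mutate_cells(comm, pairs.ravel(order="C"), mut, bounds, rng)
    comm.extinct = comm.extinct or comm.n_cells == 0
    return comm
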