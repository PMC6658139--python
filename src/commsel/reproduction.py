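"""Splitting a chosen Adult community into Newborn communities.

Methods mirror the experimental procedures they emulate:

* ``pipetting`` — volumetric dilution: every cell is assigned a uniform
  random aliquot among ``n_D = floor(adult_biomass / BM_target)``; Newborn
  biomass and species fraction fluctuate.
* ``sort_biomass`` — a cell sorter fixes both Newborn total biomass and the
  species biomass split to the parent Adult's phi_M(T) (closest achievable
  without exceeding, given that cells are discrete with length in [1, 2)).
* ``sort_cellnumber`` — fixed cell counts per species instead of biomass.
* ``fix_BM_only`` / ``fix_phiM_only`` — fix exactly one of the two Newborn
  composition determinants and let the other fluctuate.
* ``fixed_fold`` — dilute by a constant fold regardless of Adult size.

Chemicals are always reset to Newborn initial conditions (fresh Resource,
no Byproduct, no Product).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .agents import Community, H, M
from .dynamics_core import ChemState
from .params import GrowthParams

__all__ = [
    "ReproductionSpec",
    "AdultTooSmall",
    "dilution_fold",
    "SortingPool",
    "partition_pipetting",
    "partition_sort_biomass",
    "partition_sort_cellnumber",
    "partition_fix_single_determinant",
    "partition_fixed_fold",
    "found_monoculture",
]

METHODS = ("pipetting", "sort_biomass", "sort_cellnumber", "fix_BM_only",
           "fix_phiM_only", "fixed_fold")


class AdultTooSmall(ValueError):
    """Adult biomass below one Newborn target; it cannot contribute."""


@dataclass(frozen=True)
class ReproductionSpec:
    method: str = "pipetting"
    BM_target: float = 100.0
    fixed_fold_nD: int | None = None
    mean_cell_length: float = 1.5

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown reproduction method {self.method!r}")
        if self.BM_target <= 0:
            raise ValueError("BM_target must be > 0")
        if self.method == "fixed_fold" and not self.fixed_fold_nD:
            raise ValueError("fixed_fold requires fixed_fold_nD")

    def replace(self, **kw) -> "ReproductionSpec":
        return replace(self, **kw)


def dilution_fold(adult_BM: float, BM_target: float = 100.0) -> int:
    """``n_D = floor(adult_BM / BM_target)``; raises AdultTooSmall at 0."""
    if adult_BM < 0:
        raise ValueError("adult_BM must be >= 0")
    n_D = int(np.floor(adult_BM / BM_target))
    if n_D == 0:
        raise AdultTooSmall(f"adult biomass {adult_BM} < BM_target {BM_target}")
    return n_D


def _newborn_chem(R0: float) -> ChemState:
    return ChemState(R=R0, B=0.0, P=0.0)


def partition_pipetting(adult: Community, BM_target: float,
                        rng: np.random.Generator, R0: float = 1.0,
                        n_D: int | None = None) -> list[Community]:
    """Random aliquoting of every cell among n_D Newborns.

    The multiset of cells is conserved exactly; empty aliquots are retained
    (they mature trivially and score zero).
    """
    if n_D is None:
        n_D = dilution_fold(adult.biomass, BM_target)
    labels = rng.integers(1, n_D + 1, size=adult.n_cells)
    out = []
    for k in range(1, n_D + 1):
        nb = adult.subset(np.flatnonzero(labels == k), chem=_newborn_chem(R0),
                          lineage_id=adult.lineage_id)
        nb.extinct = False
        out.append(nb)
    return out


def partition_fixed_fold(adult: Community, n_D_fixed: int,
                         rng: np.random.Generator, R0: float = 1.0) -> list[Community]:
    """Constant-fold dilution: pipetting with n_D fixed regardless of size."""
    if n_D_fixed < 1:
        raise ValueError("n_D_fixed must be >= 1")
    return partition_pipetting(adult, BM_target=float("nan"), rng=rng, R0=R0,
                               n_D=n_D_fixed)


class SortingPool:
    """Random-permutation pool over an Adult's cells for sorting methods.

    Repeated draws return disjoint cells; cells skipped because they would
    overshoot a biomass window stay available for subsequent Newborns.
    """

    def __init__(self, adult: Community, rng: np.random.Generator):
        self.adult = adult
        self.order = {
            H: list(rng.permutation(np.flatnonzero(adult.species == H))),
            M: list(rng.permutation(np.flatnonzero(adult.species == M))),
        }

    def remaining(self, species) -> int:
        return len(self.order[species])

    def take_count(self, species, k: int):
        """Draw exactly k cells (uniform, without replacement)."""
        pool = self.order[species]
        if len(pool) < k:
            raise AdultTooSmall(f"pool exhausted: need {k} cells of species {species}")
        taken, self.order[species] = pool[:k], pool[k:]
        return np.array(taken, dtype=np.int64)

    def take_biomass(self, species, target: float):
        """Greedy fill: add cells while total + L <= target; skip overshoots.

        Scanning stops once no cell could fit (remaining headroom < 1, the
        minimum cell length); the realized biomass lies in (target-2, target]
        whenever the pool holds enough cells.
        """
        pool = self.order[species]
        total = 0.0
        taken: list[int] = []
        kept: list[int] = []
        for pos, i in enumerate(pool):
            if target - total < 1.0:
                kept.extend(pool[pos:])
                break
            li = self.adult.L[i]
            if total + li <= target:
                taken.append(i)
                total += li
            else:
                kept.append(i)
        self.order[species] = kept
        return np.array(taken, dtype=np.int64), total


def partition_sort_biomass(adult: Community, BM_target: float,
                           phiM_target: float, rng: np.random.Generator,
                           R0: float = 1.0, pool: SortingPool | None = None) -> Community:
    """One Newborn with both total biomass and species split fixed.

    Manufacturer biomass fills ``BM_target * phiM_target`` (closest without
    exceeding), Helper biomass fills the complement.  Pass a shared
    :class:`SortingPool` to draw several disjoint Newborns from one Adult.
    """
    pool = pool if pool is not None else SortingPool(adult, rng)
    m_idx, m_bio = pool.take_biomass(M, BM_target * phiM_target)
    h_idx, h_bio = pool.take_biomass(H, BM_target * (1.0 - phiM_target))
    return adult.subset(np.concatenate([h_idx, m_idx]), chem=_newborn_chem(R0),
                        lineage_id=adult.lineage_id)


def partition_sort_cellnumber(adult: Community, BM_target: float,
                              phiM_cells: float, rng: np.random.Generator,
                              R0: float = 1.0, mean_cell_length: float = 1.5,
                              pool: SortingPool | None = None) -> Community:
    """One Newborn with fixed cell counts per species.

    ``floor(BM_target*phiM_cells/1.5)`` Manufacturers and
    ``floor(BM_target*(1-phiM_cells)/1.5)`` Helpers, drawn uniformly without
    replacement; counts are independent of individual cell lengths.
    """
    pool = pool if pool is not None else SortingPool(adult, rng)
    n_m = int(np.floor(BM_target * phiM_cells / mean_cell_length))
    n_h = int(np.floor(BM_target * (1.0 - phiM_cells) / mean_cell_length))
    m_idx = pool.take_count(M, n_m)
    h_idx = pool.take_count(H, n_h)
    return adult.subset(np.concatenate([h_idx, m_idx]), chem=_newborn_chem(R0),
                        lineage_id=adult.lineage_id)


def partition_fix_single_determinant(adult: Community, which: str,
                                     BM_target: float, rng: np.random.Generator,
                                     R0: float = 1.0) -> list[Community]:
    """Fix exactly one Newborn composition determinant.

    ``which="BM_only"``: mixed cells fill each Newborn to BM_target (closest
    without exceeding) while the species fraction fluctuates; Newborns are
    produced until the Adult is exhausted.

    ``which="phiM_only"``: Manufacturer cells are pipetted into ``n_D``
    aliquots, then Helpers are dispensed greedily so each Newborn's Helper
    biomass approaches ``M(0) * (1 - phi_M(T)) / phi_M(T)``; total biomass
    fluctuates.
    """
    if which == "BM_only":
        order = list(rng.permutation(adult.n_cells))
        out = []
        while True:
            total = 0.0
            taken: list[int] = []
            kept: list[int] = []
            for pos, i in enumerate(order):
                if BM_target - total < 1.0:
                    kept.extend(order[pos:])
                    break
                li = adult.L[i]
                if total + li <= BM_target:
                    taken.append(i)
                    total += li
                else:
                    kept.append(i)
            if total <= BM_target - 2.0:
                break  # pool exhausted: cannot reach the (target-2, target] window
            out.append(adult.subset(np.array(taken, dtype=np.int64),
                                    chem=_newborn_chem(R0),
                                    lineage_id=adult.lineage_id))
            order = kept
        return out
    if which == "phiM_only":
        n_D = dilution_fold(adult.biomass, BM_target)
        phiM_T = adult.phi_M
        m_cells = np.flatnonzero(adult.species == M)
        labels = rng.integers(1, n_D + 1, size=len(m_cells))
        h_order = list(rng.permutation(np.flatnonzero(adult.species == H)))
        out = []
        for k in range(1, n_D + 1):
            m_idx = m_cells[labels == k]
            M0 = float(adult.L[m_idx].sum())
            target_h = M0 * (1.0 - phiM_T) / phiM_T if phiM_T > 0 else 0.0
            total = 0.0
            taken: list[int] = []
            kept: list[int] = []
            for pos, i in enumerate(h_order):
                if target_h - total < 1.0:
                    kept.extend(h_order[pos:])
                    break
                li = adult.L[i]
                if total + li <= target_h:
                    taken.append(i)
                    total += li
                else:
                    kept.append(i)
            h_order = kept
            out.append(adult.subset(
                np.concatenate([np.array(taken, dtype=np.int64), m_idx]),
                chem=_newborn_chem(R0), lineage_id=adult.lineage_id))
        return out
    raise ValueError("which must be 'BM_only' or 'phiM_only'")


def found_monoculture(f_P: float, growth: GrowthParams,
                      R0: float = 1.0) -> Community:
    """A Newborn Manufacturer group: one M cell of biomass 1, fresh Resource.

    Byproduct is treated as saturating during maturation of monoculture
    groups (run with ``excess_B=True``), so B is left at 0 here rather than
    at an arbitrary large constant.
    """
    return Community.from_counts(0, 1, growth, f_P, chem=_newborn_chem(R0))
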