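"""Cycle orchestration: score Adults, choose who reproduces, run many cycles.

Every source of randomness derives from the run's master seed through a
counter-based seed tree (`numpy.random.SeedSequence` keyed on cycle and
community index), so results are independent of execution order and any
community's maturation can be replayed in isolation from its logged seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .agents import Community, M, mature
from .config import SelectionConfig
from .dynamics_core import ChemState, deterministic_trajectory
from .reproduction import (AdultTooSmall, SortingPool, dilution_fold,
                           found_monoculture, partition_fix_single_determinant,
                           partition_fixed_fold, partition_pipetting,
                           partition_sort_biomass, partition_sort_cellnumber)

__all__ = [
    "CycleRecord",
    "RunResult",
    "ExtinctionError",
    "community_function",
    "ancestral_function",
    "add_measurement_noise",
    "choose_and_allocate",
    "run_selection",
    "run_group_selection",
    "pregrow_founder",
    "PregrowthPool",
]


class ExtinctionError(RuntimeError):
    """Fewer Newborns available than n_tot; the run cannot continue."""


@dataclass
class CycleRecord:
    """Summary of one selection cycle: the chosen Adults and aggregates."""

    cycle: int
    chosen: list  # one dict per chosen Adult
    Pbar_T: float
    fPbar_T: float

    @staticmethod
    def adult_row(cycle: int, adult_id: int, adult: Community, score: float) -> dict:
        g = adult.mean_growth_params()
        return {
            "cycle": cycle,
            "adult_id": adult_id,
            "P_T": adult.chem.P,
            "score": score,
            "phiM_T": adult.phi_M,
            "BM_T": adult.biomass,
            "mean_fP": adult.mean_f_P(),
            "mean_gHmax": g["g_Hmax"],
            "mean_affHR": g["aff_HR"],
            "mean_gMmax": g["g_Mmax"],
            "mean_affMR": g["aff_MR"],
            "mean_affMB": g["aff_MB"],
            "seed": adult.seed,
        }

    @classmethod
    def from_chosen(cls, cycle: int, rows: list) -> "CycleRecord":
        pbar = float(np.mean([r["P_T"] for r in rows])) if rows else float("nan")
        # average f_P within each Adult first (done in the row), then across
        fps = [r["mean_fP"] for r in rows if not math.isnan(r["mean_fP"])]
        fbar = float(np.mean(fps)) if fps else float("nan")
        return cls(cycle=cycle, chosen=rows, Pbar_T=pbar, fPbar_T=fbar)


@dataclass
class RunResult:
    """Records of a selection run plus the header data needed to replay it."""

    config: SelectionConfig
    records: list
    ancestral_P: float
    extinct_at: int | None = None
    seed_log: list = field(default_factory=list)  # per cycle: list of seeds


def community_function(adult: Community, function_def: str = "total_product") -> float:
    """Score one Adult: total Product, or Product per Manufacturer biomass.

    ``product_per_M`` is undefined (NaN) for an Adult whose Manufacturers
    went extinct; undefined scores rank below every defined score.
    """
    if function_def == "total_product":
        return adult.chem.P
    if function_def == "product_per_M":
        mbio = adult.M_biomass
        return adult.chem.P / mbio if mbio > 0 else float("nan")
    raise ValueError(f"unknown function_def {function_def!r}")


def ancestral_function(config: SelectionConfig) -> float:
    """Deterministic P(T) of the cycle-1 configuration (noise scale)."""
    chem = ChemState(R=config.R0)
    traj = deterministic_trajectory(
        (float(config.init_H), float(config.init_M), chem),
        config.growth, config.fixed, config.init_f_P, config.T,
        excess_B=config.excess_byproduct or config.monoculture,
    )
    return float(traj.P[-1])


def add_measurement_noise(score: float, noise_sd_frac: float,
                          P_ancestral: float, rng: np.random.Generator) -> float:
    """Gaussian measurement noise scaled to the ancestral community function."""
    if noise_sd_frac == 0:
        return score
    return score + rng.normal(0.0, noise_sd_frac * P_ancestral)


def _ranked(scores, strategy: str, rng: np.random.Generator):
    """Adult indices in reproduction order.

    Scores sort descending with NaN last; ties break toward the lower
    community index (stable).  The random control ignores scores entirely.
    """
    n = len(scores)
    if strategy == "random_control":
        return list(rng.permutation(n))
    keys = [(-s if not math.isnan(s) else math.inf, i) for i, s in enumerate(scores)]
    return [i for _, i in sorted(keys)]


def choose_and_allocate(scores, capacities, config: SelectionConfig,
                        rng: np.random.Generator):
    """Plan (adult_index, newborn_quota) pairs totaling exactly n_tot.

    top_dog: the best Adult contributes all the Newborns it can, then the
    runner-up, until n_tot.  top_tier: the best n_chosen Adults contribute
    n_tot/n_chosen each (shortfalls cascade down the ranking).
    random_control: as top_dog but in random order.
    """
    order = _ranked(scores, config.strategy, rng)
    n_left = config.n_tot
    plan = []
    if config.strategy == "top_tier":
        quota = config.n_tot // config.n_chosen
        for i in order[: config.n_chosen]:
            take = min(quota, capacities[i])
            if take > 0:
                plan.append((i, take))
                n_left -= take
        extra = iter(order)
        while n_left > 0:
            try:
                i = next(extra)
            except StopIteration:
                raise ExtinctionError("not enough Newborns to fill the cycle")
            assigned = sum(q for j, q in plan if j == i)
            take = min(n_left, capacities[i] - assigned)
            if take > 0:
                plan.append((i, take))
                n_left -= take
        return plan
    for i in order:
        take = min(n_left, capacities[i])
        if take > 0:
            plan.append((i, take))
            n_left -= take
        if n_left == 0:
            return plan
    raise ExtinctionError("not enough Newborns to fill the cycle")


def _capacity(adult: Community, config: SelectionConfig) -> int:
    rep = config.reproduction
    if config.monoculture:
        return adult.n_cells
    if rep.method == "fixed_fold":
        return int(rep.fixed_fold_nD)
    try:
        return dilution_fold(adult.biomass, rep.BM_target)
    except AdultTooSmall:
        return 0


def _make_newborns(adult: Community, k: int, config: SelectionConfig,
                   rng: np.random.Generator) -> list[Community]:
    """Produce up to k Newborns from one chosen Adult."""
    rep = config.reproduction
    R0 = config.R0
    if config.monoculture:
        idx = rng.choice(adult.n_cells, size=min(k, adult.n_cells), replace=False)
        out = []
        for i in idx:
            nb = adult.subset([i], chem=ChemState(R=R0),
                              lineage_id=adult.lineage_id)
            nb.L[:] = 1.0  # groups are founded with a fresh cell of biomass 1
            out.append(nb)
        return out
    if rep.method in ("pipetting", "fixed_fold"):
        if rep.method == "pipetting":
            batch = partition_pipetting(adult, rep.BM_target, rng, R0=R0)
        else:
            batch = partition_fixed_fold(adult, int(rep.fixed_fold_nD), rng, R0=R0)
        if k >= len(batch):
            return batch
        keep = rng.choice(len(batch), size=k, replace=False)
        return [batch[i] for i in keep]
    if rep.method in ("sort_biomass", "sort_cellnumber"):
        pool = SortingPool(adult, rng)
        phiM_bio = adult.phi_M
        phiM_cells = adult.phi_M_cells
        out = []
        for _ in range(k):
            try:
                if rep.method == "sort_biomass":
                    nb = partition_sort_biomass(adult, rep.BM_target, phiM_bio,
                                                rng, R0=R0, pool=pool)
                else:
                    nb = partition_sort_cellnumber(
                        adult, rep.BM_target, phiM_cells, rng, R0=R0,
                        mean_cell_length=rep.mean_cell_length, pool=pool)
            except AdultTooSmall:
                break
            if nb.n_cells == 0:
                break
            out.append(nb)
        return out
    if rep.method in ("fix_BM_only", "fix_phiM_only"):
        which = "BM_only" if rep.method == "fix_BM_only" else "phiM_only"
        batch = partition_fix_single_determinant(adult, which, rep.BM_target,
                                                 rng, R0=R0)
        if k >= len(batch):
            return batch
        keep = rng.choice(len(batch), size=k, replace=False)
        return [batch[i] for i in keep]
    raise ValueError(f"unknown reproduction method {rep.method!r}")


def _seed_for(master_seed: int, *key: int) -> int:
    """Counter-based per-entity seed below 2^31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _initial_newborns(config: SelectionConfig, rng: np.random.Generator):
    if config.monoculture:
        return [found_monoculture(config.init_f_P, config.growth, R0=config.R0)
                for _ in range(config.n_tot)]
    base = Community.from_counts(config.init_H, config.init_M, config.growth,
                                 config.init_f_P, chem=ChemState(R=config.R0))
    newborns = [base.copy() for _ in range(config.n_tot)]
    if config.pregrowth:
        pool = None
        for nb in newborns:
            if pool is None or not config.pregrowth_shared_pool:
                pool = pregrow_founder(rng, f_P=config.init_f_P)
            nulls = pool.draw_null_count(config.init_M, rng)
            m_idx = np.flatnonzero(nb.species == M)
            nb.f_P[m_idx[:nulls]] = 0.0
    return newborns


def run_selection(config: SelectionConfig,
                  initial_newborns: list[Community] | None = None) -> RunResult:
    """Run the full selection experiment; fully reproducible from master_seed.

    ``initial_newborns`` overrides the standard identical founding
    communities (used for scenarios seeded with standing variation).
    """
    anc = ancestral_function(config)
    records: list[CycleRecord] = []
    seed_log: list[list[int]] = []
    setup_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.master_seed, spawn_key=(0xA11CE,)))
    if initial_newborns is not None:
        if len(initial_newborns) != config.n_tot:
            raise ValueError("initial_newborns must have length n_tot")
        newborns = [nb.copy() for nb in initial_newborns]
    else:
        newborns = _initial_newborns(config, setup_rng)
    extinct_at = None
    for cycle in range(config.n_cycles):
        seeds = [_seed_for(config.master_seed, cycle, j)
                 for j in range(len(newborns))]
        seed_log.append(seeds)
        adults = []
        for nb, seed in zip(newborns, seeds):
            adults.append(mature(
                nb, T=config.T, dtau=config.dtau, fixed=config.fixed,
                mut=config.mutation, bounds=config.bounds, seed=seed,
                excess_B=config.excess_byproduct or config.monoculture,
                rtol=config.rtol, atol=config.atol))
        noise_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.master_seed,
                                   spawn_key=(cycle, 1 << 20)))
        scores = [
            add_measurement_noise(
                community_function(a, config.function_def),
                config.noise_sd_frac, anc, noise_rng)
            for a in adults
        ]
        caps = [_capacity(a, config) for a in adults]
        repro_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.master_seed,
                                   spawn_key=(cycle, (1 << 20) + 1)))
        try:
            plan = choose_and_allocate(scores, caps, config, repro_rng)
        except ExtinctionError:
            extinct_at = cycle
            break
        rows = [CycleRecord.adult_row(cycle, i, adults[i], scores[i])
                for i, _ in _dedup(plan)]
        records.append(CycleRecord.from_chosen(cycle, rows))
        next_newborns = []
        shortfall = 0
        for i, quota in plan:
            got = _make_newborns(adults[i], quota, config, repro_rng)
            for nb in got:
                nb.lineage_id = i
            shortfall += quota - len(got)
            next_newborns.extend(got)
        if shortfall:
            # sorting methods can under-deliver; cascade down the ranking
            order = _ranked(scores, config.strategy, repro_rng)
            for i in order:
                if shortfall <= 0:
                    break
                if any(j == i for j, _ in plan):
                    continue
                got = _make_newborns(adults[i], shortfall, config, repro_rng)
                for nb in got:
                    nb.lineage_id = i
                shortfall -= len(got)
                next_newborns.extend(got)
            if shortfall > 0:
                extinct_at = cycle
                break
        newborns = next_newborns
    return RunResult(config=config, records=records, ancestral_P=anc,
                     extinct_at=extinct_at, seed_log=seed_log)


def _dedup(plan):
    seen = {}
    for i, q in plan:
        seen[i] = seen.get(i, 0) + q
    return list(seen.items())


def run_group_selection(config: SelectionConfig) -> RunResult:
    """Artificial group selection on Manufacturer monocultures.

    Newborn groups start from a single cell drawn from the chosen Adult
    group and mature under saturating Byproduct; otherwise the cycle
    structure matches :func:`run_selection`.
    """
    cfg = config.replace(monoculture=True, excess_byproduct=True,
                         init_H=0, init_M=1)
    return run_selection(cfg)


# --------------------------------------------------------------------------
# pregrowth of the founder monoculture
# --------------------------------------------------------------------------


@dataclass
class PregrowthPool:
    """Population-count representation of one pregrown M monoculture."""

    n_contributor: int
    n_null: int
    f_P: float

    @property
    def null_fraction(self) -> float:
        return self.n_null / (self.n_null + self.n_contributor)

    def draw_null_count(self, k: int, rng: np.random.Generator) -> int:
        """Number of null cells among k drawn without replacement."""
        return int(rng.hypergeometric(self.n_null, self.n_contributor, k))


def pregrow_founder(rng: np.random.Generator, *, f_P: float = 0.13,
                    p_null: float = 1e-3, rel_growth: float = 0.87,
                    target_cells: int = 2 ** 23) -> PregrowthPool:
    """Grow one monoculture from a single contributor cell to ~1e7 cells.

    A two-type branching process in population counts: contributors (cost
    ``f_P``) divide synchronously every ``ln2/rel_growth`` time units; at
    each division the mother and the daughter independently convert to null
    (zero cost) with probability ``p_null``.  Null clones, free of the
    cost, double every ``ln2`` and are propagated deterministically
    (population counts are large whenever they matter).  Growth stops once
    the culture reaches ``target_cells``, about 23 contributor doublings.
    """
    n_c = 1
    clone_birth: list[int] = []
    clone_count: list[int] = []
    k = 0
    while True:
        n_0 = sum(c * 2 ** int((k - kb) / rel_growth)
                  for kb, c in zip(clone_birth, clone_count))
        if n_c + n_0 >= target_cells:
            return PregrowthPool(n_contributor=n_c, n_null=n_0, f_P=f_P)
        k += 1
        n_c *= 2
        conv = int(rng.binomial(n_c, p_null)) if p_null > 0 else 0
        n_c -= conv
        if conv:
            clone_birth.append(k)
            clone_count.append(conv)
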