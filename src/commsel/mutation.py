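"""Phenotype-altering mutations.

Each mutable phenotype of a freshly divided cell (mother and daughter alike)
mutates independently with probability ``P_mut``.  A mutation is null
(phenotype set to 0) with probability ``p_null``; otherwise the phenotype is
multiplied by ``1 + delta`` with ``delta`` drawn from a bilateral
exponential distribution truncated at -1: enhancing effects have mean
``s_plus``, diminishing effects mean magnitude ``s_minus``.  Results are
clamped to the phenotype's evolutionary bounds.  Diminishing-returns
epistasis optionally rescales the two means as a function of the cell's
current cost fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .params import PHENOTYPE_NAMES, PhenotypeBounds

__all__ = [
    "MutationModel",
    "epistatic_means",
    "sample_relative_effect",
    "effect_cdf",
    "negative_branch_mass",
    "mutate_phenotype",
    "mutate_divided_pair",
]


@dataclass(frozen=True)
class MutationModel:
    """Rates and effect-size distribution of phenotype-altering mutations."""

    P_mut: float = 2e-3
    p_null: float = 0.5
    s_plus: float = 0.050
    s_minus: float = 0.067
    epistasis_g: float | None = None
    fP_init: float = 0.13
    mutable_set: frozenset = field(default_factory=lambda: frozenset({"f_P"}))

    def __post_init__(self):
        if not 0 <= self.P_mut <= 1:
            raise ValueError("P_mut must lie in [0, 1]")
        if not 0 <= self.p_null <= 1:
            raise ValueError("p_null must lie in [0, 1]")
        if self.s_plus <= 0 or self.s_minus <= 0:
            raise ValueError("s_plus and s_minus must be > 0")
        if self.epistasis_g is not None and not 0 <= self.epistasis_g < 1:
            raise ValueError("epistasis_g must lie in [0, 1)")
        unknown = set(self.mutable_set) - set(PHENOTYPE_NAMES)
        if unknown:
            raise ValueError(f"unknown phenotypes in mutable_set: {sorted(unknown)}")

    def mutable_flags(self) -> np.ndarray:
        return np.array(
            [1 if n in self.mutable_set else 0 for n in PHENOTYPE_NAMES],
            dtype=np.int64,
        )

    def replace(self, **kw) -> "MutationModel":
        return replace(self, **kw)


def epistatic_means(f_P: float, model: MutationModel):
    """Effect-size means at the current cost under diminishing returns.

    ``s_plus`` shrinks and ``s_minus`` grows by the factor
    ``1 + g*(f_P/fP_init - 1)``; at ``f_P == fP_init`` the base means are
    returned unchanged.
    """
    g = model.epistasis_g
    if g is None or g == 0:
        return model.s_plus, model.s_minus
    fac = 1.0 + g * (f_P / model.fP_init - 1.0)
    if fac <= 0:
        raise ValueError(f"epistasis factor non-positive at f_P={f_P}")
    return model.s_plus / fac, model.s_minus * fac


def sample_relative_effect(u2, s_plus: float, s_minus: float):
    """Map uniform draws to relative mutation effects by inverse CDF.

    Scalar or array ``u2``; endpoints map to the limits -1 and +inf.
    """
    u2 = np.asarray(u2, dtype=float)
    if np.any(u2 < 0) or np.any(u2 > 1):
        raise ValueError("u2 must lie in (0, 1)")
    em = np.exp(-1.0 / s_minus)
    A = s_plus + s_minus * (1.0 - em)
    c0 = s_minus * (1.0 - em) / A
    with np.errstate(divide="ignore"):
        neg = s_minus * np.log(u2 * A / s_minus + em)
        pos = -s_plus * np.log((1.0 - u2) * A / s_plus)
    out = np.where(u2 <= c0, neg, pos)
    return float(out) if out.ndim == 0 else out


def effect_cdf(delta, s_plus: float, s_minus: float):
    """Closed-form CDF of the relative-effect distribution (for testing)."""
    delta = np.asarray(delta, dtype=float)
    em = np.exp(-1.0 / s_minus)
    A = s_plus + s_minus * (1.0 - em)
    neg = s_minus / A * (np.exp(np.clip(delta, -1.0, 0.0) / s_minus) - em)
    pos = 1.0 - s_plus / A * np.exp(-np.clip(delta, 0.0, None) / s_plus)
    out = np.where(delta <= 0, neg, pos)
    out = np.where(delta <= -1, 0.0, out)
    return float(out) if out.ndim == 0 else out


def negative_branch_mass(s_plus: float, s_minus: float) -> float:
    """Probability that a non-null mutation diminishes the phenotype, C(0)."""
    em = np.exp(-1.0 / s_minus)
    return s_minus * (1.0 - em) / (s_plus + s_minus * (1.0 - em))


def mutate_phenotype(
    value: float,
    bound_lo: float,
    bound_hi: float,
    model: MutationModel,
    rng: np.random.Generator,
    *,
    f_P_context: float | None = None,
) -> float:
    """Apply one phenotype-altering mutation to a parameter value.

    With probability ``p_null`` the value becomes 0; otherwise it is scaled
    by ``1 + delta`` and clamped to the bounds.  When ``f_P_context`` is
    given (the parameter being mutated is the cost fraction and epistasis is
    enabled) the effect-size means are rescaled first.
    """
    if not bound_lo <= value <= bound_hi:
        raise ValueError(f"value {value} outside [{bound_lo}, {bound_hi}]")
    if rng.random() < model.p_null:
        return 0.0
    if f_P_context is not None and model.epistasis_g:
        s_plus, s_minus = epistatic_means(f_P_context, model)
    else:
        s_plus, s_minus = model.s_plus, model.s_minus
    delta = _kernels.sample_delta(rng.random(), s_plus, s_minus)
    return float(np.clip(value * (1.0 + delta), bound_lo, bound_hi))


# per-species phenotype columns of a community's cell table
_H_PHENOS = (("g_Hmax", "g_max"), ("aff_HR", "aff_R"))
_M_PHENOS = (
    ("g_Mmax", "g_max"),
    ("aff_MR", "aff_R"),
    ("aff_MB", "aff_B"),
    ("f_P", "f_P"),
)


def mutate_cells(
    comm,
    indices,
    model: MutationModel,
    bounds: PhenotypeBounds,
    rng: np.random.Generator,
) -> None:
    """Mutate each mutable phenotype of the given cells, in place.

    Cells are visited in the given order; per cell, phenotypes are visited
    in canonical order, each with an independent Bernoulli(P_mut) trial.
    """
    for i in indices:
        is_h = comm.species[i] == 0
        for pheno, col in (_H_PHENOS if is_h else _M_PHENOS):
            if pheno not in model.mutable_set:
                continue
            if rng.random() >= model.P_mut:
                continue
            arr = getattr(comm, col)
            ctx = comm.f_P[i] if (pheno == "f_P" and model.epistasis_g) else None
            arr[i] = mutate_phenotype(
                arr[i], 0.0, bounds.upper(pheno), model, rng, f_P_context=ctx
            )


def mutate_divided_pair(mother, daughter, model: MutationModel,
                        bounds: PhenotypeBounds, rng: np.random.Generator):
    """Independently mutate every mutable phenotype of a divided pair.

    ``mother`` and ``daughter`` are `commsel.agents.Cell` records; mutated
    copies are returned (inputs are not modified).
    """
    from .agents import Community

    comm = Community.from_cells([mother, daughter])
    mutate_cells(comm, [0, 1], model, bounds, rng)
    cells = list(comm.cells())
    return cells[0], cells[1]
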