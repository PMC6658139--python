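"""Species parameters for the Helper–Manufacturer community.

All quantities are expressed in the scaled units of the model: Resource in
units of the amount supplied to one Newborn community, Byproduct in units of
the amount released per Helper biomass grown, Product in units of the amount
made at the cost of one Manufacturer biomass.  Affinities are stored as 1/K
(per unit substrate) so that a null mutation — complete loss of transport —
is representable as exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

__all__ = [
    "GrowthParams",
    "FixedParams",
    "PhenotypeBounds",
    "ANCESTRAL_GROWTH",
    "PREADAPTED_GROWTH",
    "DEFAULT_FIXED",
    "DEFAULT_BOUNDS",
    "FAST_HELPER_BOUNDS",
    "ANCESTRAL_FP",
    "PREADAPTED_FP",
    "PHENOTYPE_NAMES",
]

#: canonical ordering of the six mutable phenotypes
PHENOTYPE_NAMES = ("g_Hmax", "aff_HR", "g_Mmax", "aff_MR", "aff_MB", "f_P")


@dataclass(frozen=True)
class GrowthParams:
    """Heritable growth phenotypes shared by the deterministic and agent layers.

    Parameters
    ----------
    g_Hmax, g_Mmax
        Maximal biomass growth rates of Helper and Manufacturer (1/time).
    aff_HR
        Helper's affinity for Resource, ``1/K_HR`` (per unit Resource).
    aff_MR, aff_MB
        Manufacturer's affinities for Resource and Byproduct, ``1/K_MR``
        and ``1/K_MB``.
    """

    g_Hmax: float = 0.3
    g_Mmax: float = 0.7
    aff_HR: float = 5.0
    aff_MR: float = 3.0
    aff_MB: float = 0.03

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if val < 0:
                raise ValueError(f"{name} must be >= 0, got {val}")

    def replace(self, **kw) -> "GrowthParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class FixedParams:
    """Consumption, death and interaction parameters held constant through evolution.

    ``B0`` is the Byproduct scale at which Helper growth is reduced e-fold in
    the mutualistic variant of the community; ``None`` selects the commensal
    model (Byproduct does not inhibit Helper).
    """

    c_RM: float = 1e-4
    c_RH: float = 1e-4
    c_BM: float = 1.0 / 3.0
    delta_M: float = 3.5e-3
    delta_H: float = 1.5e-3
    B0: float | None = None

    def __post_init__(self) -> None:
        for name in ("c_RM", "c_RH", "c_BM", "delta_M", "delta_H"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.B0 is not None and self.B0 <= 0:
            raise ValueError("B0 must be > 0 (or None for the commensal model)")

    @property
    def b0_inv(self) -> float:
        """1/B0, or 0.0 for the commensal model (inhibition factor 1)."""
        return 0.0 if self.B0 is None else 1.0 / self.B0

    def replace(self, **kw) -> "FixedParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PhenotypeBounds:
    """Evolutionary upper bounds for the six mutable phenotypes.

    Lower bounds are 0 for every phenotype (a null mutation sets a phenotype
    to 0); the cost fraction ``f_P`` is additionally bounded above by 1.
    """

    g_Hmax: float = 0.3
    g_Mmax: float = 0.7
    aff_HR: float = 5.0
    aff_MR: float = 3.0
    aff_MB: float = 0.03
    f_P: float = 1.0

    def upper(self, name: str) -> float:
        return getattr(self, name)

    def as_array(self):
        import numpy as np

        return np.array([getattr(self, n) for n in PHENOTYPE_NAMES], dtype=float)

    def replace(self, **kw) -> "PhenotypeBounds":
        return replace(self, **kw)


# Ancestral phenotypes: moderate growth, unevolved affinities.
ANCESTRAL_GROWTH = GrowthParams(
    g_Hmax=0.25, g_Mmax=0.58, aff_HR=1.0, aff_MR=1.0, aff_MB=1.0 / (5.0 / 3.0 * 100.0)
)
#: growth parameters at their evolutionary upper bounds ("preadapted")
PREADAPTED_GROWTH = GrowthParams(
    g_Hmax=0.3, g_Mmax=0.7, aff_HR=5.0, aff_MR=3.0, aff_MB=0.03
)

DEFAULT_FIXED = FixedParams()
DEFAULT_BOUNDS = PhenotypeBounds()
#: bounds for the coexistence-under-selection scenario where Helper may evolve
#: to outgrow Manufacturer (g_Hmax up to 0.8 > g_Mmax bound 0.7)
FAST_HELPER_BOUNDS = PhenotypeBounds(g_Hmax=0.8)

ANCESTRAL_FP = 0.10
#: cost optimal for a Manufacturer monoculture; starting point of most runs
PREADAPTED_FP = 0.13
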