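"""Run configuration for community-selection simulations."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .mutation import MutationModel
from .params import (DEFAULT_BOUNDS, DEFAULT_FIXED, PREADAPTED_FP,
                     PREADAPTED_GROWTH, FixedParams, GrowthParams,
                     PhenotypeBounds)
from .reproduction import ReproductionSpec

__all__ = ["SelectionConfig", "ConfigError"]

STRATEGIES = ("top_dog", "top_tier", "random_control")
FUNCTION_DEFS = ("total_product", "product_per_M")


class ConfigError(ValueError):
    """Invalid run configuration; message lists every violated invariant."""


@dataclass(frozen=True)
class SelectionConfig:
    """Everything needed to reproduce one selection run.

    Defaults are the baseline regimen: 100 communities, top-dog choice,
    pipetting reproduction, maturation T = 17 in steps of 0.05, Resource
    supporting 1e4 biomass, Newborns of 40 Helpers + 60 Manufacturers at
    the monoculture-optimal cost 0.13, and only the cost fraction mutable.
    """

    n_tot: int = 100
    n_chosen: int = 10  # used by the top_tier strategy
    strategy: str = "top_dog"
    function_def: str = "total_product"
    noise_sd_frac: float = 0.0
    T: float = 17.0
    dtau: float = 0.05
    R0: float = 1.0
    BM_target: float = 100.0
    init_H: int = 40
    init_M: int = 60
    init_f_P: float = PREADAPTED_FP
    n_cycles: int = 100
    master_seed: int = 0
    growth: GrowthParams = PREADAPTED_GROWTH
    fixed: FixedParams = DEFAULT_FIXED
    bounds: PhenotypeBounds = DEFAULT_BOUNDS
    mutation: MutationModel = field(default_factory=MutationModel)
    reproduction: ReproductionSpec = field(default_factory=ReproductionSpec)
    # scenario flags
    monoculture: bool = False  # Manufacturer-only group selection
    excess_byproduct: bool = False  # Byproduct saturating during maturation
    pregrowth: bool = False  # found cycle-1 Newborns from pregrown monoculture
    pregrowth_shared_pool: bool = True
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self):
        errors = []
        if self.strategy not in STRATEGIES:
            errors.append(f"strategy must be one of {STRATEGIES}")
        if self.function_def not in FUNCTION_DEFS:
            errors.append(f"function_def must be one of {FUNCTION_DEFS}")
        if self.n_tot < 1:
            errors.append("n_tot must be >= 1")
        if self.strategy == "top_tier":
            if self.n_chosen < 1:
                errors.append("n_chosen must be >= 1")
            elif self.n_tot % self.n_chosen != 0:
                errors.append(
                    f"n_tot ({self.n_tot}) must be divisible by n_chosen "
                    f"({self.n_chosen}) for the top_tier strategy"
                )
        if self.noise_sd_frac < 0:
            errors.append("noise_sd_frac must be >= 0")
        if self.T < 0 or self.dtau <= 0:
            errors.append("T must be >= 0 and dtau > 0")
        if self.R0 <= 0:
            errors.append("R0 must be > 0")
        if not 0 <= self.init_f_P <= 1:
            errors.append("init_f_P must lie in [0, 1]")
        if self.n_cycles < 0:
            errors.append("n_cycles must be >= 0")
        if self.monoculture and self.init_H:
            errors.append("monoculture scenario admits no Helper cells")
        if errors:
            raise ConfigError("; ".join(errors))

    def replace(self, **kw) -> "SelectionConfig":
        return replace(self, **kw)
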