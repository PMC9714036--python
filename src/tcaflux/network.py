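"""Reduced TCA-cycle flux network and tracer definitions.

The network carries one mitochondrial pool set: pyruvate (3C), acetyl-CoA
(2C), oxaloacetate (4C), citrate (6C), alpha-ketoglutarate (5C), glutamate
(5C), succinate (4C) and malate (4C; fumarate is lumped into the
succinate→malate step and handled by symmetry averaging). Fluxes, in
concentration/min:

``v_cs``
    Citrate synthase: condensation of acetyl-CoA and oxaloacetate.
``v_ana``
    Anaplerotic entry of unlabeled carbon at alpha-ketoglutarate, balanced
    by a cataplerotic oxaloacetate efflux of the same magnitude.
``v_dil_acecoa``, ``v_dil_oaa``
    Unlabeled exchange (equal in/out) at acetyl-CoA and oxaloacetate.
``v_exchange_glu``
    Bidirectional glutamate ↔ alpha-ketoglutarate exchange; this is the
    route by which glutamine tracer label enters the cycle and by which
    cycle label reaches the measured glutamate pool.
``v_gln_in``
    External glutamate turnover (labeled under the glutamine tracer,
    unlabeled otherwise), with a matched efflux.
``fao_fraction``
    Fraction of the citrate-synthase acetyl-CoA supply provided by fatty
    acid beta-oxidation (labeled under the palmitate tracer); the rest
    comes from pyruvate dehydrogenase, which is fed by glycolysis.
``v_glycolysis``
    Pyruvate supply; defaults to the pyruvate-dehydrogenase demand. Any
    surplus leaves as a balancing efflux (lactate export); a deficit is a
    balance error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import BalanceError, ConfigurationError, DomainError

POOL_CARBONS: dict[str, int] = {
    "pyruvate": 3,
    "acetyl_coa": 2,
    "oxaloacetate": 4,
    "citrate": 6,
    "alpha_ketoglutarate": 5,
    "glutamate": 5,
    "succinate": 4,
    "malate": 4,
}

TRACER_NAMES = ("glucose_U13C6", "glutamine_U13C5", "palmitate_U13C16")

#: Pool the labeled unit of each tracer feeds (acetyl-CoA for glucose via
#: pyruvate dehydrogenase and for palmitate via beta-oxidation; the
#: glutamine label reaches alpha-ketoglutarate through the glutamate pool).
TRACER_ENTRY: dict[str, str] = {
    "glucose_U13C6": "acetyl_coa",
    "palmitate_U13C16": "acetyl_coa",
    "glutamine_U13C5": "alpha_ketoglutarate",
}


@dataclass(frozen=True)
class PlasmaModel:
    """Infusion input function: primed mono-exponential approach to plateau.

    A primed-continuous infusion delivers an initial bolus of
    ``prime_multiplier`` times the per-minute infusion rate, then infuses
    at a constant rate. In a one-compartment plasma model with turnover
    ``rate_constant`` (per minute) the prime contributes an instantaneous
    enrichment step of ``prime_multiplier * rate_constant`` of the plateau,
    capped at the plateau itself.
    """

    prime_multiplier: float = 3.0
    rate_constant: float = 0.09
    plateau_enrichment: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.plateau_enrichment <= 1.0:
            raise ConfigurationError(
                f"plateau_enrichment must be in [0,1], got {self.plateau_enrichment}"
            )
        if self.prime_multiplier < 0:
            raise ConfigurationError("prime_multiplier must be >= 0")
        if self.rate_constant <= 0:
            raise ConfigurationError("rate_constant must be > 0")

    @property
    def prime_step(self) -> float:
        """Fraction of the plateau reached instantaneously by the prime."""
        return min(1.0, self.prime_multiplier * self.rate_constant)


@dataclass(frozen=True)
class TracerSpec:
    """One of the three uniformly labeled 13C tracers and its input kinetics."""

    name: str
    plasma_model: PlasmaModel = field(default_factory=PlasmaModel)

    def __post_init__(self) -> None:
        if self.name not in TRACER_NAMES:
            raise ConfigurationError(
                f"unknown tracer {self.name!r}; expected one of {TRACER_NAMES}"
            )

    @property
    def entry_node(self) -> str:
        return TRACER_ENTRY[self.name]

    @property
    def labeled_pattern(self) -> tuple[bool, ...]:
        """Fully labeled carbon mask of the entry unit (2C acetyl or 5C AKG)."""
        n = 2 if self.entry_node == "acetyl_coa" else 5
        return (True,) * n

    @classmethod
    def constant(cls, name: str, enrichment: float = 0.99) -> "TracerSpec":
        """Tracer held at constant enrichment from t=0 (in vitro tracer media)."""
        k = 1.0
        return cls(name, PlasmaModel(prime_multiplier=1.0 / k, rate_constant=k,
                                     plateau_enrichment=enrichment))


def plasma_enrichment(t, tracer: TracerSpec):
    """Plasma (or medium) tracer enrichment at time ``t`` minutes.

    ``plateau * (1 - (1 - prime_step) * exp(-k t))``: monotone
    nondecreasing, equal to the plateau in the limit of large ``t``.
    Accepts scalars or arrays.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise DomainError("time must be nonnegative")
    pm = tracer.plasma_model
    e = pm.plateau_enrichment * (
        1.0 - (1.0 - pm.prime_step) * np.exp(-pm.rate_constant * arr)
    )
    return float(e) if np.isscalar(t) or arr.ndim == 0 else e


DEFAULT_POOLS: dict[str, float] = {
    "pyruvate": 2.0,
    "acetyl_coa": 0.5,
    "oxaloacetate": 0.5,
    "citrate": 4.0,
    "alpha_ketoglutarate": 2.0,
    "glutamate": 3.0,
    "succinate": 2.0,
    "malate": 2.0,
}

DEFAULT_FLUXES: dict[str, float] = {
    "v_cs": 1.0,
    "v_ana": 0.25,
    "v_dil_acecoa": 0.1,
    "v_dil_oaa": 0.1,
    "v_exchange_glu": 1.5,
    "v_gln_in": 0.25,
    "fao_fraction": 0.25,
    # v_glycolysis defaults to the pyruvate-dehydrogenase demand
}


@dataclass(frozen=True)
class NetworkModel:
    """Mass-balanced reduced TCA isotopomer network."""

    pool_sizes: Mapping[str, float]
    fluxes: Mapping[str, float]
    balancing_effluxes: Mapping[str, float]

    @property
    def v_cs(self) -> float:
        return self.fluxes["v_cs"]

    @property
    def v_ana(self) -> float:
        return self.fluxes["v_ana"]

    @property
    def v_pdh(self) -> float:
        return (1.0 - self.fluxes["fao_fraction"]) * self.v_cs

    @property
    def v_fao(self) -> float:
        return self.fluxes["fao_fraction"] * self.v_cs

    @property
    def v_glycolysis(self) -> float:
        return self.fluxes["v_glycolysis"]

    def net_pool_flux(self, pool: str) -> float:
        """Net inflow minus outflow at a pool; zero for a balanced model."""
        return _pool_balances(self.pool_sizes, self.fluxes)[pool] - (
            self.balancing_effluxes.get(pool, 0.0)
        )


def _pool_balances(pools: Mapping[str, float], fx: Mapping[str, float]) -> dict[str, float]:
    """Inflow minus configured outflow per pool (before balancing effluxes)."""
    v_cs = fx["v_cs"]
    v_pdh = (1.0 - fx["fao_fraction"]) * v_cs
    v_fao = fx["fao_fraction"] * v_cs
    v_cycle = v_cs + fx["v_ana"]
    return {
        "pyruvate": fx["v_glycolysis"] - v_pdh,
        "acetyl_coa": (v_pdh + v_fao + fx["v_dil_acecoa"]) - (v_cs + fx["v_dil_acecoa"]),
        "citrate": v_cs - v_cs,
        "alpha_ketoglutarate": (v_cs + fx["v_ana"] + fx["v_exchange_glu"])
        - (v_cycle + fx["v_exchange_glu"]),
        "glutamate": (fx["v_exchange_glu"] + fx["v_gln_in"])
        - (fx["v_exchange_glu"] + fx["v_gln_in"]),
        "succinate": v_cycle - v_cycle,
        "malate": v_cycle - v_cycle,
        "oxaloacetate": (v_cycle + fx["v_dil_oaa"]) - (v_cs + fx["v_dil_oaa"]),
    }


def build_network(config: Mapping | None = None) -> NetworkModel:
    """Build a mass-balanced network from a (possibly partial) config.

    ``config`` may carry ``pools`` and ``fluxes`` mappings. When ``pools``
    is given it must name every pool; ``fluxes`` entries override the
    defaults individually. The balancing efflux of each pool is computed so
    every net pool flux is zero; a configuration that would force a
    negative balancing efflux is rejected.
    """
    config = dict(config or {})
    unknown = set(config) - {"pools", "fluxes"}
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")

    if "pools" in config:
        pools = {str(k): float(v) for k, v in dict(config["pools"]).items()}
        for name in POOL_CARBONS:
            if name not in pools:
                raise ConfigurationError(f"missing pool: {name}")
        extra = set(pools) - set(POOL_CARBONS)
        if extra:
            raise ConfigurationError(f"unknown pools: {sorted(extra)}")
    else:
        pools = dict(DEFAULT_POOLS)
    for name, size in pools.items():
        if not (math.isfinite(size) and size > 0):
            raise ConfigurationError(f"pool_size must be > 0 for pool {name!r}")

    fx = dict(DEFAULT_FLUXES)
    overrides = dict(config.get("fluxes", {}))
    extra = set(overrides) - (set(DEFAULT_FLUXES) | {"v_glycolysis"})
    if extra:
        raise ConfigurationError(f"unknown fluxes: {sorted(extra)}")
    fx.update({k: float(v) for k, v in overrides.items()})
    for name, val in fx.items():
        if not (math.isfinite(val) and val >= 0):
            raise ConfigurationError(f"flux {name} must be >= 0, got {val}")
    if not 0.0 <= fx["fao_fraction"] <= 1.0:
        raise ConfigurationError("fao_fraction must be in [0, 1]")
    fx.setdefault("v_glycolysis", (1.0 - fx["fao_fraction"]) * fx["v_cs"])
    fx["v_glycolysis"] = float(fx["v_glycolysis"])
    if fx["v_glycolysis"] < 0:
        raise ConfigurationError("v_glycolysis must be >= 0")

    balances = _pool_balances(pools, fx)
    effluxes: dict[str, float] = {}
    for pool, net in balances.items():
        if net < -1e-9:
            raise BalanceError(
                f"pool {pool!r} cannot be balanced: configured outflow exceeds "
                f"inflow by {-net:.4g}; reduce its consumption or raise its supply"
            )
        if net > 1e-12:
            effluxes[pool] = net
    return NetworkModel(pool_sizes=pools, fluxes=fx, balancing_effluxes=effluxes)
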