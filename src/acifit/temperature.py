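"""Arrhenius temperature scaling of kinetic constants.

Rubisco kinetics and the photocompensation point are defined at a 25 degC
reference and scaled to leaf temperature with a one-parameter Arrhenius
response exp(Ha*(Tk - 298.15)/(298.15*R*Tk)). Default activation energies
follow the Bernacchi conventions common to spreadsheet-lineage A/Ci fitting
tools; everything is overridable through the flat config (see
:mod:`acifit.io`).

Fitted rates (Vcmax, J, TPU, RL) are reported at measurement temperature;
:func:`normalize_rate_to_25` is an optional post-hoc helper, off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .model_core import KineticConstants

__all__ = [
    "R_GAS",
    "DEFAULT_KINETICS_25",
    "DEFAULT_HA",
    "ArrheniusSpec",
    "arrhenius_scale",
    "kinetics_at",
    "normalize_rate_to_25",
]

R_GAS = 8.314  # J mol-1 K-1
_T_REF_K = 298.15

# Bernacchi-style Cc-basis defaults at 25 degC
DEFAULT_KINETICS_25: Mapping[str, float] = {
    "gamma_star_25": 4.275,  # Pa
    "kc_25": 40.49,          # Pa
    "ko_25": 27.84,          # kPa
    "o2": 21.0,              # kPa (chloroplast O2 at ~100 kPa air)
}
DEFAULT_HA: Mapping[str, float] = {
    "ha_gamma_star": 37.83,  # kJ mol-1
    "ha_kc": 79.43,
    "ha_ko": 36.38,
}


@dataclass(frozen=True)
class ArrheniusSpec:
    """A quantity at 25 degC plus its activation energy Ha (kJ mol-1)."""

    value_25: float
    ha: float

    def __post_init__(self) -> None:
        if not self.value_25 > 0:
            raise ValueError("value_25 must be > 0")
        if self.ha < 0:
            raise ValueError("Ha must be >= 0")


def _arrhenius_factor(ha_kj: float, tleaf: float) -> float:
    if not -10.0 < tleaf < 60.0:
        raise ValueError(f"Tleaf {tleaf} degC outside the supported (-10, 60) range")
    tk = tleaf + 273.15
    return math.exp(ha_kj * 1e3 * (tk - _T_REF_K) / (_T_REF_K * R_GAS * tk))


def arrhenius_scale(spec: ArrheniusSpec, tleaf: float) -> float:
    """Scale ``spec.value_25`` from 25 degC to ``tleaf`` (degC)."""
    return spec.value_25 * _arrhenius_factor(spec.ha, tleaf)


def kinetics_at(tleaf: float, config: Mapping[str, float] | None = None) -> KineticConstants:
    """Kinetic constants at leaf temperature.

    ``config`` may override any of gamma_star_25 / kc_25 / ko_25 / o2 and
    ha_gamma_star / ha_kc / ha_ko; O2 passes through unscaled.
    """
    cfg = {**DEFAULT_KINETICS_25, **DEFAULT_HA, **(config or {})}
    return KineticConstants(
        gamma_star=arrhenius_scale(ArrheniusSpec(cfg["gamma_star_25"], cfg["ha_gamma_star"]), tleaf),
        kc=arrhenius_scale(ArrheniusSpec(cfg["kc_25"], cfg["ha_kc"]), tleaf),
        ko=arrhenius_scale(ArrheniusSpec(cfg["ko_25"], cfg["ha_ko"]), tleaf),
        o=float(cfg["o2"]),
        tref=tleaf,
    )


def normalize_rate_to_25(value: float, ha_kj: float, tleaf: float) -> float:
    """Post-hoc back-scaling of a fitted rate from ``tleaf`` to 25 degC.

    Divides by the Arrhenius factor; purely a reporting convenience, never
    applied during fitting.
    """
    return value / _arrhenius_factor(ha_kj, tleaf)
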