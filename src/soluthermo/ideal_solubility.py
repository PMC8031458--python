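"""Ideal (solvent-independent) solubility from fusion calorimetry.

For a crystalline solute dissolving below its melting point, the ideal
mole-fraction solubility follows from the fusion enthalpy and the
solid–liquid heat-capacity difference:

    ln x_idl = -ΔH_fus (T_fus - T) / (R T_fus T)
               + (ΔC_p / R) [ (T_fus - T)/T + ln(T / T_fus) ]

The first (enthalpic) term dominates; the second corrects for ΔC_p ≠ 0.
When ΔC_p is unmeasured it is commonly approximated by the fusion entropy
ΔS_fus = ΔH_fus / T_fus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_data import R, FusionProperties, ValidationError


@dataclass(frozen=True)
class IdealSolubilityResult:
    """Ideal solubility at one temperature, with the two ln-space terms."""

    T: float
    x_idl: float
    term_enthalpic: float
    term_heat_capacity: float


def fusion_entropy(f: FusionProperties) -> float:
    """Fusion entropy ΔS_fus = ΔH_fus / T_fus, J/(mol K)."""
    return f.dH_fus / f.T_fus


def ideal_solubility(T: float, f: FusionProperties) -> IdealSolubilityResult:
    """Ideal mole-fraction solubility of the solute at temperature ``T``.

    Valid for 0 < T <= T_fus (solid solute); at T = T_fus both terms vanish
    and x_idl = 1.

    Raises
    ------
    ValidationError
        If T is non-positive or above the melting point.
    """
    if not T > 0:
        raise ValidationError("temperature must be positive")
    if T > f.T_fus:
        raise ValidationError(
            f"T={T} K exceeds T_fus={f.T_fus} K: melt regime not modelled"
        )
    term_h = -f.dH_fus * (f.T_fus - T) / (R * f.T_fus * T)
    term_cp = (f.dCp / R) * ((f.T_fus - T) / T + math.log(T / f.T_fus))
    return IdealSolubilityResult(
        T=T,
        x_idl=math.exp(term_h + term_cp),
        term_enthalpic=term_h,
        term_heat_capacity=term_cp,
    )


def ideal_solubility_table(temperatures, f: FusionProperties) -> list[IdealSolubilityResult]:
    """Vector convenience: one :class:`IdealSolubilityResult` per temperature."""
    return [ideal_solubility(float(T), f) for T in temperatures]
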