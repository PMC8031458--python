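"""Micellar solubilization capacity and Hansen parameter combination.

The molar solubilization capacity of a surfactant above its critical
micelle concentration (CMC) is the drug uptake per mole of micellized
surfactant:

    S_c = (S_t − S_w) / (C_s − CMC) × 1000        [mM per M]

with S_t the total drug solubility in the surfactant solution, S_w the
intrinsic water solubility and C_s the surfactant concentration, all in
mol/L.

The total Hansen solubility parameter combines the dispersion, polar and
hydrogen-bonding components Euclidean-wise: δ² = δd² + δp² + δh².
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .core_data import HansenRecord, ValidationError

log = logging.getLogger(__name__)

#: Molar concentration of pure water, mol/L — the dilute-limit factor
#: converting aqueous mole fraction to molarity (x · 55.49 ≈ mol/L).
WATER_MOLARITY = 55.49


@dataclass(frozen=True)
class SolubilizationInput:
    """Inputs of the solubilization-capacity calculation (all mol/L)."""

    S_t: float
    S_w: float
    C_s: float
    CMC: float = 0.0

    def __post_init__(self) -> None:
        if self.CMC < 0:
            raise ValidationError("CMC must be >= 0")
        if self.C_s <= self.CMC:
            raise ValidationError(
                f"C_s={self.C_s} <= CMC={self.CMC}: no micelles, capacity undefined"
            )
        if self.S_w < 0 or self.S_t < self.S_w:
            raise ValidationError("need S_t >= S_w >= 0")


def solubilization_capacity(inp: SolubilizationInput) -> float:
    """Molar solubilization capacity S_c in mM per M of micellized surfactant."""
    return (inp.S_t - inp.S_w) / (inp.C_s - inp.CMC) * 1000.0


def mole_fraction_to_molarity(x: float, water_molarity: float = WATER_MOLARITY) -> float:
    """Dilute-limit conversion of aqueous mole fraction to mol/L."""
    if not 0.0 <= x < 1.0:
        raise ValidationError("mole fraction must be in [0, 1)")
    return x * water_molarity


def capacity_from_mole_fractions(
    x_t: float, x_w: float, C_s: float, CMC: float = 0.0,
    water_molarity: float = WATER_MOLARITY,
) -> float:
    """Solubilization capacity with drug solubilities given as mole fractions.

    Both solubilities are converted to molarity with the dilute-limit
    factor before applying the capacity formula.  A CMC of 0 (every
    surfactant molecule counted as micellized) overstates the micellar
    concentration and is logged as a warning — supply the surfactant's
    CMC whenever it is known.
    """
    if CMC == 0.0:
        log.warning(
            "CMC defaulted to 0 mol/L: capacity treats all surfactant as "
            "micellized and is a lower bound"
        )
    inp = SolubilizationInput(
        S_t=mole_fraction_to_molarity(x_t, water_molarity),
        S_w=mole_fraction_to_molarity(x_w, water_molarity),
        C_s=C_s,
        CMC=CMC,
    )
    return solubilization_capacity(inp)


def hansen_total(delta_d: float, delta_p: float, delta_h: float) -> float:
    """Total Hansen parameter sqrt(δd² + δp² + δh²), MPa^1/2."""
    if delta_d < 0 or delta_p < 0 or delta_h < 0:
        raise ValidationError("Hansen components must be >= 0")
    return math.sqrt(delta_d**2 + delta_p**2 + delta_h**2)


@dataclass(frozen=True)
class HansenDiscrepancy:
    """One substance whose stated total disagrees with its components."""

    substance: str
    stated_total: float
    computed_total: float
    relative_deviation: float


def hansen_table_check(
    records: list[HansenRecord], tol: float = 0.02
) -> list[HansenDiscrepancy]:
    """Flag records whose stated δ disagrees with sqrt(δd²+δp²+δh²).

    Records without a stated total are skipped.  ``tol`` is the relative
    deviation above which a record is flagged; the default 2 % tolerates
    rounding of printed tables while catching genuinely inconsistent rows
    (e.g. a transposed component).
    """
    out = []
    for rec in records:
        if rec.delta_total is None:
            continue
        computed = rec.computed_total
        rel = abs(computed - rec.delta_total) / rec.delta_total
        if rel > tol:
            out.append(
                HansenDiscrepancy(
                    substance=rec.substance,
                    stated_total=rec.delta_total,
                    computed_total=computed,
                    relative_deviation=rel,
                )
            )
    return out
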