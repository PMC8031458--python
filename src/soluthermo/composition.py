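"""Conversions between raw measurements and mole-fraction solubility.

Saturation assays report either dissolved masses or a mass concentration
(μg/mL) of supernatant; all downstream modelling works in mole fraction
x = n_solute / (n_solute + n_solvent).  Concentration conversions assume a
dilute solution (solution density ≈ solvent density).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_data import ValidationError


@dataclass(frozen=True)
class MassPair:
    """Dissolved solute mass and solvent-system mass with molar masses.

    m1: solute mass, g (may be 0);  M1: solute molar mass, g/mol;
    m2: solvent-system mass, g;     M2: solvent-system molar mass, g/mol.
    """

    m1: float
    M1: float
    m2: float
    M2: float

    def __post_init__(self) -> None:
        if self.m1 < 0:
            raise ValidationError("solute mass m1 must be >= 0")
        for name in ("M1", "m2", "M2"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")


def mole_fraction_from_masses(p: MassPair) -> float:
    """Mole fraction from dissolved masses: (m1/M1) / (m1/M1 + m2/M2)."""
    n1 = p.m1 / p.M1
    n2 = p.m2 / p.M2
    return n1 / (n1 + n2)


def mole_fraction_two_component(
    m1: float, M1: float, m_w: float, M_w: float, m_s: float, M_s: float
) -> float:
    """Mole fraction with water and surfactant as separate solvent species.

    The single-solvent formula treats the whole liquid phase as one
    pseudo-component; for micellar media one may instead count water and
    surfactant moles separately:  n1 / (n1 + m_w/M_w + m_s/M_s).
    At surfactant loadings of a few tens of mM the two conventions differ
    by under 2 %, but the choice should be explicit.
    """
    if m1 < 0 or m_w < 0 or m_s < 0:
        raise ValidationError("masses must be >= 0")
    for name, M in (("M1", M1), ("M_w", M_w), ("M_s", M_s)):
        if not M > 0:
            raise ValidationError(f"{name} must be strictly positive")
    n1 = m1 / M1
    denom = n1 + m_w / M_w + m_s / M_s
    if denom == 0:
        raise ValidationError("no material in the system")
    return n1 / denom


def mole_fraction_from_concentration(
    c_ug_per_ml: float,
    M_solute: float,
    M_solvent: float = 18.015,
    rho_solvent: float = 1.0,
) -> float:
    """Mole fraction from a μg/mL mass concentration (dilute assumption).

    Per mL of solution:  n_solute = c·1e-6 / M_solute,
    n_solvent ≈ rho_solvent / M_solvent  (solution density taken equal to
    the solvent density, valid for x ≪ 1).
    """
    if c_ug_per_ml < 0:
        raise ValidationError("concentration must be >= 0")
    if not (M_solute > 0 and M_solvent > 0 and rho_solvent > 0):
        raise ValidationError("molar masses and density must be positive")
    n1 = c_ug_per_ml * 1e-6 / M_solute
    n2 = rho_solvent / M_solvent
    return n1 / (n1 + n2)


def concentration_from_mole_fraction(
    x: float,
    M_solute: float,
    M_solvent: float = 18.015,
    rho_solvent: float = 1.0,
) -> float:
    """Exact algebraic inverse of :func:`mole_fraction_from_concentration`."""
    if not 0.0 <= x < 1.0:
        raise ValidationError("mole fraction must be in [0, 1)")
    if not (M_solute > 0 and M_solvent > 0 and rho_solvent > 0):
        raise ValidationError("molar masses and density must be positive")
    n2 = rho_solvent / M_solvent
    n1 = x / (1.0 - x) * n2
    return n1 * M_solute * 1e6
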