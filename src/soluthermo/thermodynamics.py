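"""Apparent thermodynamics of dissolution from solubility–temperature data.

The apparent standard dissolution enthalpy is obtained from a van't Hoff
regression of ln x_e on (1/T − 1/T_hm), where T_hm = n / Σ(1/T_i) is the
mean harmonic temperature of the study (the Krug reparameterization, which
decorrelates the slope and intercept estimates):

    Δ_sol H⁰ = −R · slope
    Δ_sol G⁰ = −R · T_hm · intercept
    Δ_sol S⁰ = (Δ_sol H⁰ − Δ_sol G⁰) / T_hm

Because the u-regression is an affine reparameterization of the plain
ln x vs 1/T regression, the same quantities follow directly from van't
Hoff parameters (a, b):  Δ_sol H⁰ = −R·b,  Δ_sol G⁰ = −R(T_hm·a + b),
Δ_sol S⁰ = R·a.

Enthalpy and Gibbs energy are reported in kJ/mol, entropy in J/(mol K).
A dissolution is classified endothermic when Δ_sol H⁰ > 0 and
entropy-driven when Δ_sol S⁰ > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import R, SolubilityCurve, ValidationError
from .model_fitting import VantHoffFit, fit_vant_hoff, r_squared


@dataclass(frozen=True)
class ThermoResult:
    """Apparent dissolution thermodynamics of one sample at T_hm.

    dH and dG in kJ/mol; dS in J/(mol K); dS is defined by the Gibbs
    difference identity, so dG = dH − T_hm·dS/1000 holds exactly.
    """

    sample_id: str
    T_hm: float
    dH: float
    dG: float
    dS: float
    r2: float

    @property
    def endothermic(self) -> bool:
        return self.dH > 0

    @property
    def entropy_driven(self) -> bool:
        return self.dS > 0

    @property
    def classification(self) -> str:
        return (
            ("endothermic" if self.endothermic else "exothermic")
            + ", "
            + ("entropy-driven" if self.entropy_driven else "enthalpy-driven")
        )


def harmonic_mean_temperature(temps) -> float:
    """Mean harmonic temperature n / Σ(1/T_i) of a temperature set, K."""
    t = np.asarray(list(temps), dtype=float)
    if t.size == 0:
        raise ValidationError("need at least one temperature")
    if np.any(t <= 0):
        raise ValidationError("temperatures must be positive")
    return float(t.size / np.sum(1.0 / t))


def thermo_from_vant_hoff(fit: VantHoffFit, T_hm: float) -> ThermoResult:
    """Apparent thermodynamics from already-fitted van't Hoff parameters."""
    if not T_hm > 0:
        raise ValidationError("T_hm must be positive")
    dH = -R * fit.b / 1000.0
    dG = -R * (T_hm * fit.a + fit.b) / 1000.0
    dS = (dH - dG) * 1000.0 / T_hm
    return ThermoResult(
        sample_id=fit.sample_id, T_hm=T_hm, dH=dH, dG=dG, dS=dS, r2=fit.r2
    )


def apparent_thermodynamics(curve: SolubilityCurve, T_hm: float) -> ThermoResult:
    """Krug-style regression of ln x_e on (1/T − 1/T_hm) for one curve.

    Numerically identical to :func:`thermo_from_vant_hoff` applied to the
    plain van't Hoff fit of the same curve; kept as the primary route
    because it is the analysis as usually stated.
    """
    if not T_hm > 0:
        raise ValidationError("T_hm must be positive")
    if len(curve) < 2:
        raise ValidationError(f"{curve.sample_id!r}: need >= 2 points")
    T = np.asarray(curve.temperatures)
    u = 1.0 / T - 1.0 / T_hm
    ln_x = np.log(np.asarray(curve.x_e))
    design = np.column_stack([np.ones_like(u), u])
    (intercept, slope), *_ = np.linalg.lstsq(design, ln_x, rcond=None)
    r2 = r_squared(ln_x, design @ np.array([intercept, slope]))
    dH = -R * slope / 1000.0
    dG = -R * T_hm * intercept / 1000.0
    dS = (dH - dG) * 1000.0 / T_hm
    return ThermoResult(
        sample_id=curve.sample_id, T_hm=T_hm,
        dH=float(dH), dG=float(dG), dS=float(dS), r2=float(r2),
    )


def analyze_curves(
    curves, T_hm: float | None = None
) -> tuple[float, list[ThermoResult]]:
    """Apparent thermodynamics for a whole dataset.

    T_hm defaults to the harmonic mean of the union of all measured
    temperatures (an override exists to replay a stated reference
    temperature exactly).  Returns (T_hm, results).
    """
    curves = list(curves)
    if T_hm is None:
        all_T = sorted({t for c in curves for t in c.temperatures})
        T_hm = harmonic_mean_temperature(all_T)
    return T_hm, [apparent_thermodynamics(c, T_hm) for c in curves]
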