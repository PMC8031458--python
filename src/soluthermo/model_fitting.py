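"""van't Hoff and Apelblat correlation of solubility–temperature data.

Both correlations are fitted to ln x_e by ordinary unweighted least
squares:

    van't Hoff:  ln x = a + b/T
    Apelblat:    ln x = A + B/T + C ln T

The Apelblat model, although usually described as nonlinear, is linear in
its parameters once written in ln space, so both fits reduce to a linear
least-squares solve; we use an orthogonal (QR/SVD) factorization rather
than the normal equations because 1/T and ln T are nearly collinear over
the narrow temperature spans typical of shake-flask studies.

Goodness of fit is reported two ways, matching field convention: R² on the
ln-space residuals, and the percent root-mean-square *relative* deviation
(RMSD%) on the back-transformed solubilities:

    RMSD% = 100 · sqrt( (1/N) Σ ((x_fit − x_e)/x_e)² )
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_data import SolubilityCurve, ValidationError

#: Condition number of the scaled design above which a collinearity
#: warning is raised for the Apelblat fit.
CONDITION_LIMIT = 1e10


class FitError(ValueError):
    """Raised when a curve has too few points or a degenerate design."""


class ConditioningWarning(UserWarning):
    """The regression design is ill-conditioned; parameters are unstable."""


class ExtrapolationWarning(UserWarning):
    """A model was evaluated outside its fitted temperature range."""


@dataclass(frozen=True)
class VantHoffFit:
    """ln x = a + b/T fitted to one curve (b in kelvin)."""

    sample_id: str
    a: float
    b: float
    r2: float
    rmsd_pct: float
    n: int
    T_min: float
    T_max: float
    residuals_ln: tuple[float, ...] = field(repr=False, default=())

    def predict_ln(self, T):
        return self.a + self.b / np.asarray(T, dtype=float)

    def predict(self, T):
        """Model solubility x at temperature(s) T (kelvin)."""
        return np.exp(self.predict_ln(T))


@dataclass(frozen=True)
class ApelblatFit:
    """ln x = A + B/T + C ln T fitted to one curve (B in kelvin)."""

    sample_id: str
    A: float
    B: float
    C: float
    r2: float
    rmsd_pct: float
    n: int
    T_min: float
    T_max: float
    condition_number: float = math.nan

    def predict_ln(self, T):
        T = np.asarray(T, dtype=float)
        return self.A + self.B / T + self.C * np.log(T)

    def predict(self, T):
        """Model solubility x at temperature(s) T (kelvin)."""
        return np.exp(self.predict_ln(T))


def rmsd_percent(observed, predicted) -> float:
    """Percent RMS relative deviation between observed and model solubility."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValidationError("observed and predicted must have equal nonzero length")
    if np.any(obs <= 0):
        raise ValidationError("observed solubilities must be strictly positive")
    return 100.0 * math.sqrt(np.mean(((pred - obs) / obs) ** 2))


def r_squared(observed, fitted) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.size < 2:
        raise ValidationError("need >= 2 paired values")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValidationError("zero total variance: R^2 undefined")
    return 1.0 - float(np.sum((obs - fit) ** 2) / ss_tot)


def _ln_space_fit(curve: SolubilityCurve, design: np.ndarray):
    ln_x = np.log(np.asarray(curve.x_e))
    coef, *_ = np.linalg.lstsq(design, ln_x, rcond=None)
    fitted_ln = design @ coef
    r2 = r_squared(ln_x, fitted_ln)
    rmsd = rmsd_percent(curve.x_e, np.exp(fitted_ln))
    return coef, fitted_ln - ln_x, r2, rmsd


def fit_vant_hoff(curve: SolubilityCurve) -> VantHoffFit:
    """Ordinary least squares of ln x_e on 1/T."""
    if len(curve) < 2:
        raise FitError(f"{curve.sample_id!r}: van't Hoff fit needs >= 2 points")
    T = np.asarray(curve.temperatures)
    design = np.column_stack([np.ones_like(T), 1.0 / T])
    coef, resid, r2, rmsd = _ln_space_fit(curve, design)
    return VantHoffFit(
        sample_id=curve.sample_id,
        a=float(coef[0]), b=float(coef[1]),
        r2=r2, rmsd_pct=rmsd, n=len(curve),
        T_min=float(T[0]), T_max=float(T[-1]),
        residuals_ln=tuple(-resid),
    )


def fit_apelblat(curve: SolubilityCurve) -> ApelblatFit:
    """Least squares of ln x_e on the regressors {1, 1/T, ln T}.

    With exactly 3 points the fit is interpolatory (zero residuals).
    A :class:`ConditioningWarning` is raised when the column-scaled design
    has condition number above ``CONDITION_LIMIT``; a rank-deficient design
    (e.g. all temperatures equal after replicate averaging) is an error.
    """
    if len(curve) < 3:
        raise FitError(f"{curve.sample_id!r}: Apelblat fit needs >= 3 points")
    T = np.asarray(curve.temperatures)
    design = np.column_stack([np.ones_like(T), 1.0 / T, np.log(T)])
    # condition of the column-normalised design: scale-free collinearity measure
    scaled = design / np.linalg.norm(design, axis=0)
    cond = float(np.linalg.cond(scaled))
    if np.linalg.matrix_rank(design) < 3:
        raise FitError(f"{curve.sample_id!r}: rank-deficient Apelblat design")
    if cond > CONDITION_LIMIT:
        warnings.warn(
            f"{curve.sample_id!r}: Apelblat design condition number {cond:.2e} "
            "exceeds limit; 1/T and ln T are nearly collinear over this span",
            ConditioningWarning,
            stacklevel=2,
        )
    coef, _, r2, rmsd = _ln_space_fit(curve, design)
    return ApelblatFit(
        sample_id=curve.sample_id,
        A=float(coef[0]), B=float(coef[1]), C=float(coef[2]),
        r2=r2, rmsd_pct=rmsd, n=len(curve),
        T_min=float(T[0]), T_max=float(T[-1]),
        condition_number=cond,
    )


def predict_solubility(fit: VantHoffFit | ApelblatFit, T: float) -> float:
    """Evaluate a fitted correlation at ``T`` (kelvin).

    Emits an :class:`ExtrapolationWarning` when ``T`` lies outside the
    fitted temperature range (e.g. extrapolating down to 298.2 K from a
    300–320 K study).
    """
    if not T > 0:
        raise ValidationError("temperature must be positive")
    if not (fit.T_min <= T <= fit.T_max):
        warnings.warn(
            f"{fit.sample_id!r}: T={T} K outside fitted range "
            f"[{fit.T_min}, {fit.T_max}] K — extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(fit.predict(T))
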