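"""Synthetic shake-flask solubility studies with known ground truth.

The generator emulates the design of a saturation shake-flask study:
a handful of temperature levels (default 300.2/310.2/320.2 K), replicate
equilibrations per level (default triplicate), and multiplicative
measurement noise on solubility — i.e. additive Gaussian noise on ln x,
matching the relative-uncertainty convention of solubility reporting.
The default noise level, sd(ln x) = 0.014, corresponds to a 1.4 %
relative standard uncertainty on x_e.

Truth is either a van't Hoff pair (a, b) or an Apelblat triple (A, B, C);
:func:`recovery_study` runs generate → fit → thermodynamics repeatedly and
summarises the bias and RMSE of the recovered parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import SolubilityCurve, ValidationError
from .model_fitting import fit_vant_hoff
from .thermodynamics import harmonic_mean_temperature, thermo_from_vant_hoff

DEFAULT_TEMPERATURES = (300.2, 310.2, 320.2)


@dataclass(frozen=True)
class SyntheticSpec:
    """Design and ground truth of one synthetic solubility study.

    Exactly one of (true_a, true_b) or (true_A, true_B, true_C) defines
    the true temperature dependence of ln x.
    """

    true_a: float | None = None
    true_b: float | None = None
    true_A: float | None = None
    true_B: float | None = None
    true_C: float | None = None
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    replicates: int = 3
    noise_sd_ln: float = 0.014
    seed: int = 0
    sample_id: str = "synthetic"
    surfactant: str = "water"
    conc_mM: float = 0.0

    def __post_init__(self) -> None:
        vh = self.true_a is not None and self.true_b is not None
        apl = all(v is not None for v in (self.true_A, self.true_B, self.true_C))
        if vh == apl:
            raise ValidationError(
                "specify either (true_a, true_b) or (true_A, true_B, true_C)"
            )
        if self.noise_sd_ln < 0:
            raise ValidationError("noise_sd_ln must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        for t in self.temperatures:
            if not 250.0 < t < 400.0:
                raise ValidationError(f"temperature {t} K outside (250, 400)")

    def true_ln_x(self, T) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        if self.true_a is not None:
            return self.true_a + self.true_b / T
        return self.true_A + self.true_B / T + self.true_C * np.log(T)


@dataclass(frozen=True)
class RecoverySummary:
    """Bias and RMSE of recovered parameters over repeated synthetic studies."""

    n_reps: int
    noise_sd_ln: float
    bias: dict[str, float] = field(default_factory=dict)
    rmse: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    truth: dict[str, float] = field(default_factory=dict)


def generate_curve(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> SolubilityCurve:
    """Simulate one study and return its replicate-averaged curve.

    Per temperature, ``replicates`` noisy solubilities are drawn as
    x = exp(ln x_true + ε) with ε ~ N(0, noise_sd_ln²), then averaged
    arithmetically — the same reduction applied to replicate rows on file
    input.  The same seed always yields the same curve.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    T = np.asarray(spec.temperatures)
    ln_true = spec.true_ln_x(T)
    eps = rng.normal(0.0, spec.noise_sd_ln, size=(spec.replicates, T.size))
    x = np.exp(ln_true[None, :] + eps).mean(axis=0)
    if np.any(x >= 1.0):
        raise ValidationError("spec generates x >= 1: not a valid mole fraction")
    return SolubilityCurve(
        sample_id=spec.sample_id,
        surfactant=spec.surfactant,
        conc_mM=spec.conc_mM,
        temperatures=tuple(T),
        x_e=tuple(x),
    )


def recovery_study(spec: SyntheticSpec, n_reps: int) -> RecoverySummary:
    """Repeat generate → van't Hoff fit → thermodynamics; summarise recovery.

    Requires a van't Hoff truth.  Tracks a, b, and the derived apparent
    thermodynamic quantities dH/dG/dS (at the design's harmonic mean
    temperature) against their true values.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if spec.true_a is None:
        raise ValidationError("recovery_study needs a van't Hoff truth (true_a, true_b)")
    rng = np.random.default_rng(spec.seed)
    T_hm = harmonic_mean_temperature(spec.temperatures)

    true_fit_like = fit_vant_hoff(
        generate_curve(
            SyntheticSpec(
                true_a=spec.true_a, true_b=spec.true_b,
                temperatures=spec.temperatures, replicates=1,
                noise_sd_ln=0.0, seed=0,
            )
        )
    )
    true_thermo = thermo_from_vant_hoff(true_fit_like, T_hm)
    truth = {
        "a": spec.true_a, "b": spec.true_b,
        "dH": true_thermo.dH, "dG": true_thermo.dG, "dS": true_thermo.dS,
    }

    draws: dict[str, list[float]] = {k: [] for k in truth}
    for _ in range(n_reps):
        curve = generate_curve(spec, rng=rng)
        fit = fit_vant_hoff(curve)
        th = thermo_from_vant_hoff(fit, T_hm)
        for k, v in (("a", fit.a), ("b", fit.b), ("dH", th.dH), ("dG", th.dG), ("dS", th.dS)):
            draws[k].append(v)

    bias, rmse, sd = {}, {}, {}
    for k, vals in draws.items():
        arr = np.asarray(vals)
        err = arr - truth[k]
        bias[k] = float(err.mean())
        rmse[k] = float(np.sqrt((err**2).mean()))
        sd[k] = float(arr.std(ddof=1)) if n_reps > 1 else 0.0
    return RecoverySummary(
        n_reps=n_reps, noise_sd_ln=spec.noise_sd_ln,
        bias=bias, rmse=rmse, sd=sd, truth=truth,
    )


def ols_slope_sd(temperatures, noise_sd_ln: float, replicates: int = 1) -> float:
    """Closed-form OLS standard deviation of the fitted van't Hoff slope b.

    For ln x regressed on u = 1/T with i.i.d. noise of standard deviation
    σ on each averaged ln x value: sd(b̂) = σ_eff / sqrt(Σ (u_i − ū)²).
    With m replicates averaged on the x scale and small σ, the effective
    noise on ln(mean x) is ≈ σ/sqrt(m).
    """
    u = 1.0 / np.asarray(temperatures, dtype=float)
    s_uu = np.sum((u - u.mean()) ** 2)
    return noise_sd_ln / np.sqrt(replicates) / np.sqrt(s_uu)
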