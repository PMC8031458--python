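"""Domain types and I/O for saturation-solubility datasets.

The central object is :class:`SolubilityCurve`: one sample's mole-fraction
solubility measured at several absolute temperatures, together with the
identity and molar concentration of the surfactant (``"water"`` with 0 mM
for the neat aqueous sample).  Curves are the unit of model fitting and of
the apparent thermodynamic analysis.

Input tables are tidy CSV with columns ``sample_id, surfactant, conc_mM,
T_K, x_e`` — one row per (sample, temperature).  Replicate rows sharing
(sample_id, T_K) are averaged arithmetically on construction.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

#: Universal gas constant, J/(mol K).  Fixed at the 4-digit rounding used
#: throughout the solubility literature this package targets.
R = 8.314

#: Molar mass of water, g/mol.
M_WATER = 18.015

#: Molar mass of simvastatin (C25H38O5), g/mol.
M_SIMVASTATIN = 418.57

_REQUIRED_COLUMNS = ("sample_id", "surfactant", "conc_mM", "T_K", "x_e")

#: Temperatures below this are almost certainly Celsius values fed in by
#: mistake; every equation in the package needs kelvin.
_MIN_PLAUSIBLE_KELVIN = 200.0


class FormatError(ValueError):
    """A table is structurally wrong (missing column, bad header)."""


class ValidationError(ValueError):
    """A value violates a physical or structural invariant."""


@dataclass(frozen=True)
class SolubilityCurve:
    """One sample's (T, x_e) saturation-solubility series.

    Parameters
    ----------
    sample_id
        Label of the sample, e.g. ``"20 mM M59"`` or ``"H2O"``.
    surfactant
        Surfactant name, or ``"water"`` for the neat aqueous sample.
    conc_mM
        Surfactant molar concentration in mmol/L (0 for pure water).
    temperatures
        Absolute temperatures in kelvin, strictly increasing.
    x_e
        Mole-fraction solubilities, parallel to ``temperatures``.
    """

    sample_id: str
    surfactant: str
    conc_mM: float
    temperatures: tuple[float, ...]
    x_e: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperatures", tuple(float(t) for t in self.temperatures))
        object.__setattr__(self, "x_e", tuple(float(x) for x in self.x_e))
        if len(self.temperatures) != len(self.x_e):
            raise ValidationError(
                f"{self.sample_id!r}: {len(self.temperatures)} temperatures but "
                f"{len(self.x_e)} solubilities"
            )
        if len(self.temperatures) < 2:
            raise ValidationError(f"{self.sample_id!r}: need at least 2 points")
        for t in self.temperatures:
            if not t > 0:
                raise ValidationError(f"{self.sample_id!r}: non-positive temperature {t}")
            if t < _MIN_PLAUSIBLE_KELVIN:
                raise ValidationError(
                    f"{self.sample_id!r}: T={t} K is below {_MIN_PLAUSIBLE_KELVIN} K — "
                    "probable Celsius input; temperatures must be kelvin"
                )
        if any(b <= a for a, b in zip(self.temperatures, self.temperatures[1:])):
            raise ValidationError(f"{self.sample_id!r}: temperatures must be strictly increasing")
        for x in self.x_e:
            if not 0.0 < x < 1.0:
                raise ValidationError(f"{self.sample_id!r}: x_e={x} outside (0, 1)")
        if self.conc_mM < 0:
            raise ValidationError(f"{self.sample_id!r}: negative conc_mM")

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass(frozen=True)
class FusionProperties:
    """Fusion (melting) properties of the solute.

    ``dH_fus`` is in J/mol, ``dCp`` in J/(mol K).  The fusion entropy
    ``dS_fus`` is derived as dH_fus/T_fus; if supplied explicitly it must
    agree with the derived value to 0.1 %.
    """

    T_fus: float
    dH_fus: float
    dCp: float = 0.0
    dS_fus: float | None = None

    def __post_init__(self) -> None:
        if not self.T_fus > 0:
            raise ValidationError("T_fus must be positive")
        if not self.dH_fus > 0:
            raise ValidationError("dH_fus must be positive")
        if self.dCp < 0:
            raise ValidationError("dCp must be non-negative")
        derived = self.dH_fus / self.T_fus
        if self.dS_fus is None:
            object.__setattr__(self, "dS_fus", derived)
        elif abs(self.dS_fus - derived) > 1e-3 * abs(derived):
            raise ValidationError(
                f"dS_fus={self.dS_fus} inconsistent with dH_fus/T_fus={derived:.4f}"
            )

    @classmethod
    def from_config(cls, cfg: Mapping[str, float]) -> "FusionProperties":
        """Build from a config mapping.

        Enthalpy may be given either as ``dH_fus_J_mol`` or as
        ``dH_fus_kJ_mol`` (converted once, and logged); heat capacity as
        ``dCp_J_mol_K`` (defaults to dS_fus when absent — the standard
        substitution when the true heat-capacity difference is unmeasured).
        """
        T_fus = float(cfg["T_fus_K"])
        if "dH_fus_J_mol" in cfg:
            dH = float(cfg["dH_fus_J_mol"])
        else:
            dH = float(cfg["dH_fus_kJ_mol"]) * 1000.0
            log.info("fusion enthalpy given in kJ/mol; converted to %.1f J/mol", dH)
        dCp = cfg.get("dCp_J_mol_K")
        if dCp is None:
            dCp = dH / T_fus
            log.info("dCp not given; defaulting to dS_fus = %.2f J/(mol K)", dCp)
        return cls(T_fus=T_fus, dH_fus=dH, dCp=float(dCp))


@dataclass(frozen=True)
class HansenRecord:
    """Hansen solubility parameters of one substance, MPa^1/2."""

    substance: str
    delta_d: float
    delta_p: float
    delta_h: float
    delta_total: float | None = None

    def __post_init__(self) -> None:
        for name in ("delta_d", "delta_p", "delta_h"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.substance!r}: negative {name}")
        if self.delta_total is not None and self.delta_total < 0:
            raise ValidationError(f"{self.substance!r}: negative delta_total")

    @property
    def computed_total(self) -> float:
        """Total parameter from the components, sqrt(dd^2 + dp^2 + dh^2)."""
        return math.sqrt(self.delta_d**2 + self.delta_p**2 + self.delta_h**2)


# ---------------------------------------------------------------------------
# Readers / writers


def _apply_dialect(df: pd.DataFrame, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    return df


def read_solubility_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[SolubilityCurve]:
    """Read a tidy solubility CSV into a list of :class:`SolubilityCurve`.

    Rows are grouped by ``sample_id`` (curve order follows first appearance
    in the file), sorted by temperature within each curve.  Replicate rows
    sharing (sample_id, T_K) are averaged arithmetically; the replicate
    count is logged.

    Parameters
    ----------
    path
        CSV with columns ``sample_id, surfactant, conc_mM, T_K, x_e``.
    dialect
        Optional mapping from canonical column name to the name used in the
        file, e.g. ``{"T_K": "temperature"}``.
    """
    df = _apply_dialect(pd.read_csv(path), dialect)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if df.empty:
        return []
    for col in ("T_K", "x_e"):
        bad = df.index[~(df[col] > 0)]
        if len(bad):
            raise ValidationError(
                f"{path}: non-positive {col} in row(s) {[int(i) + 2 for i in bad]} "
                "(1-based, counting the header)"
            )
    return curves_from_frame(df)


def curves_from_frame(df: pd.DataFrame) -> list[SolubilityCurve]:
    """Group a tidy solubility frame into curves (replicates averaged)."""
    curves: list[SolubilityCurve] = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        reps = grp.groupby("T_K", sort=True)["x_e"]
        n_rep = reps.size()
        if (n_rep > 1).any():
            log.info(
                "sample %r: averaged replicates at %d temperature(s) (max %d reps)",
                sample_id, int((n_rep > 1).sum()), int(n_rep.max()),
            )
        mean_x = reps.mean()
        curves.append(
            SolubilityCurve(
                sample_id=str(sample_id),
                surfactant=str(grp["surfactant"].iloc[0]),
                conc_mM=float(grp["conc_mM"].iloc[0]),
                temperatures=tuple(mean_x.index),
                x_e=tuple(mean_x.values),
            )
        )
    return curves


def curves_to_frame(curves: Iterable[SolubilityCurve]) -> pd.DataFrame:
    """Inverse of :func:`curves_from_frame` (one row per point)."""
    records = [
        {"sample_id": c.sample_id, "surfactant": c.surfactant,
         "conc_mM": c.conc_mM, "T_K": t, "x_e": x}
        for c in curves
        for t, x in zip(c.temperatures, c.x_e)
    ]
    return pd.DataFrame(records, columns=list(_REQUIRED_COLUMNS))


def read_hansen_table(path: str | Path) -> list[HansenRecord]:
    """Read a Hansen-parameter CSV (``substance,delta_d,delta_p,delta_h[,delta_total]``)."""
    df = pd.read_csv(path)
    missing = [c for c in ("substance", "delta_d", "delta_p", "delta_h") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    has_total = "delta_total" in df.columns
    return [
        HansenRecord(
            substance=str(row["substance"]),
            delta_d=float(row["delta_d"]),
            delta_p=float(row["delta_p"]),
            delta_h=float(row["delta_h"]),
            delta_total=float(row["delta_total"]) if has_total else None,
        )
        for _, row in df.iterrows()
    ]


def _as_frame(results: Any) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    results = list(results)
    if results and hasattr(results[0], "__dataclass_fields__"):
        cols = [f.name for f in fields(results[0])]
        return pd.DataFrame(
            [{c: getattr(r, c) for c in cols} for r in results], columns=cols
        )
    return pd.DataFrame(results)


def write_results(results: Any, path: str | Path) -> None:
    """Write a result set (dataclasses, dicts or a DataFrame) to CSV or JSON.

    Numeric fields are written with 12 significant digits so that a
    write/read round-trip is lossless at that precision.  An empty result
    set produces a header-only CSV (or an empty JSON list).
    """
    path = Path(path)
    df = _as_frame(results)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1, default=str))
    else:
        df.to_csv(path, index=False, float_format="%.12g")


def write_curves(curves: Iterable[SolubilityCurve], path: str | Path) -> None:
    """Write curves back to the standard tidy CSV schema."""
    write_results(curves_to_frame(curves), path)


# ---------------------------------------------------------------------------
# Packaged example data


def _data_path(name: str):
    return resources.files("soluthermo.data").joinpath(name)


def load_simvastatin_table() -> list[SolubilityCurve]:
    """The packaged simvastatin shake-flask dataset.

    25 curves — neat water plus 6 non-ionic surfactants (Tween-80/20,
    Myrj-52/59, Brij-35/58) at 1, 5, 10 and 20 mM — each measured at
    300.2, 310.2 and 320.2 K.
    """
    with resources.as_file(_data_path("simvastatin_solubility.csv")) as p:
        return read_solubility_table(p)


def load_simvastatin_fusion() -> FusionProperties:
    """Fusion properties of simvastatin from DSC (T_fus, dH_fus, dCp)."""
    cfg = json.loads(_data_path("simvastatin_fusion.json").read_text())
    return FusionProperties.from_config(cfg)


def load_hansen_table() -> list[HansenRecord]:
    """Hansen parameters for simvastatin, water and the 6 surfactants."""
    with resources.as_file(_data_path("hansen_parameters.csv")) as p:
        return read_hansen_table(p)
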