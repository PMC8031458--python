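"""Whole-dataset analysis: fit both correlations, run the apparent
thermodynamic analysis, tabulate ideal solubility, and write the result
tables as CSV plus aligned text."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core_data import FusionProperties, SolubilityCurve, write_results
from .ideal_solubility import ideal_solubility_table
from .model_fitting import fit_apelblat, fit_vant_hoff
from .thermodynamics import analyze_curves

log = logging.getLogger(__name__)


def overall_rmsd(fits) -> float:
    """Average of the per-sample RMSD% values (the usual 'overall RMSD')."""
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit")
    return sum(f.rmsd_pct for f in fits) / len(fits)


@dataclass
class AnalysisBundle:
    """All result tables of one full run."""

    vant_hoff: pd.DataFrame
    apelblat: pd.DataFrame
    thermodynamics: pd.DataFrame
    ideal: pd.DataFrame | None
    T_hm: float
    overall_rmsd_vant_hoff: float
    overall_rmsd_apelblat: float
    warnings: list[str]


def run_full_analysis(
    curves: list[SolubilityCurve],
    fusion: FusionProperties | None = None,
    T_hm: float | None = None,
) -> AnalysisBundle:
    """Fit van't Hoff + Apelblat per curve and run the thermodynamic analysis.

    ``T_hm`` defaults to the harmonic mean of all measured temperatures.
    The ideal-solubility table is produced when fusion properties are
    given, at the union of measured temperatures.  Deterministic: the same
    curves and options always produce identical tables.
    """
    if not curves:
        raise ValueError("no curves to analyse")
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        vh = [fit_vant_hoff(c) for c in curves]
        apl = [fit_apelblat(c) for c in curves if len(c) >= 3]
        T_hm, thermo = analyze_curves(curves, T_hm)
        captured = [str(w.message) for w in wlist]

    vh_df = pd.DataFrame(
        [{"sample_id": f.sample_id, "a": f.a, "b": f.b, "r2": f.r2,
          "rmsd_pct": f.rmsd_pct} for f in vh]
    )
    apl_df = pd.DataFrame(
        [{"sample_id": f.sample_id, "A": f.A, "B": f.B, "C": f.C,
          "r2": f.r2, "rmsd_pct": f.rmsd_pct} for f in apl]
    )
    th_df = pd.DataFrame(
        [{"sample_id": t.sample_id, "dH_kJ_mol": t.dH, "dG_kJ_mol": t.dG,
          "dS_J_mol_K": t.dS, "r2": t.r2, "classification": t.classification}
         for t in thermo]
    )
    ideal_df = None
    if fusion is not None:
        temps = sorted({t for c in curves for t in c.temperatures})
        ideal_df = pd.DataFrame(
            [{"T_K": r.T, "x_idl": r.x_idl} for r in ideal_solubility_table(temps, fusion)]
        )
    return AnalysisBundle(
        vant_hoff=vh_df,
        apelblat=apl_df,
        thermodynamics=th_df,
        ideal=ideal_df,
        T_hm=T_hm,
        overall_rmsd_vant_hoff=overall_rmsd(vh),
        overall_rmsd_apelblat=overall_rmsd(apl) if apl else float("nan"),
        warnings=captured,
    )


def write_bundle(bundle: AnalysisBundle, outdir: str | Path) -> list[Path]:
    """Write every table of a bundle as CSV plus an aligned-text report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "vant_hoff_fits": bundle.vant_hoff,
        "apelblat_fits": bundle.apelblat,
        "thermodynamics": bundle.thermodynamics,
    }
    if bundle.ideal is not None:
        tables["ideal_solubility"] = bundle.ideal
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        write_results(df, p)
        written.append(p)
    report = outdir / "report.txt"
    with report.open("w") as fh:
        fh.write(f"T_hm = {bundle.T_hm:.2f} K\n")
        fh.write(f"overall RMSD (van't Hoff) = {bundle.overall_rmsd_vant_hoff:.2f} %\n")
        fh.write(f"overall RMSD (Apelblat)   = {bundle.overall_rmsd_apelblat:.2f} %\n\n")
        for name, df in tables.items():
            fh.write(f"== {name} ==\n")
            fh.write(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
            fh.write("\n\n")
        if bundle.warnings:
            fh.write("== provenance / warnings ==\n")
            for w in bundle.warnings:
                fh.write(f"- {w}\n")
    written.append(report)
    return written
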