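"""End-to-end orchestration: simulate → convert → fit → metrics → trends.

Per-bottle results are organised into three summary tables per additive,
mirroring the conventional layout of in-vitro gas-production papers:

* kinetics — A1, H1, Vmax, Tmax and gas production at fixed hours;
* fermentation — pH, dDM, dNDF, dADF, PF48, tVFA, CH4 %;
* VFA — total VFA and the seven-acid molar profile;

each with dose-mean rows plus Linear / Quadratic p-value and SEM rows from
the random-incubation trend model.  The dose-0 control is shared by every
additive's dose series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dose_response import fit_dose_model
from .errors import DataError
from .fermentation_metrics import FermentationRecord, compute_metrics
from .formats_io import (
    BottleMeta,
    RunConfig,
    VFA_ACIDS,
    write_results_table,
)
from .gas_conversion import (
    ConversionContext,
    GasCurve,
    PressureTrace,
    blank_mean,
    gp_at_hours,
    trace_to_curve,
)
from .kinetics import derive_kinetics, fit_bottle
from .synthetic_data import DesignSpec, generate_experiment

logger = logging.getLogger(__name__)

KINETIC_COLUMNS = ("A1", "H1", "Vmax", "Tmax")
FERMENTATION_COLUMNS = ("pH", "dDM", "dNDF", "dADF", "PF48", "tVFA", "CH4_pct")
VFA_COLUMNS = ("total_vfa",) + VFA_ACIDS


def gp_column(hour: float) -> str:
    return f"GP{hour:g}"


def convert_experiment(
    traces: Sequence[PressureTrace],
    metas: Sequence[BottleMeta],
    cfg: RunConfig,
) -> tuple[dict[str, GasCurve], GasCurve]:
    """Blank-correct and normalise every treatment bottle's trace.

    Returns per-bottle gas curves (mL STP per g DM) and the mean blank
    curve (absolute mL) used for the correction.
    """
    ctx = ConversionContext.from_config(cfg)
    meta_by_id = {m.bottle_id: m for m in metas}
    missing = [t.bottle_id for t in traces if t.bottle_id not in meta_by_id]
    if missing:
        raise DataError(f"traces without sample-sheet rows: {missing}")
    blanks = [
        trace_to_curve(t, meta_by_id[t.bottle_id], ctx)
        for t in traces
        if meta_by_id[t.bottle_id].is_blank
    ]
    if not blanks:
        raise DataError("no blank bottles found; cannot blank-correct")
    blank = blank_mean(blanks)
    curves = {}
    for t in traces:
        meta = meta_by_id[t.bottle_id]
        if meta.is_blank:
            continue
        curves[t.bottle_id] = trace_to_curve(t, meta, ctx, blank=blank)
    return curves, blank


def fit_kinetics_table(
    curves: dict[str, GasCurve],
    metas: Sequence[BottleMeta],
    cfg: RunConfig,
) -> pd.DataFrame:
    """Per-bottle kinetic fits: best family by AIC plus derived parameters."""
    meta_by_id = {m.bottle_id: m for m in metas}
    rows = []
    for bottle_id, curve in sorted(curves.items()):
        meta = meta_by_id[bottle_id]
        best = fit_bottle(curve.times_h, curve.values)
        derived = derive_kinetics(
            best, first_time_h=cfg.recording_interval_min / 60.0
        )
        gp = gp_at_hours(curve, cfg.fixed_hours)
        row = {
            "bottle_id": bottle_id,
            "treatment": meta.treatment,
            "dose_pct": meta.dose_pct,
            "incubation_id": meta.incubation_id,
            "family": best.family,
            "aic": best.aic,
            "A1": derived.A1_ml_per_g,
            "H1": derived.H1_h,
            "Vmax": derived.Vmax_ml_per_g_h,
            "Tmax": derived.Tmax_min,
        }
        for h, v in zip(cfg.fixed_hours, gp):
            row[gp_column(h)] = float(v)
        rows.append(row)
    return pd.DataFrame(rows)


def metrics_table(
    records: Sequence[FermentationRecord],
    curves: dict[str, GasCurve],
    metas: Sequence[BottleMeta],
    blank: GasCurve,
    ch4_correction: str = "volume_weighted",
) -> pd.DataFrame:
    """Per-bottle endpoint metrics with blank-corrected residues and CH4."""
    meta_by_id = {m.bottle_id: m for m in metas}
    rec_by_id = {r.bottle_id: r for r in records}
    blank_records = [
        r for r in records
        if r.bottle_id in meta_by_id and meta_by_id[r.bottle_id].is_blank
    ]
    blank_residue = (
        float(np.mean([r.residue_dm_mg for r in blank_records]))
        if blank_records else 0.0
    )
    blank_ch4 = (
        float(np.mean([r.ch4_fraction for r in blank_records]))
        if blank_records else None
    )
    blank_gas48 = float(blank.interpolate(np.array([48.0]))[0]) \
        if blank.times_h[-1] >= 48.0 else None

    rows = []
    for bottle_id, curve in sorted(curves.items()):
        meta = meta_by_id[bottle_id]
        rec = rec_by_id.get(bottle_id)
        if rec is None:
            logger.warning("bottle %s has no endpoint record; skipped", bottle_id)
            continue
        gp24, gp48 = gp_at_hours(curve, [24.0, 48.0])
        total_gas48 = (
            gp48 * meta.dm_mass_g + blank_gas48
            if blank_gas48 is not None else None
        )
        result = compute_metrics(
            rec,
            gp24_ml_per_g=float(gp24),
            gp48_ml_per_g=float(gp48),
            dm_mass_g=meta.dm_mass_g,
            blank_residue_dm_mg=blank_residue,
            ch4_blank_pct=blank_ch4,
            total_gas48_ml=total_gas48,
            blank_gas48_ml=blank_gas48,
            ch4_correction=ch4_correction,
        )
        row = {
            "bottle_id": bottle_id,
            "treatment": meta.treatment,
            "dose_pct": meta.dose_pct,
            "incubation_id": meta.incubation_id,
            "pH": result.ph,
            "dDM": result.dDM_pct,
            "dNDF": result.dNDF_pct,
            "dADF": result.dADF_pct,
            "PF48": result.pf48,
            "tVFA": result.tvfa_mmol,
            "CH4_pct": result.ch4_pct,
            "CH4_ml_per_g": result.ch4_ml_per_g,
            "total_vfa": result.total_vfa_mmol_per_l,
            "ap_ratio": result.ap_ratio if result.ap_ratio is not None else np.nan,
        }
        for a in VFA_ACIDS:
            row[a] = result.molar_pct[a]
        rows.append(row)
    return pd.DataFrame(rows)


def additives_in(per_bottle: pd.DataFrame) -> list[str]:
    return sorted(t for t in per_bottle["treatment"].unique() if t != "MS")


def additive_subset(per_bottle: pd.DataFrame, additive: str) -> pd.DataFrame:
    """One additive's dose series, with the dose-0 control attached."""
    mask = (per_bottle["treatment"] == additive) | (
        (per_bottle["treatment"] == "MS") & (per_bottle["dose_pct"] == 0)
    )
    return per_bottle.loc[mask]


def summary_table(
    per_bottle: pd.DataFrame,
    responses: Sequence[str],
    method: str = "auto",
) -> tuple[pd.DataFrame, dict[tuple[str, str], "object"]]:
    """Dose means + Linear/Quadratic/SEM rows per additive.

    Returns the printed-table DataFrame and the underlying
    DoseResponseResult per (additive, response).
    """
    tables = []
    results: dict[tuple[str, str], object] = {}
    for additive in additives_in(per_bottle):
        sub = additive_subset(per_bottle, additive)
        doses = sorted(sub["dose_pct"].unique())
        mean_rows = {d: {"additive": additive, "dose": f"{d:g}"} for d in doses}
        stat_rows = {
            label: {"additive": additive, "dose": label}
            for label in ("Linear", "Quadratic", "SEM")
        }
        for resp in responses:
            res = fit_dose_model(
                sub, response=resp, dose_col="dose_pct",
                incubation_col="incubation_id", method=method,
            )
            results[(additive, resp)] = res
            for d in doses:
                mean_rows[d][resp] = res.dose_means[float(d)]
            stat_rows["Linear"][resp] = res.p_linear
            stat_rows["Quadratic"][resp] = res.p_quadratic
            stat_rows["SEM"][resp] = res.sem
        tables.extend(mean_rows[d] for d in doses)
        tables.extend(stat_rows[label] for label in ("Linear", "Quadratic", "SEM"))
    return pd.DataFrame(tables), results


@dataclass
class PipelineResult:
    """All artifacts of one end-to-end run."""

    per_bottle_kinetics: pd.DataFrame
    per_bottle_metrics: pd.DataFrame
    kinetics_table: pd.DataFrame
    fermentation_table: pd.DataFrame
    vfa_table: pd.DataFrame
    trend_results: dict
    blank: GasCurve
    truth: Optional[pd.DataFrame] = None

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("per_bottle_kinetics", self.per_bottle_kinetics),
            ("per_bottle_metrics", self.per_bottle_metrics),
            ("kinetics_table", self.kinetics_table),
            ("fermentation_table", self.fermentation_table),
            ("vfa_table", self.vfa_table),
        ):
            paths[name] = directory / f"{name}.tsv"
            write_results_table(df, paths[name])
        return paths


def analyze_experiment(
    traces: Sequence[PressureTrace],
    metas: Sequence[BottleMeta],
    records: Sequence[FermentationRecord],
    cfg: RunConfig,
    method: str = "auto",
) -> PipelineResult:
    """Run convert → fit → metrics → trends on measured (or simulated) data."""
    curves, blank = convert_experiment(traces, metas, cfg)
    kin = fit_kinetics_table(curves, metas, cfg)
    met = metrics_table(records, curves, metas, blank)

    gp_cols = tuple(gp_column(h) for h in cfg.fixed_hours)
    kin_table, kin_res = summary_table(kin, KINETIC_COLUMNS + gp_cols, method)
    ferm_table, ferm_res = summary_table(met, FERMENTATION_COLUMNS, method)
    vfa_table, vfa_res = summary_table(met, VFA_COLUMNS, method)

    return PipelineResult(
        per_bottle_kinetics=kin,
        per_bottle_metrics=met,
        kinetics_table=kin_table,
        fermentation_table=ferm_table,
        vfa_table=vfa_table,
        trend_results={**kin_res, **ferm_res, **vfa_res},
        blank=blank,
    )


def dose_mean_coverage(result: PipelineResult, z: float = 2.0) -> tuple[float, int]:
    """Fraction of summary-table cells whose estimated dose mean lies
    within ``z`` pooled SEMs of the generator's realized truth.

    Truth per cell is the mean of the generator's per-bottle true values
    (treatment mean plus realized run effect); the comparison therefore
    measures estimation error, using the residual-based pooled SEM of the
    trend model.  Requires ``result.truth``.
    """
    if result.truth is None:
        raise DataError("pipeline result carries no ground truth")
    truth_mean = (
        result.truth.groupby(["treatment", "dose_pct", "response"])["true_value"]
        .mean()
    )
    ok = 0
    total = 0
    for (additive, resp), trend in result.trend_results.items():
        for dose, est in trend.dose_means.items():
            treatment = "MS" if dose == 0 else additive
            key = (treatment, dose, resp)
            if key not in truth_mean.index:
                continue
            tru = truth_mean.loc[key]
            total += 1
            ok += abs(est - tru) <= z * trend.sem
    return (ok / total if total else float("nan")), total


def run_pipeline(
    design: Optional[DesignSpec] = None,
    cfg: Optional[RunConfig] = None,
    seed: int = 0,
    method: str = "auto",
) -> PipelineResult:
    """Simulate a full experiment and analyze it."""
    design = design if design is not None else DesignSpec()
    experiment = generate_experiment(design, cfg=cfg, seed=seed)
    result = analyze_experiment(
        experiment.traces, experiment.metas, experiment.records,
        experiment.cfg, method=method,
    )
    result.truth = experiment.truth
    return result
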