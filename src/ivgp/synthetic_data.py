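"""Synthetic in-vitro fermentation experiments with known ground truth.

The generator inverts the analyzer's conversion chain: it draws per-bottle
gas curves from known kinetics, converts them to the cumulative-pressure
traces an automated headspace sensor would log, and draws endpoint
measurements (residues, pH, methane fraction, VFA concentrations) from a
means-plus-random-effects model

    Y_ijk = mu_i + R_j + E_ijk

with treatment mean mu_i, a run (incubation) effect R_j shared by every
bottle fermented with the same day's inoculum, and iid Gaussian residual
E_ijk.  The run effect enters gas kinetics multiplicatively on the
asymptote (scale factor 1 + e_j, keeping curves positive) and additively
on endpoint responses.

Default conditions emulate a dose-titration study of three tannin-rich
fruit additives (BA, HA, TC) in a maize-silage (MS) basal substrate:
500 mg samples, doses 0/20/40/100 % of DM, two incubation runs with
quadruplicate bottles plus inoculum-only blanks, 48-h horizon recorded
every 10 min.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .formats_io import (
    BLANK_CODE,
    BottleMeta,
    RunConfig,
    VFA_ACIDS,
    write_endpoints,
    write_pressure_log,
    write_sample_sheet,
)
from .fermentation_metrics import FermentationRecord
from .gas_conversion import ConversionContext, GasCurve, PressureTrace, ml_stp_to_psi
from .kinetics import EXPONENTIAL, GROOT, groot_curve, groot_rate, exponential_curve


@dataclass(frozen=True)
class TrueKinetics:
    """Ground-truth gas-curve parameters for one treatment.

    Either the sigmoidal family (A asymptote mL/g, B half-time h, C shape)
    or the exponential family (b asymptote mL/g, c fractional rate /h).
    """

    family: str = GROOT
    A_ml_per_g: float = 0.0
    B_h: float = 0.0
    C_shape: float = 0.0
    b_ml_per_g: float = 0.0
    c_per_h: float = 0.0

    def __post_init__(self) -> None:
        if self.family == GROOT:
            if not (self.A_ml_per_g > 0 and self.B_h > 0 and self.C_shape > 0):
                raise ValidationError("sigmoidal truth requires A, B, C > 0")
        elif self.family == EXPONENTIAL:
            if not (self.b_ml_per_g > 0 and self.c_per_h > 0):
                raise ValidationError("exponential truth requires b, c > 0")
        else:
            raise ValidationError(f"unknown kinetic family {self.family!r}")

    def mean(self, t) -> np.ndarray:
        if self.family == GROOT:
            return groot_curve(t, self.A_ml_per_g, self.B_h, self.C_shape)
        return exponential_curve(t, self.b_ml_per_g, self.c_per_h)

    def rate(self, t) -> np.ndarray:
        if self.family == GROOT:
            return groot_rate(t, self.A_ml_per_g, self.B_h, self.C_shape)
        return self.b_ml_per_g * self.c_per_h * np.exp(-self.c_per_h * np.asarray(t, float))

    def scaled(self, factor: float) -> "TrueKinetics":
        """Asymptote scaled by ``factor`` (run effect), shape unchanged."""
        if self.family == GROOT:
            return TrueKinetics(GROOT, self.A_ml_per_g * factor, self.B_h, self.C_shape)
        return TrueKinetics(EXPONENTIAL, b_ml_per_g=self.b_ml_per_g * factor,
                            c_per_h=self.c_per_h)


@dataclass(frozen=True)
class TreatmentTruth:
    """Ground-truth kinetics plus endpoint means for one treatment × dose."""

    kinetics: TrueKinetics
    ph: float
    ddm_pct: float
    dndf_pct: float
    dadf_pct: float
    ch4_pct: float          # net methane, % of net (blank-corrected) gas
    total_vfa_mmol_per_l: float
    molar_pct: Mapping[str, float]
    dm_fraction: float
    ndf_frac_of_dm: float
    adf_frac_of_dm: float

    def normalized_molar(self) -> dict[str, float]:
        total = sum(self.molar_pct.values())
        return {a: 100.0 * v / total for a, v in self.molar_pct.items()}


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

# Substrate composition (fractions of DM) of the pure ingredients: maize
# silage and the three fruit additives.  Mixtures are dose-weighted blends.
_COMPOSITION = {
    # ingredient: (dm_fraction, ndf_frac_of_dm, adf_frac_of_dm)
    "MS": (0.931, 0.442, 0.241),
    "BA": (0.927, 0.915, 0.037),
    "HA": (0.928, 0.773, 0.068),
    "TC": (0.949, 0.806, 0.081),
}


def _blend(treatment: str, dose_pct: float) -> tuple[float, float, float]:
    w = dose_pct / 100.0
    ms = np.array(_COMPOSITION["MS"])
    add = np.array(_COMPOSITION[treatment if treatment != "MS" else "MS"])
    return tuple((1 - w) * ms + w * add)


def _truth(treatment, dose, A, B, C, ph, ddm, dndf, dadf, ch4, tvfa_total, molar):
    dmf, ndf, adf = _blend(treatment, dose)
    return TreatmentTruth(
        kinetics=TrueKinetics(GROOT, A, B, C),
        ph=ph, ddm_pct=ddm, dndf_pct=dndf, dadf_pct=dadf, ch4_pct=ch4,
        total_vfa_mmol_per_l=tvfa_total,
        molar_pct=dict(zip(VFA_ACIDS, molar)),
        dm_fraction=dmf, ndf_frac_of_dm=ndf, adf_frac_of_dm=adf,
    )


#: Per-treatment ground truth used by default.  Kinetic asymptotes and
#: half-times span the range typical of maize-silage substrates diluted
#: with poorly fermentable tannin-rich fruit; shape parameters place the
#: inflection between ~1 and ~12 h.  Endpoint means describe the same
#: gradient: gas and methane fall and fermentation efficiency rises with
#: increasing additive dose.
DEFAULT_TRUTH: dict[tuple[str, float], TreatmentTruth] = {
    ("MS", 0.0): _truth("MS", 0, 194.89, 16.92, 2.59, 6.94, 76.2, 36.7, 32.1,
                        8.15, 66.7, (42.1, 24.0, 2.21, 22.4, 4.67, 2.85, 1.69)),
    ("BA", 20.0): _truth("BA", 20, 185.74, 15.77, 2.45, 6.83, 69.8, 41.2, 44.6,
                         10.05, 63.6, (39.1, 25.1, 1.78, 25.1, 3.68, 2.85, 2.27)),
    ("BA", 40.0): _truth("BA", 40, 172.12, 15.38, 2.04, 6.84, 65.8, 39.2, 47.1,
                         8.03, 63.1, (42.0, 24.0, 1.75, 24.3, 3.61, 2.98, 1.84)),
    ("BA", 100.0): _truth("BA", 100, 116.28, 8.50, 2.37, 6.90, 69.3, 24.5, 40.0,
                          4.31, 61.9, (42.1, 25.5, 1.83, 21.8, 3.53, 2.80, 2.12)),
    ("HA", 20.0): _truth("HA", 20, 176.35, 16.12, 2.02, 6.84, 69.1, 43.6, 35.0,
                         8.78, 68.3, (42.7, 26.4, 1.74, 21.1, 3.56, 2.95, 1.44)),
    ("HA", 40.0): _truth("HA", 40, 156.10, 15.81, 1.92, 6.85, 69.5, 36.7, 24.6,
                         7.83, 61.9, (42.9, 24.4, 1.86, 22.4, 3.86, 3.00, 1.56)),
    ("HA", 100.0): _truth("HA", 100, 71.92, 4.52, 1.27, 6.69, 84.1, 13.7, 9.8,
                          1.76, 46.9, (46.5, 19.5, 2.04, 24.8, 4.00, 2.40, 0.75)),
    ("TC", 20.0): _truth("TC", 20, 196.89, 15.77, 2.32, 6.85, 72.5, 40.8, 31.9,
                         9.11, 67.2, (40.9, 24.5, 1.85, 24.4, 3.90, 2.86, 1.66)),
    ("TC", 40.0): _truth("TC", 40, 177.37, 14.97, 2.04, 6.84, 70.6, 36.2, 23.9,
                         8.03, 67.9, (42.0, 23.9, 1.67, 24.6, 3.47, 2.72, 1.57)),
    ("TC", 100.0): _truth("TC", 100, 127.53, 9.28, 1.25, 6.90, 79.2, 20.7, 13.9,
                          4.58, 58.6, (50.0, 20.2, 1.73, 20.6, 3.32, 2.82, 1.23)),
}

#: Residual (between-bottle, within-run) SDs for endpoint responses, sized
#: so that pooled SEMs over 8 replicate bottles land in the range typical
#: of replicated batch-culture studies.
ENDPOINT_NOISE_SD: dict[str, float] = {
    "ph": 0.20,
    "ddm_pct": 1.5,
    "dndf_pct": 4.0,
    "dadf_pct": 6.0,
    "ch4_pct": 3.0,
    "total_vfa_mmol_per_l": 8.0,
    "acetic": 4.5,
    "propionic": 2.5,
    "iso_butyric": 0.5,
    "butyric": 4.0,
    "isovaleric": 1.2,
    "valeric": 0.7,
    "caproic": 0.6,
}

DEFAULT_TREATMENTS: tuple[tuple[str, tuple[float, ...]], ...] = (
    ("MS", (0.0,)),
    ("BA", (20.0, 40.0, 100.0)),
    ("HA", (20.0, 40.0, 100.0)),
    ("TC", (20.0, 40.0, 100.0)),
)


@dataclass(frozen=True)
class DesignSpec:
    """Structure and noise levels of a simulated experiment."""

    treatments: tuple[tuple[str, tuple[float, ...]], ...] = DEFAULT_TREATMENTS
    reps_per_incubation: int = 4
    n_incubations: int = 2
    n_blanks: int = 4                      # blanks per incubation
    noise_sd_ml_per_g: float = 5.0         # iid noise on cumulative gas
    incubation_sd: float = 0.02            # relative SD of the run effect
    dose_effects: Optional[Mapping[str, tuple[float, float]]] = None
    blank_gas_ml: float = 8.0              # mean blank asymptote, absolute mL
    blank_noise_ml: float = 1.0
    blank_residue_mg: float = 5.0
    blank_ch4_pct: float = 6.0
    sample_mass_mg: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.reps_per_incubation, self.n_incubations, self.n_blanks) < 1:
            raise ConfigError("replicate, incubation and blank counts must be >= 1")
        for name in ("noise_sd_ml_per_g", "incubation_sd", "blank_noise_ml"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


#: Kinetic shape of blank (inoculum-only) gas evolution: a slow sigmoid
#: reaching ``blank_gas_ml`` mL.
_BLANK_B_H = 12.0
_BLANK_C = 1.3


def default_run_config(headspace_ml: float = 110.0) -> RunConfig:
    """Configuration used for simulated bottles.

    110 mL headspace corresponds to a nominal 100 mL bottle (90 mL
    inoculum) plus ~100 mL of bottle overcapacity and sensor-module volume.
    """
    return RunConfig(headspace_ml=headspace_ml)


# ---------------------------------------------------------------------------
# Elementary simulators
# ---------------------------------------------------------------------------

def simulate_gas_curve(
    truth: TrueKinetics,
    grid_h: Sequence[float],
    noise_sd: float,
    seed: int | np.random.Generator = 0,
    bottle_id: str = "sim",
) -> GasCurve:
    """Model mean plus iid Gaussian noise on a strictly increasing grid."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = np.asarray(grid_h, dtype=float)
    if grid.size and (grid[0] < 0 or np.any(np.diff(grid) <= 0)):
        raise ValueError("time grid must start >= 0 and strictly increase")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = truth.mean(grid)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=grid.shape)
    return GasCurve(bottle_id, grid, values, per_g=True, blank_corrected=True)


def blank_gas_profile(grid_h, blank_gas_ml: float) -> np.ndarray:
    """Absolute mL of inoculum-only gas at each grid time."""
    return groot_curve(np.asarray(grid_h, float), blank_gas_ml, _BLANK_B_H, _BLANK_C)


def curve_to_pressure_trace(
    curve: GasCurve,
    meta: BottleMeta,
    cfg: RunConfig,
    blank_ml: Optional[np.ndarray] = None,
) -> PressureTrace:
    """Invert the analyzer's conversion: gas curve → cumulative PSI trace.

    For treatment bottles the per-g curve is scaled by DM mass and the
    blank gas profile is added on top, so that downstream blank correction
    is exercised; blank bottles pass their absolute volumes straight
    through.
    """
    ctx = ConversionContext.from_config(cfg)
    if curve.per_g:
        if not meta.dm_mass_g > 0:
            raise ValidationError(
                f"bottle {meta.bottle_id!r}: per-g curve needs positive DM mass"
            )
        abs_ml = curve.values * meta.dm_mass_g
    else:
        abs_ml = curve.values.copy()
    if blank_ml is not None:
        abs_ml = abs_ml + np.asarray(blank_ml, dtype=float)
    return PressureTrace(
        bottle_id=meta.bottle_id,
        times_min=curve.times_h * 60.0,
        cum_psi=ml_stp_to_psi(abs_ml, ctx),
        temp_c=cfg.incubation_temp_c,
    )


def simulate_response_table(
    doses: Sequence[float],
    mu: float,
    linear: float = 0.0,
    quadratic: float = 0.0,
    incubation_sd: float = 0.0,
    resid_sd: float = 1.0,
    reps_per_incubation: int = 4,
    n_incubations: int = 2,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Directly simulate one response under the means + run-effect model.

    The mean at dose d is mu + linear·d + quadratic·d²; every bottle in
    incubation j shares the same N(0, incubation_sd²) shift.  Used for
    trend-test calibration and power studies without the full gas chain.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inc_effects = rng.normal(0.0, incubation_sd, size=n_incubations)
    rows = []
    for j in range(n_incubations):
        for d in doses:
            mean = mu + linear * d + quadratic * d**2
            vals = mean + inc_effects[j] + rng.normal(0.0, resid_sd, reps_per_incubation)
            for r, v in enumerate(vals, start=1):
                rows.append(
                    {"dose": float(d), "incubation": f"I{j + 1}",
                     "replicate": r, "value": float(v)}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full experiment generator
# ---------------------------------------------------------------------------

#: Table responses carried in the ground-truth ledger.
KINETIC_RESPONSES = ("A1", "H1", "Vmax", "Tmax", "GP6", "GP9", "GP12", "GP24", "GP48")
ENDPOINT_RESPONSES = ("pH", "dDM", "dNDF", "dADF", "PF48", "tVFA", "CH4_pct",
                      "total_vfa") + VFA_ACIDS


@dataclass
class SimulatedExperiment:
    """Everything a wet-lab run would deliver, plus the generating truth."""

    metas: list[BottleMeta]
    traces: list[PressureTrace]
    records: list[FermentationRecord]
    truth: pd.DataFrame
    design: DesignSpec
    cfg: RunConfig

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "pressure_log": directory / "pressure_log.csv",
            "sample_sheet": directory / "sample_sheet.csv",
            "endpoints": directory / "endpoints.csv",
            "truth": directory / "truth.csv",
            "config": directory / "run_config.yaml",
        }
        write_pressure_log(self.traces, paths["pressure_log"])
        write_sample_sheet(self.metas, paths["sample_sheet"])
        write_endpoints(self.records, paths["endpoints"])
        self.truth.to_csv(paths["truth"], index=False)
        self.cfg.to_yaml(paths["config"])
        return paths


def _derived_truth(kin: TrueKinetics, hours: Sequence[float]) -> dict[str, float]:
    """True A1/H1/Vmax/Tmax and fixed-hour GP of a noiseless curve."""
    out: dict[str, float] = {}
    if kin.family == GROOT:
        A, B, C = kin.A_ml_per_g, kin.B_h, kin.C_shape
        out["A1"], out["H1"] = A, B
        if C > 1:
            tmax_h = B * ((C - 1.0) / (C + 1.0)) ** (1.0 / C)
            out["Tmax"] = tmax_h * 60.0
            out["Vmax"] = float(kin.rate(tmax_h))
        else:
            out["Tmax"] = 0.0
            out["Vmax"] = float(kin.rate(1.0 / 6.0))
    else:
        out["A1"] = kin.b_ml_per_g
        out["H1"] = float(np.log(2.0) / kin.c_per_h)
        out["Tmax"] = 0.0
        out["Vmax"] = kin.b_ml_per_g * kin.c_per_h
    for h in hours:
        out[f"GP{h:g}"] = float(kin.mean(h))
    return out


def generate_experiment(
    design: DesignSpec = DesignSpec(),
    truth_table: Optional[Mapping[tuple[str, float], TreatmentTruth]] = None,
    cfg: Optional[RunConfig] = None,
    seed: Optional[int] = None,
) -> SimulatedExperiment:
    """Generate a complete synthetic experiment.

    All randomness flows from a single generator seeded by ``seed`` (or
    ``design.seed``); fixing the seed fixes every emitted value, changing
    it changes noise realizations but never the design structure.
    """
    truth_table = dict(truth_table) if truth_table is not None else dict(DEFAULT_TRUTH)
    cfg = cfg if cfg is not None else default_run_config()
    rng = np.random.default_rng(design.seed if seed is None else seed)

    cells = [(t, d) for t, doses in design.treatments for d in doses]
    missing = [c for c in cells if c not in truth_table]
    if missing:
        raise ConfigError(f"truth_table lacks treatments {missing}")

    grid_h = np.arange(
        0.0, cfg.horizon_h + 1e-9, cfg.recording_interval_min / 60.0
    )
    blank_profile = blank_gas_profile(grid_h, design.blank_gas_ml)
    hours = cfg.fixed_hours

    # run effects: one multiplicative kinetic factor per incubation, one
    # additive shift per (incubation, endpoint response)
    inc_ids = [f"I{j + 1}" for j in range(design.n_incubations)]
    kin_factor = 1.0 + rng.normal(0.0, design.incubation_sd, design.n_incubations)
    endpoint_names = list(ENDPOINT_NOISE_SD)
    grand_mean = {
        name: float(np.mean([_endpoint_mean(truth_table[c], name) for c in cells]))
        for name in endpoint_names
    }
    inc_shift = {
        (inc, name): design.incubation_sd * grand_mean[name] * z
        for (inc, name), z in zip(
            ((i, n) for i in inc_ids for n in endpoint_names),
            rng.normal(0.0, 1.0, design.n_incubations * len(endpoint_names)),
        )
    }

    metas: list[BottleMeta] = []
    traces: list[PressureTrace] = []
    records: list[FermentationRecord] = []
    truth_rows: list[dict] = []

    for j, inc in enumerate(inc_ids):
        for treatment, dose in cells:
            tt = _apply_dose_effects(truth_table[(treatment, dose)], dose,
                                     design.dose_effects)
            kin_j = tt.kinetics.scaled(kin_factor[j])
            derived = _derived_truth(kin_j, hours)
            for r in range(1, design.reps_per_incubation + 1):
                bottle_id = f"{inc}_{treatment}{dose:g}_r{r}"
                meta = BottleMeta(
                    bottle_id=bottle_id,
                    treatment=treatment,
                    dose_pct=dose,
                    incubation_id=inc,
                    sample_mass_mg=design.sample_mass_mg,
                    dm_fraction=tt.dm_fraction,
                )
                curve = simulate_gas_curve(
                    kin_j, grid_h, design.noise_sd_ml_per_g, rng, bottle_id
                )
                traces.append(
                    curve_to_pressure_trace(curve, meta, cfg, blank_ml=blank_profile)
                )
                metas.append(meta)
                rec, bottle_truth = _draw_endpoints(
                    tt, kin_j, meta, inc, cfg, design, inc_shift, rng
                )
                records.append(rec)
                truth_rows.extend(
                    {
                        "bottle_id": bottle_id,
                        "treatment": treatment,
                        "dose_pct": dose,
                        "incubation_id": inc,
                        "response": resp,
                        "true_value": val,
                    }
                    for resp, val in {**derived, **bottle_truth}.items()
                )
        for r in range(1, design.n_blanks + 1):
            bottle_id = f"{inc}_{BLANK_CODE}_r{r}"
            meta = BottleMeta(
                bottle_id=bottle_id, treatment=BLANK_CODE, dose_pct=0.0,
                incubation_id=inc, sample_mass_mg=0.0, dm_fraction=1.0,
                is_blank=True,
            )
            metas.append(meta)
            abs_ml = blank_profile.copy()
            if design.blank_noise_ml > 0:
                abs_ml = abs_ml + rng.normal(0.0, design.blank_noise_ml, grid_h.shape)
            blank_curve = GasCurve(bottle_id, grid_h, abs_ml, per_g=False)
            traces.append(curve_to_pressure_trace(blank_curve, meta, cfg))
            records.append(
                FermentationRecord(
                    bottle_id=bottle_id,
                    initial_dm_mg=0.0,
                    residue_dm_mg=max(
                        0.0, design.blank_residue_mg + rng.normal(0.0, 1.0)
                    ),
                    initial_ndf_mg=0.0, residue_ndf_mg=0.0,
                    initial_adf_mg=0.0, residue_adf_mg=0.0,
                    ph=6.9 + rng.normal(0.0, 0.05),
                    ch4_fraction=max(
                        0.0, design.blank_ch4_pct + rng.normal(0.0, 0.5)
                    ),
                    vfa_mmol_per_l={a: 0.0 for a in VFA_ACIDS},
                )
            )

    truth = pd.DataFrame(truth_rows)
    return SimulatedExperiment(metas, traces, records, truth, design, cfg)


def _endpoint_mean(tt: TreatmentTruth, name: str) -> float:
    if name in VFA_ACIDS:
        return tt.normalized_molar()[name]
    return getattr(tt, name)


def _apply_dose_effects(tt, dose, dose_effects):
    """Override treatment means with parametric dose trends when requested."""
    if not dose_effects:
        return tt
    from dataclasses import replace

    updates = {}
    for resp, (lin, quad) in dose_effects.items():
        base_key = resp if resp in ENDPOINT_NOISE_SD else None
        if base_key is None:
            raise ConfigError(f"dose_effects: unknown endpoint response {resp!r}")
        base = getattr(DEFAULT_TRUTH[("MS", 0.0)], base_key) if base_key not in VFA_ACIDS \
            else DEFAULT_TRUTH[("MS", 0.0)].normalized_molar()[base_key]
        updates[base_key] = base + lin * dose + quad * dose**2
    molar = dict(tt.molar_pct)
    plain = {k: v for k, v in updates.items() if k not in VFA_ACIDS}
    for k, v in updates.items():
        if k in VFA_ACIDS:
            molar[k] = v
    return replace(tt, molar_pct=molar, **plain)


def _draw_endpoints(tt, kin_j, meta, inc, cfg, design, inc_shift, rng):
    """One bottle's endpoint record plus its per-bottle truth values.

    Truth is everything except iid residual noise, i.e. the treatment mean
    plus the realized run effect — the quantity an unbiased analyzer
    should recover as noise averages out.
    """
    sd = ENDPOINT_NOISE_SD
    dm_g = meta.dm_mass_g
    initial_dm = meta.sample_mass_mg * tt.dm_fraction
    initial_ndf = initial_dm * tt.ndf_frac_of_dm
    initial_adf = initial_dm * tt.adf_frac_of_dm

    def shifted(name):
        return _endpoint_mean(tt, name) + inc_shift[(inc, name)]

    ddm = shifted("ddm_pct")
    dndf = shifted("dndf_pct")
    dadf = shifted("dadf_pct")
    ph_true = shifted("ph")
    ch4_true = shifted("ch4_pct")
    tvfa_total_true = shifted("total_vfa_mmol_per_l")

    ddm_obs = ddm + rng.normal(0.0, sd["ddm_pct"])
    dndf_obs = dndf + rng.normal(0.0, sd["dndf_pct"])
    dadf_obs = dadf + rng.normal(0.0, sd["dadf_pct"])

    residue_dm = initial_dm * (1.0 - ddm_obs / 100.0) + design.blank_residue_mg
    residue_ndf = max(0.0, initial_ndf * (1.0 - dndf_obs / 100.0))
    residue_adf = max(0.0, initial_adf * (1.0 - dadf_obs / 100.0))

    # methane: the sensor bag mixes net (substrate) and blank (inoculum)
    # gas, so the measured concentration is the volume-weighted blend
    net_gas48 = float(kin_j.mean(48.0)) * dm_g
    blank_gas48 = float(blank_gas_profile(48.0, design.blank_gas_ml))
    total48 = net_gas48 + blank_gas48
    ch4_measured = (
        ch4_true * net_gas48 + design.blank_ch4_pct * blank_gas48
    ) / total48
    ch4_obs = float(np.clip(ch4_measured + rng.normal(0.0, sd["ch4_pct"] / 2.0),
                            0.0, 100.0))

    total_obs = max(1.0, tvfa_total_true
                    + rng.normal(0.0, sd["total_vfa_mmol_per_l"]))
    molar_true = {a: _endpoint_mean(tt, a) + inc_shift[(inc, a)] for a in VFA_ACIDS}
    molar_obs = np.array(
        [max(0.01, molar_true[a] + rng.normal(0.0, sd[a])) for a in VFA_ACIDS]
    )
    molar_obs = 100.0 * molar_obs / molar_obs.sum()
    conc = {a: total_obs * m / 100.0 for a, m in zip(VFA_ACIDS, molar_obs)}

    rec = FermentationRecord(
        bottle_id=meta.bottle_id,
        initial_dm_mg=initial_dm,
        residue_dm_mg=residue_dm,
        initial_ndf_mg=initial_ndf,
        residue_ndf_mg=residue_ndf,
        initial_adf_mg=initial_adf,
        residue_adf_mg=residue_adf,
        ph=ph_true + rng.normal(0.0, sd["ph"]),
        ch4_fraction=ch4_obs,
        vfa_mmol_per_l=conc,
    )

    degraded_true_mg = initial_dm * ddm / 100.0
    gas48_true_ml = float(kin_j.mean(48.0)) * dm_g
    gp24_true_per_g = float(kin_j.mean(24.0))
    bottle_truth = {
        "pH": ph_true,
        "dDM": ddm,
        "dNDF": dndf,
        "dADF": dadf,
        "PF48": degraded_true_mg / gas48_true_ml,
        "tVFA": 0.0222 * (gp24_true_per_g / 5.0) - 0.00425,
        "CH4_pct": ch4_true,
        "total_vfa": tvfa_total_true,
        **molar_true,
    }
    return rec, bottle_truth
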