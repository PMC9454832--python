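"""Tabular file dialects and run configuration.

All on-disk inputs are comma-separated UTF-8 text with a mandatory header
row and "." as the decimal mark.  Result tables are written tab-separated
at fixed precision so that repeated runs produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Additive treatment codes.  ``MS`` is the maize-silage control (dose 0);
#: the three fruit additives are titrated at 20/40/100 % of sample DM.
TREATMENTS = ("MS", "BA", "HA", "TC")

#: Code used on sample sheets for inoculum-only blank bottles.
BLANK_CODE = "BL"

ALLOWED_DOSES = (0.0, 20.0, 40.0, 100.0)

#: Volatile fatty acids reported in the molar profile, in table order.
VFA_ACIDS = (
    "acetic",
    "propionic",
    "iso_butyric",
    "butyric",
    "isovaleric",
    "valeric",
    "caproic",
)


@dataclass(frozen=True)
class BottleMeta:
    """Identity and loading of one fermentation bottle.

    ``sample_mass_mg`` is the as-fed mass weighed into the bottle;
    multiplying by ``dm_fraction`` gives the dry-matter mass that gas
    volumes are normalised by.  Blank bottles carry inoculum only and may
    omit the mass fields.
    """

    bottle_id: str
    treatment: str
    dose_pct: float
    incubation_id: str
    sample_mass_mg: float
    dm_fraction: float
    is_blank: bool = False

    def __post_init__(self) -> None:
        if self.is_blank:
            return
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"bottle {self.bottle_id!r}: unknown treatment code "
                f"{self.treatment!r}; expected one of {TREATMENTS}"
            )
        if self.dose_pct not in ALLOWED_DOSES:
            raise ValidationError(
                f"bottle {self.bottle_id!r}: dose {self.dose_pct} not in "
                f"{ALLOWED_DOSES}"
            )
        if not self.sample_mass_mg > 0:
            raise ValidationError(
                f"bottle {self.bottle_id!r}: sample_mass_mg must be > 0"
            )
        if not 0 < self.dm_fraction <= 1:
            raise ValidationError(
                f"bottle {self.bottle_id!r}: dm_fraction must lie in (0, 1]"
            )

    @property
    def dm_mass_g(self) -> float:
        """Dry-matter mass in grams (0 for blanks without a sample)."""
        if self.is_blank and not self.sample_mass_mg:
            return 0.0
        return self.sample_mass_mg * self.dm_fraction / 1000.0


@dataclass(frozen=True)
class RunConfig:
    """Physical and reporting configuration of one incubation run.

    ``headspace_ml`` is the gas headspace volume of a closed bottle (the V
    in PV = nRT) and has no default: it depends on the actual bottle
    overcapacity plus the sensor module's internal volume, so it must be
    stated explicitly rather than silently assumed.

    The incubation temperature defaults to 39.5 °C (rumen temperature as
    used in the pressure-to-volume conversion); standard temperature and
    pressure default to the strict thermodynamic convention 273.15 K and
    101.325 kPa and are configurable.
    """

    headspace_ml: float
    incubation_temp_c: float = 39.5
    stp_temp_k: float = 273.15
    stp_pressure_kpa: float = 101.325
    recording_interval_min: float = 10.0
    horizon_h: float = 48.0
    fixed_hours: tuple[float, ...] = (6.0, 9.0, 12.0, 24.0, 48.0)

    def __post_init__(self) -> None:
        for name in ("headspace_ml", "stp_temp_k", "stp_pressure_kpa",
                     "recording_interval_min", "horizon_h"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.incubation_temp_c <= -273.15:
            raise ConfigError("incubation_temp_c below absolute zero")
        bad = [h for h in self.fixed_hours if not 0 <= h <= self.horizon_h]
        if bad:
            raise ConfigError(
                f"fixed_hours {bad} fall outside [0, {self.horizon_h}]"
            )
        object.__setattr__(self, "fixed_hours", tuple(float(h) for h in self.fixed_hours))

    @property
    def incubation_temp_k(self) -> float:
        return self.incubation_temp_c + 273.15

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "headspace_ml" not in raw:
            raise ConfigError(
                f"{path}: headspace_ml is required and has no default"
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "fixed_hours" in raw:
            raw["fixed_hours"] = tuple(raw["fixed_hours"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "headspace_ml": self.headspace_ml,
            "incubation_temp_c": self.incubation_temp_c,
            "stp_temp_k": self.stp_temp_k,
            "stp_pressure_kpa": self.stp_pressure_kpa,
            "recording_interval_min": self.recording_interval_min,
            "horizon_h": self.horizon_h,
            "fixed_hours": list(self.fixed_hours),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# pressure logs
# ---------------------------------------------------------------------------

PRESSURE_COLUMNS = ("bottle_id", "time_min", "cum_pressure_psi")


def read_pressure_log(path: str | Path):
    """Read a cumulative-pressure log into one trace per bottle.

    Returns a list of :class:`~ivgp.gas_conversion.PressureTrace`, each with
    rows sorted by time.  Duplicate (bottle, time) rows are a data error;
    an empty data section yields an empty list with a warning.
    """
    from .gas_conversion import PressureTrace

    df = _read_csv(path, PRESSURE_COLUMNS)
    if df.empty:
        logger.warning("pressure log %s has an empty data section", path)
        return []
    dupes = df.duplicated(subset=["bottle_id", "time_min"])
    if dupes.any():
        first = df.loc[dupes.idxmax()]
        raise DataError(
            f"{path}: duplicate time {first['time_min']} for bottle "
            f"{first['bottle_id']!r}"
        )
    traces = []
    for bottle_id, grp in df.groupby("bottle_id", sort=True):
        grp = grp.sort_values("time_min")
        traces.append(
            PressureTrace(
                bottle_id=str(bottle_id),
                times_min=grp["time_min"].to_numpy(dtype=float),
                cum_psi=grp["cum_pressure_psi"].to_numpy(dtype=float),
            )
        )
    return traces


def write_pressure_log(traces, path: str | Path) -> None:
    """Write traces back to the CSV dialect ``read_pressure_log`` accepts."""
    frames = [
        pd.DataFrame(
            {
                "bottle_id": tr.bottle_id,
                "time_min": tr.times_min,
                "cum_pressure_psi": tr.cum_psi,
            }
        )
        for tr in traces
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(PRESSURE_COLUMNS))
    )
    out.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = (
    "bottle_id",
    "treatment",
    "dose_pct",
    "incubation_id",
    "sample_mass_mg",
    "dm_fraction",
    "is_blank",
)


def read_sample_sheet(path: str | Path) -> list[BottleMeta]:
    """Read and validate bottle metadata.

    Blank rows (``is_blank`` truthy or treatment ``BL``) may leave the mass
    fields empty; every other row must satisfy the BottleMeta invariants.
    """
    df = _read_csv(path, SAMPLE_COLUMNS)
    metas = []
    for _, row in df.iterrows():
        is_blank = _as_bool(row["is_blank"]) or str(row["treatment"]) == BLANK_CODE
        mass = row["sample_mass_mg"]
        dmf = row["dm_fraction"]
        metas.append(
            BottleMeta(
                bottle_id=str(row["bottle_id"]),
                treatment=str(row["treatment"]),
                dose_pct=float(row["dose_pct"]) if pd.notna(row["dose_pct"]) else 0.0,
                incubation_id=str(row["incubation_id"]),
                sample_mass_mg=float(mass) if pd.notna(mass) else 0.0,
                dm_fraction=float(dmf) if pd.notna(dmf) else 1.0,
                is_blank=is_blank,
            )
        )
    return metas


def write_sample_sheet(metas: Iterable[BottleMeta], path: str | Path) -> None:
    rows = [
        {
            "bottle_id": m.bottle_id,
            "treatment": m.treatment,
            "dose_pct": m.dose_pct,
            "incubation_id": m.incubation_id,
            "sample_mass_mg": m.sample_mass_mg,
            "dm_fraction": m.dm_fraction,
            "is_blank": m.is_blank,
        }
        for m in metas
    ]
    pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# endpoint measurements
# ---------------------------------------------------------------------------

ENDPOINT_COLUMNS = (
    "bottle_id",
    "initial_dm_mg",
    "residue_dm_mg",
    "initial_ndf_mg",
    "residue_ndf_mg",
    "initial_adf_mg",
    "residue_adf_mg",
    "ph",
    "ch4_pct",
) + tuple(f"vfa_{a}" for a in VFA_ACIDS)


def read_endpoints(path: str | Path):
    """Read post-fermentation measurements into FermentationRecords."""
    from .fermentation_metrics import FermentationRecord

    df = _read_csv(path, ENDPOINT_COLUMNS)
    records = []
    for _, row in df.iterrows():
        records.append(
            FermentationRecord(
                bottle_id=str(row["bottle_id"]),
                initial_dm_mg=float(row["initial_dm_mg"]),
                residue_dm_mg=float(row["residue_dm_mg"]),
                initial_ndf_mg=float(row["initial_ndf_mg"]),
                residue_ndf_mg=float(row["residue_ndf_mg"]),
                initial_adf_mg=float(row["initial_adf_mg"]),
                residue_adf_mg=float(row["residue_adf_mg"]),
                ph=float(row["ph"]),
                ch4_fraction=float(row["ch4_pct"]),
                vfa_mmol_per_l={a: float(row[f"vfa_{a}"]) for a in VFA_ACIDS},
            )
        )
    return records


def write_endpoints(records, path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "bottle_id": r.bottle_id,
            "initial_dm_mg": r.initial_dm_mg,
            "residue_dm_mg": r.residue_dm_mg,
            "initial_ndf_mg": r.initial_ndf_mg,
            "residue_ndf_mg": r.residue_ndf_mg,
            "initial_adf_mg": r.initial_adf_mg,
            "residue_adf_mg": r.residue_adf_mg,
            "ph": r.ph,
            "ch4_pct": r.ch4_fraction,
        }
        for a in VFA_ACIDS:
            row[f"vfa_{a}"] = r.vfa_mmol_per_l.get(a, 0.0)
        rows.append(row)
    pd.DataFrame(rows, columns=list(ENDPOINT_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results_table(rows: pd.DataFrame | Sequence[dict], path: str | Path,
                        precision: int = 4) -> None:
    """Write a homogeneous result table as TSV at fixed precision.

    Rows are sorted by (treatment, dose) when those columns are present, so
    repeated runs on identical input produce byte-identical files.
    """
    df = pd.DataFrame(rows)
    sort_cols = [c for c in ("treatment", "dose_pct", "dose", "response", "bottle_id")
                 if c in df.columns]
    if sort_cols and not df.empty:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{precision}f")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gas-curve tables (intermediate pipeline artifact)
# ---------------------------------------------------------------------------

CURVE_COLUMNS = ("bottle_id", "time_h", "gas_ml_stp_per_g")


def write_gas_curves(curves, path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "bottle_id": c.bottle_id,
                "time_h": c.times_h,
                "gas_ml_stp_per_g": c.values,
            }
        )
        for c in curves
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(CURVE_COLUMNS))
    )
    out.to_csv(path, index=False, float_format="%.17g")


def read_gas_curves(path: str | Path):
    from .gas_conversion import GasCurve

    df = _read_csv(path, CURVE_COLUMNS)
    curves = []
    for bottle_id, grp in df.groupby("bottle_id", sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            GasCurve(
                bottle_id=str(bottle_id),
                times_h=grp["time_h"].to_numpy(dtype=float),
                values=grp["gas_ml_stp_per_g"].to_numpy(dtype=float),
                per_g=True,
                blank_corrected=True,
            )
        )
    return curves


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if pd.isna(value):
        return False
    return str(value).strip().lower() in {"1", "true", "t", "yes", "y"}
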