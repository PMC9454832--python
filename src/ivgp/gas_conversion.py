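"""Pressure-to-gas conversion and blank correction.

A sealed fermentation bottle of fixed headspace V accumulates pressure as
gas evolves.  By the ideal gas law the moles vented/accumulated at bottle
temperature T are n = P·V/(R·T); re-expressed at standard temperature and
pressure (STP) the produced volume is

    V_stp = cum_psi · 6.89476 kPa/PSI · headspace_ml · T_stp / (T · P_stp)

which is linear in the recorded cumulative pressure.  Blank bottles
(inoculum, no feed) quantify the gas the inoculum produces on its own; the
pointwise mean blank volume is subtracted from each treatment bottle's
absolute volume before normalising by sample dry matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DataError, RangeError, ValidationError
from .formats_io import BottleMeta, RunConfig

logger = logging.getLogger(__name__)

#: Exact conversion factor from pounds per square inch to kilopascal.
PSI_TO_KPA = 6.89476


@dataclass(frozen=True)
class PressureTrace:
    """One bottle's cumulative headspace pressure time series (PSI)."""

    bottle_id: str
    times_min: np.ndarray
    cum_psi: np.ndarray
    temp_c: Optional[float] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        p = np.asarray(self.cum_psi, dtype=float)
        if t.shape != p.shape:
            raise DataError(
                f"trace {self.bottle_id!r}: times and pressures differ in length"
            )
        if t.size and t[0] < 0:
            raise DataError(f"trace {self.bottle_id!r}: negative start time")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DataError(
                f"trace {self.bottle_id!r}: times must be strictly increasing"
            )
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "cum_psi", p)


@dataclass(frozen=True)
class GasCurve:
    """Cumulative gas volume versus time.

    ``per_g`` distinguishes substrate-normalised curves (mL STP per g DM)
    from absolute curves (mL STP), which is what blank bottles yield.
    """

    bottle_id: str
    times_h: np.ndarray
    values: np.ndarray
    per_g: bool = True
    blank_corrected: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise DataError(
                f"curve {self.bottle_id!r}: times and values differ in length"
            )
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DataError(
                f"curve {self.bottle_id!r}: times must be strictly increasing"
            )
        if v.size and not np.all(np.isfinite(v)):
            raise DataError(f"curve {self.bottle_id!r}: non-finite gas values")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "values", v)

    def interpolate(self, times_h: np.ndarray) -> np.ndarray:
        """Linear interpolation of the cumulative curve (no extrapolation)."""
        times_h = np.asarray(times_h, dtype=float)
        lo, hi = self.times_h[0], self.times_h[-1]
        if np.any(times_h < lo) or np.any(times_h > hi):
            raise RangeError(
                f"curve {self.bottle_id!r}: requested times outside "
                f"[{lo}, {hi}] h; extrapolation is not supported"
            )
        return np.interp(times_h, self.times_h, self.values)


@dataclass(frozen=True)
class ConversionContext:
    """Physical constants for the pressure → STP-volume conversion."""

    headspace_ml: float
    temp_k: float
    stp_temp_k: float = 273.15
    stp_pressure_kpa: float = 101.325

    def __post_init__(self) -> None:
        for name in ("headspace_ml", "temp_k", "stp_temp_k", "stp_pressure_kpa"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "ConversionContext":
        return cls(
            headspace_ml=cfg.headspace_ml,
            temp_k=cfg.incubation_temp_k,
            stp_temp_k=cfg.stp_temp_k,
            stp_pressure_kpa=cfg.stp_pressure_kpa,
        )

    @property
    def ml_per_psi(self) -> float:
        """STP volume produced per PSI of cumulative pressure (linear factor)."""
        return (
            PSI_TO_KPA
            * self.headspace_ml
            * self.stp_temp_k
            / (self.temp_k * self.stp_pressure_kpa)
        )


def psi_to_ml_stp(cum_psi, ctx: ConversionContext):
    """Convert cumulative pressure (PSI) to cumulative gas volume (mL STP).

    Negative pressures are allowed (sensor noise below baseline) and yield
    negative volumes, which are logged, not clamped.
    """
    cum_psi = np.asarray(cum_psi, dtype=float)
    out = cum_psi * ctx.ml_per_psi
    if np.any(cum_psi < 0):
        logger.info("negative cumulative pressure encountered; volume kept negative")
    if out.ndim == 0:
        return float(out)
    return out


def ml_stp_to_psi(ml_stp, ctx: ConversionContext):
    """Inverse conversion, used when synthesising pressure traces."""
    return np.asarray(ml_stp, dtype=float) / ctx.ml_per_psi


def blank_mean(blanks: Sequence[GasCurve]) -> GasCurve:
    """Pointwise mean of blank bottles' absolute gas volumes.

    Blanks recorded on shifted grids are combined on the union grid via
    linear interpolation, restricted to the overlapping time range.
    """
    if not blanks:
        raise DataError(
            "no blank curves supplied; pass blank=None to trace_to_curve to "
            "disable blank correction explicitly"
        )
    if any(b.per_g for b in blanks):
        raise ValidationError("blank curves must be absolute mL, not per-g")
    if len(blanks) == 1:
        b = blanks[0]
        return GasCurve("blank_mean", b.times_h, b.values, per_g=False)
    grid = np.unique(np.concatenate([b.times_h for b in blanks]))
    lo = max(b.times_h[0] for b in blanks)
    hi = min(b.times_h[-1] for b in blanks)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size == 0:
        raise DataError("blank curves have no overlapping time range")
    stacked = np.vstack([b.interpolate(grid) for b in blanks])
    return GasCurve("blank_mean", grid, stacked.mean(axis=0), per_g=False)


def trace_to_curve(
    trace: PressureTrace,
    meta: BottleMeta,
    ctx: ConversionContext,
    blank: Optional[GasCurve] = None,
) -> GasCurve:
    """Convert a pressure trace to a (blank-corrected) gas curve.

    Treatment bottles are normalised by dry-matter mass; blank bottles stay
    in absolute mL.  Blank correction subtracts the mean blank's absolute
    volume *before* normalisation, because blanks carry no substrate.
    Negative corrected values are retained so downstream noise statistics
    stay unbiased.
    """
    times_h = trace.times_min / 60.0
    abs_ml = psi_to_ml_stp(trace.cum_psi, ctx)
    corrected = blank is not None
    if blank is not None:
        abs_ml = abs_ml - blank.interpolate(times_h)
        if np.any(abs_ml < -1e-9):
            logger.info(
                "bottle %s: negative blank-corrected volumes retained",
                trace.bottle_id,
            )
    if meta.is_blank:
        return GasCurve(trace.bottle_id, times_h, abs_ml, per_g=False,
                        blank_corrected=corrected)
    dm_g = meta.dm_mass_g
    if not dm_g > 0:
        raise ValidationError(
            f"bottle {trace.bottle_id!r}: non-blank bottle with zero DM mass"
        )
    return GasCurve(trace.bottle_id, times_h, abs_ml / dm_g, per_g=True,
                    blank_corrected=corrected)


def gp_at_hours(curve: GasCurve, hours: Sequence[float]) -> np.ndarray:
    """Gas production at the requested hours by linear interpolation."""
    return curve.interpolate(np.asarray(hours, dtype=float))
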