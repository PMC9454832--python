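"""Endpoint fermentation metrics.

Degradation percentages relate residue masses to the unfermented sample;
the 48-h partitioning factor (PF48, mg degraded DM per mL gas) indexes
fermentation efficiency — high values mean more substrate routed into
microbial biomass and VFA rather than gas.  The theoretical short-chain
fatty acid yield is the empirical linear predictor

    tVFA (mmol / 200 mg DM) = 0.0222 · GP24 − 0.00425

where GP24 is 24-h net gas production in mL per 200 mg DM at STP.
Methane yield converts a bag concentration (% of collected gas) into
mL CH4 per g DM; the VFA profile re-expresses acid concentrations as a
molar percentage of the total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .errors import ValidationError
from .formats_io import VFA_ACIDS

logger = logging.getLogger(__name__)

TVFA_SLOPE = 0.0222
TVFA_INTERCEPT = -0.00425


@dataclass(frozen=True)
class FermentationRecord:
    """Per-bottle post-fermentation measurements (as measured, uncorrected)."""

    bottle_id: str
    initial_dm_mg: float
    residue_dm_mg: float
    initial_ndf_mg: float
    residue_ndf_mg: float
    initial_adf_mg: float
    residue_adf_mg: float
    ph: float
    ch4_fraction: float                      # % of collected gas
    vfa_mmol_per_l: Mapping[str, float]

    def __post_init__(self) -> None:
        for name in ("initial_dm_mg", "residue_dm_mg", "initial_ndf_mg",
                     "residue_ndf_mg", "initial_adf_mg", "residue_adf_mg"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.bottle_id}: {name} must be >= 0")
        if not 0.0 <= self.ch4_fraction <= 100.0:
            raise ValidationError(
                f"{self.bottle_id}: ch4_fraction must lie in [0, 100]"
            )
        if any(v < 0 for v in self.vfa_mmol_per_l.values()):
            raise ValidationError(f"{self.bottle_id}: negative VFA concentration")


@dataclass(frozen=True)
class MetricsResult:
    """Derived endpoint metrics for one bottle."""

    bottle_id: str
    dDM_pct: float
    dNDF_pct: float
    dADF_pct: float
    pf48: float
    tvfa_mmol: float
    ch4_pct: float
    ch4_ml_per_g: float
    total_vfa_mmol_per_l: float
    molar_pct: Mapping[str, float]
    ap_ratio: Optional[float]
    ph: float


def degradation_pct(initial_mg: float, residue_mg: float) -> float:
    """Percent of the unfermented mass degraded during fermentation."""
    if not initial_mg > 0:
        raise ValidationError("initial mass must be strictly positive")
    if residue_mg < 0:
        raise ValidationError("residue mass must be >= 0")
    if residue_mg > initial_mg:
        logger.warning(
            "residue (%.3g mg) exceeds initial (%.3g mg); negative degradation",
            residue_mg, initial_mg,
        )
    return (initial_mg - residue_mg) / initial_mg * 100.0


def pf48(degraded_dm_mg: float, gas48_ml: float) -> float:
    """Partitioning factor: mg degraded DM per mL of 48-h gas."""
    if not gas48_ml > 0:
        raise ValidationError("48-h gas volume must be strictly positive")
    return degraded_dm_mg / gas48_ml


def tvfa(gp24_ml_per_200mg: float) -> float:
    """Theoretical VFA yield (mmol per 200 mg DM) from 24-h gas production.

    The affine predictor is left unclamped; a (physically impossible)
    negative prediction at very low gas is reported raw and logged.
    """
    if not np.isfinite(gp24_ml_per_200mg):
        raise ValidationError("gp24 must be finite")
    out = TVFA_SLOPE * gp24_ml_per_200mg + TVFA_INTERCEPT
    if out < 0:
        logger.warning("tVFA prediction negative (%.4g); reported raw", out)
    return out


def tvfa_from_per_g(gp24_ml_per_g: float) -> float:
    """Adapter: per-g gas production → per-200-mg basis (divide by 5)."""
    return tvfa(gp24_ml_per_g / 5.0)


def methane_metrics(tgp_ml_per_g: float, ch4_pct: float) -> tuple[float, float]:
    """Methane concentration (%) and yield (mL CH4 per g DM)."""
    if not 0.0 <= ch4_pct <= 100.0:
        raise ValidationError("ch4_pct must lie in [0, 100]")
    if tgp_ml_per_g < 0:
        raise ValidationError("total gas production must be >= 0")
    return ch4_pct, tgp_ml_per_g * ch4_pct / 100.0


def correct_ch4(
    ch4_pct_measured: float,
    total_gas_ml: float,
    blank_ch4_pct: float,
    blank_gas_ml: float,
    method: str = "volume_weighted",
) -> float:
    """Blank-correct a bag methane concentration.

    ``volume_weighted`` removes the blank's CH4 *volume* from the bag and
    re-expresses the remainder over the net gas volume; ``simple``
    subtracts concentrations directly.
    """
    if method == "simple":
        return ch4_pct_measured - blank_ch4_pct
    if method != "volume_weighted":
        raise ValidationError(f"unknown CH4 correction method {method!r}")
    net = total_gas_ml - blank_gas_ml
    if not net > 0:
        raise ValidationError("net gas volume must be positive for correction")
    return (ch4_pct_measured * total_gas_ml - blank_ch4_pct * blank_gas_ml) / net


def vfa_profile(
    conc: Mapping[str, float],
) -> tuple[float, dict[str, float], Optional[float]]:
    """Total VFA, molar profile (mol/100 mol) and acetate:propionate ratio.

    Acids missing from the map are treated as zero with a warning; the
    ratio is ``None`` (flagged) when propionate is zero.
    """
    missing = [a for a in VFA_ACIDS if a not in conc]
    if missing:
        logger.warning("VFA acids %s missing; treated as 0", missing)
    values = {a: float(conc.get(a, 0.0)) for a in VFA_ACIDS}
    if any(v < 0 for v in values.values()):
        raise ValidationError("VFA concentrations must be >= 0")
    total = sum(values.values())
    if not total > 0:
        raise ValidationError("all VFA concentrations are zero")
    molar = {a: 100.0 * v / total for a, v in values.items()}
    if values["propionic"] > 0:
        ap: Optional[float] = values["acetic"] / values["propionic"]
    else:
        ap = None
        logger.warning("propionate is zero; acetate:propionate undefined")
    return total, molar, ap


def compute_metrics(
    record: FermentationRecord,
    gp24_ml_per_g: float,
    gp48_ml_per_g: float,
    dm_mass_g: float,
    blank_residue_dm_mg: float = 0.0,
    ch4_blank_pct: Optional[float] = None,
    total_gas48_ml: Optional[float] = None,
    blank_gas48_ml: Optional[float] = None,
    ch4_correction: str = "volume_weighted",
) -> MetricsResult:
    """Assemble all endpoint metrics for one bottle.

    Residue DM is blank-corrected by subtracting the mean blank residue
    before computing degradation; the methane concentration is optionally
    blank-corrected when the blank bag concentration and gas volumes are
    supplied.
    """
    residue_dm = record.residue_dm_mg - blank_residue_dm_mg
    ddm = degradation_pct(record.initial_dm_mg, max(0.0, residue_dm))
    dndf = (
        degradation_pct(record.initial_ndf_mg, record.residue_ndf_mg)
        if record.initial_ndf_mg > 0 else float("nan")
    )
    dadf = (
        degradation_pct(record.initial_adf_mg, record.residue_adf_mg)
        if record.initial_adf_mg > 0 else float("nan")
    )
    degraded_mg = record.initial_dm_mg * ddm / 100.0
    gas48_abs = gp48_ml_per_g * dm_mass_g
    pf = pf48(degraded_mg, gas48_abs)
    tv = tvfa_from_per_g(gp24_ml_per_g)
    ch4 = record.ch4_fraction
    if ch4_blank_pct is not None and total_gas48_ml is not None \
            and blank_gas48_ml is not None:
        ch4 = correct_ch4(ch4, total_gas48_ml, ch4_blank_pct, blank_gas48_ml,
                          method=ch4_correction)
        ch4 = float(np.clip(ch4, 0.0, 100.0))
    ch4_pct, ch4_yield = methane_metrics(max(0.0, gp48_ml_per_g), ch4)
    total, molar, ap = vfa_profile(record.vfa_mmol_per_l)
    return MetricsResult(
        bottle_id=record.bottle_id,
        dDM_pct=ddm,
        dNDF_pct=dndf,
        dADF_pct=dadf,
        pf48=pf,
        tvfa_mmol=tv,
        ch4_pct=ch4_pct,
        ch4_ml_per_g=ch4_yield,
        total_vfa_mmol_per_l=total,
        molar_pct=molar,
        ap_ratio=ap,
        ph=record.ph,
    )
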