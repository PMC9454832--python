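"""Dose-response trend analysis with orthogonal polynomial contrasts.

Each response is modelled as

    Y_ijk = mu + D_i + R_j + E_ijk

with dose level D_i as a categorical fixed effect and incubation run R_j
as a random intercept (REML).  Linear and quadratic dose trends are tested
with orthogonal contrasts built for the *actual* dose spacings — with
doses 0/20/40/100 the textbook equally-spaced coefficients are not
orthogonal, so coefficients are derived by Gram–Schmidt orthogonalisation
of the dose powers.  Contrast Wald t-tests use containment denominator
degrees of freedom, n − (#doses) − (#incubations) + 1.

When the REML estimate of the run variance hits the zero boundary (common
with only two runs), the model is refitted with incubation as a fixed
block, which yields the identical contrast inference in the balanced case.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import gcd
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DoseResponseResult:
    """Trend statistics for one response."""

    response: str
    dose_means: Mapping[float, float]
    sem: float                    # residual-based pooled SEM of a dose mean
    sem_model: float              # includes the run variance component
    p_linear: float
    p_quadratic: float
    var_incubation: float
    var_residual: float
    df_denom: int
    method: str                   # "mixed" or "fixed_block"


def contrast_coefficients(
    doses: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Linear and quadratic orthogonal contrast vectors for given doses.

    The linear contrast is the centred dose vector; the quadratic contrast
    is the Gram–Schmidt residual of squared doses against the constant and
    linear vectors.  Both sum to zero and are mutually orthogonal exactly
    (computed in rational arithmetic), and are scaled to the smallest
    integer form with the last coefficient positive.
    """
    d = list(doses)
    if len(d) != len(set(d)):
        raise ValidationError("dose levels must be distinct")
    if len(d) < 3:
        raise ValidationError("quadratic contrast needs at least 3 dose levels")
    if any(d[i] >= d[i + 1] for i in range(len(d) - 1)):
        raise ValidationError("doses must be strictly increasing")
    fr = [Fraction(x).limit_denominator(10**9) for x in d]
    n = len(fr)
    mean = sum(fr, Fraction(0)) / n
    lin = [x - mean for x in fr]
    sq = [x * x for x in fr]
    sq_mean = sum(sq, Fraction(0)) / n
    sq_c = [s - sq_mean for s in sq]
    lin_norm = sum(l * l for l in lin)
    proj = sum(s * l for s, l in zip(sq_c, lin)) / lin_norm
    quad = [s - proj * l for s, l in zip(sq_c, lin)]
    return _integer_scale(lin), _integer_scale(quad)


def _integer_scale(vec: list[Fraction]) -> np.ndarray:
    denom_lcm = 1
    for v in vec:
        denom_lcm = denom_lcm * v.denominator // gcd(denom_lcm, v.denominator)
    ints = [int(v * denom_lcm) for v in vec]
    g = 0
    for i in ints:
        g = gcd(g, abs(i))
    if g:
        ints = [i // g for i in ints]
    if ints[-1] < 0:
        ints = [-i for i in ints]
    return np.array(ints, dtype=float)


def fit_dose_model(
    table: pd.DataFrame,
    response: str = "value",
    dose_col: str = "dose",
    incubation_col: str = "incubation",
    method: str = "auto",
) -> DoseResponseResult:
    """Fit the random-incubation model and test linear/quadratic trends.

    ``method`` may be ``"auto"`` (mixed model with fixed-block fallback at
    the variance boundary), ``"mixed"`` or ``"fixed_block"``.
    """
    df = table[[dose_col, incubation_col, response]].rename(
        columns={dose_col: "dose", incubation_col: "incubation", response: "value"}
    ).dropna()
    doses = np.array(sorted(df["dose"].unique()), dtype=float)
    incubations = sorted(df["incubation"].unique())
    if doses.size < 2:
        raise DataError("need at least 2 dose levels")
    counts = df.groupby(["dose", "incubation"]).size()
    balanced = counts.nunique() == 1 and len(counts) == doses.size * len(incubations)
    if not balanced:
        logger.warning("unbalanced dose × incubation design; containment df kept")
    n = len(df)
    q, r = doses.size, len(incubations)
    df_denom = max(1, n - q - r + 1)
    n_per_dose = df.groupby("dose").size().min()

    lin, quad = contrast_coefficients(doses)

    if len(incubations) < 2 and method in ("auto", "mixed"):
        logger.warning("fewer than 2 incubations: random run effect is "
                       "degenerate; using fixed-block model")
        method = "fixed_block"

    used = method
    if method in ("auto", "mixed"):
        fit = _fit_mixed(df)
        if fit is None or (method == "auto" and fit["var_inc"]
                           < 1e-8 * max(fit["var_resid"], 1e-12)):
            if method == "mixed" and fit is not None:
                used = "mixed"
            else:
                logger.info("run-variance estimate at the zero boundary; "
                            "refitting with incubation as a fixed block")
                used = "fixed_block"
        else:
            used = "mixed"
    if used in ("auto", "fixed_block"):
        fit = _fit_fixed_block(df)
        used = "fixed_block"

    means = fit["means"]
    cov = fit["cov_means"]
    var_inc, var_resid = fit["var_inc"], fit["var_resid"]

    def contrast_p(c: np.ndarray) -> float:
        est = float(c @ means)
        se = float(np.sqrt(c @ cov @ c))
        if se == 0:
            return 0.0 if est != 0 else 1.0
        t = est / se
        return float(2.0 * stats.t.sf(abs(t), df_denom))

    sem = float(np.sqrt(var_resid / n_per_dose))
    sem_model = float(np.sqrt((var_resid + var_inc) / n_per_dose))
    return DoseResponseResult(
        response=response,
        dose_means={float(d): float(m) for d, m in zip(doses, means)},
        sem=sem,
        sem_model=sem_model,
        p_linear=contrast_p(lin),
        p_quadratic=contrast_p(quad),
        var_incubation=float(var_inc),
        var_residual=float(var_resid),
        df_denom=df_denom,
        method=used,
    )


def _dose_design(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Cell-means coding for dose: X[i, j] = 1 iff row i has dose level j."""
    doses = np.array(sorted(df["dose"].unique()), dtype=float)
    X = (df["dose"].to_numpy()[:, None] == doses[None, :]).astype(float)
    return doses, X


def _fit_mixed(df: pd.DataFrame) -> Optional[dict]:
    import statsmodels.api as sm

    doses, X = _dose_design(df)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(
                df["value"].to_numpy(), X, groups=df["incubation"].to_numpy()
            )
            res = model.fit(reml=True, method=["lbfgs", "powell"])
    except Exception as exc:  # numerical failure → caller falls back
        logger.info("mixed-model fit failed (%s)", exc)
        return None
    if not np.all(np.isfinite(res.params)):
        return None
    k = doses.size
    means = np.asarray(res.fe_params, dtype=float)
    cov = np.asarray(res.cov_params())[:k, :k]
    var_inc = float(np.asarray(res.cov_re)[0, 0])
    var_resid = float(res.scale)
    return {"means": means, "cov_means": cov, "var_inc": var_inc,
            "var_resid": var_resid}


def _fit_fixed_block(df: pd.DataFrame) -> dict:
    """OLS with dose cell means and incubation as a sum-coded fixed block."""
    import statsmodels.api as sm

    doses, X = _dose_design(df)
    incs = sorted(df["incubation"].unique())
    blocks = []
    for inc in incs[:-1]:
        col = (df["incubation"] == inc).astype(float) \
            - (df["incubation"] == incs[-1]).astype(float)
        blocks.append(col.to_numpy())
    design = np.column_stack([X] + blocks) if blocks else X
    res = sm.OLS(df["value"].to_numpy(), design).fit()
    k = doses.size
    means = np.asarray(res.params[:k], dtype=float)
    cov = np.asarray(res.cov_params())[:k, :k]
    return {"means": means, "cov_means": cov, "var_inc": 0.0,
            "var_resid": float(res.mse_resid)}


def trend_table(
    data: pd.DataFrame,
    responses: Sequence[str],
    dose_col: str = "dose_pct",
    incubation_col: str = "incubation_id",
    method: str = "auto",
) -> pd.DataFrame:
    """Run ``fit_dose_model`` for several responses of one additive.

    Returns one row per response with dose means, pooled SEM and trend
    p-values — the layout of a published dose-response table.
    """
    rows = []
    for resp in responses:
        result = fit_dose_model(
            data, response=resp, dose_col=dose_col,
            incubation_col=incubation_col, method=method,
        )
        row: dict = {"response": resp}
        for d, m in result.dose_means.items():
            row[f"mean_{d:g}"] = m
        row.update(
            SEM=result.sem,
            SEM_model=result.sem_model,
            p_linear=result.p_linear,
            p_quadratic=result.p_quadratic,
            method=result.method,
        )
        rows.append(row)
    return pd.DataFrame(rows)
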