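"""Log-linear calibration between mean erythrocyte age and erythrocyte creatine.

The calibration fits ordinary least squares with ln EC as the response,

    ln EC = a·M_RBC + b,

and inverts it *algebraically* to the estimator form

    M_RBC = (1/a)·ln EC + (−b/a).

The inversion is deliberately not a re-regression of M_RBC on ln EC — the two
give different coefficients, and the published estimator is the algebraic
inverse of the forward fit.  Fit strength is summarized by the Pearson
correlation r between M_RBC and ln EC, its t statistic t = |r|·√df/√(1−r²)
with df = n − 2, and the two-sided p-value from the central t distribution.

``published_model`` carries the reference coefficients exactly as printed
(forward slope −0.04379, intercept 2.882; inverse −22.84 and 65.83; the
printed inverse was produced from unrounded coefficients, so it differs in
the third decimal from inverting the printed forward pair).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidMeasurementError,
    InvalidParameterError,
    NonInvertibleError,
)

__all__ = [
    "CalibrationModel",
    "fit_loglinear",
    "correlation_t_stat",
    "correlation_p_value",
    "invert_model",
    "published_model",
    "compare_group_fits",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "EQ_FORWARD_SLOPE",
    "EQ_FORWARD_INTERCEPT",
]

# reference calibration constants (forward fit on the 21-patient dataset)
EQ_FORWARD_SLOPE = -0.04379
EQ_FORWARD_INTERCEPT = 2.882


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted (or published) log-linear calibration and its statistics.

    ``slope``/``intercept`` are the forward fit of ln EC on M_RBC;
    ``inv_slope``/``inv_intercept`` the inverse estimator coefficients;
    ``ec_range_seen`` the EC range (μmol/g Hb) covered by the fitting data,
    used to flag extrapolation at estimation time.
    """

    slope: float
    intercept: float
    inv_slope: float
    inv_intercept: float
    r: float
    n: int
    df: int
    t_stat: float
    p_value: float
    ec_range_seen: tuple[float, float]
    model_id: str = "fitted"


def correlation_t_stat(r: float, df: int) -> float:
    """t statistic of a Pearson correlation: |r|·√df / √(1 − r²)."""
    if df < 1:
        raise InvalidParameterError(f"df must be >= 1, got {df}")
    if abs(r) >= 1:
        raise InvalidParameterError(f"t statistic undefined for |r| >= 1, got {r}")
    return abs(r) * np.sqrt(df) / np.sqrt(1.0 - r * r)


def correlation_p_value(t: float, df: int) -> float:
    """Two-sided tail probability of a central t distribution."""
    if df < 1:
        raise InvalidParameterError(f"df must be >= 1, got {df}")
    if t < 0:
        raise InvalidParameterError(f"t must be non-negative, got {t}")
    return float(2.0 * stats.t.sf(t, df))


def fit_loglinear(m_rbc, ec, model_id: str = "fitted") -> CalibrationModel:
    """Fit ln EC = a·M_RBC + b by ordinary least squares.

    Parameters are paired arrays of mean cell age (days) and EC (μmol/g Hb).
    The inverse estimator coefficients are populated by algebraic inversion.
    """
    m = np.asarray(m_rbc, dtype=float)
    e = np.asarray(ec, dtype=float)
    if m.shape != e.shape:
        raise InvalidParameterError("m_rbc and ec must have equal length")
    n = m.size
    if n < 3:
        raise InsufficientDataError(f"need at least 3 subjects, got {n}")
    if np.any(e <= 0):
        raise InvalidMeasurementError("EC values must be positive to take logarithms")
    if np.ptp(m) == 0:
        raise DegenerateDesignError("mean-age values are all identical")
    res = stats.linregress(m, np.log(e))
    r = float(res.rvalue)
    df = n - 2
    denom = 1.0 - r * r
    if denom <= 0:  # exact fit: correlation test degenerates
        t_stat, p_value = float("inf"), 0.0
    else:
        t_stat = float(correlation_t_stat(r, df))
        p_value = correlation_p_value(t_stat, df)
    model = CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        inv_slope=float("nan"),
        inv_intercept=float("nan"),
        r=r,
        n=n,
        df=df,
        t_stat=t_stat,
        p_value=p_value,
        ec_range_seen=(float(e.min()), float(e.max())),
        model_id=model_id,
    )
    return invert_model(model)


def invert_model(model: CalibrationModel) -> CalibrationModel:
    """Populate the inverse-estimator coefficients by algebraic inversion:
    inv_slope = 1/a, inv_intercept = −b/a."""
    if model.slope == 0:
        raise NonInvertibleError("zero forward slope cannot be inverted")
    return dataclasses.replace(
        model,
        inv_slope=1.0 / model.slope,
        inv_intercept=-model.intercept / model.slope,
    )


def published_model() -> CalibrationModel:
    """The reference calibration with every constant as printed.

    Inverse coefficients are the printed −22.84 and 65.83, not re-derived
    from the printed forward pair (which would give −22.8363 and 65.814).
    """
    return CalibrationModel(
        slope=EQ_FORWARD_SLOPE,
        intercept=EQ_FORWARD_INTERCEPT,
        inv_slope=-22.84,
        inv_intercept=65.83,
        r=-0.9475,
        n=21,
        df=19,
        t_stat=12.92,
        p_value=7.368e-11,
        ec_range_seen=(1.45, 11.76),
        model_id="published",
    )


def compare_group_fits(
    cohort,
    group_col: str = "group",
    mrbc_col: str = "true_mrbc_days",
    ec_col: str = "ec_umol_ghb",
) -> dict:
    """Compare severity-group regressions on linear vs logarithmic EC scale.

    On a linear scale the severe and mild subgroups of a hemolytic cohort
    fall on visibly different EC-vs-age lines; on a semi-log scale a single
    line unifies them.  Returns per-group slopes on both scales, a
    unification score (relative difference of the group log-scale slopes),
    and ``unified`` = True when the pooled log-scale r² exceeds the pooled
    linear-scale r².
    """
    if group_col not in cohort.columns:
        raise InvalidParameterError(f"cohort is missing the {group_col!r} column")
    groups = {name: g for name, g in cohort.groupby(group_col, observed=True)}
    if len(groups) != 2:
        raise InvalidParameterError(f"need exactly 2 groups, got {len(groups)}")
    for name, g in groups.items():
        if len(g) < 3:
            raise InsufficientDataError(f"group {name!r} has fewer than 3 subjects")

    def slopes(g):
        m = g[mrbc_col].to_numpy(float)
        e = g[ec_col].to_numpy(float)
        lin = stats.linregress(m, e)
        log = stats.linregress(m, np.log(e))
        return lin, log

    report = {"groups": {}}
    log_slopes, lin_slopes = [], []
    for name, g in groups.items():
        lin, log = slopes(g)
        report["groups"][name] = {
            "n": int(len(g)),
            "linear_slope": float(lin.slope),
            "log_slope": float(log.slope),
        }
        lin_slopes.append(lin.slope)
        log_slopes.append(log.slope)

    mean_abs_log = np.mean(np.abs(log_slopes))
    mean_abs_lin = np.mean(np.abs(lin_slopes))
    report["log_slope_rel_diff"] = float(
        abs(log_slopes[0] - log_slopes[1]) / mean_abs_log
    )
    report["linear_slope_rel_diff"] = float(
        abs(lin_slopes[0] - lin_slopes[1]) / mean_abs_lin
    )
    report["unification_score"] = report["log_slope_rel_diff"]

    m_all = cohort[mrbc_col].to_numpy(float)
    e_all = cohort[ec_col].to_numpy(float)
    pooled_lin = stats.linregress(m_all, e_all)
    pooled_log = stats.linregress(m_all, np.log(e_all))
    report["pooled_linear_r2"] = float(pooled_lin.rvalue**2)
    report["pooled_log_r2"] = float(pooled_log.rvalue**2)
    report["unified"] = report["pooled_log_r2"] > report["pooled_linear_r2"]
    return report


# --- JSON (de)serialization of fitted models -------------------------------

def model_to_dict(model: CalibrationModel) -> dict:
    d = dataclasses.asdict(model)
    d["ec_range_seen"] = list(model.ec_range_seen)
    return d


def model_from_dict(d: dict) -> CalibrationModel:
    d = dict(d)
    d["ec_range_seen"] = tuple(d["ec_range_seen"])
    return CalibrationModel(**d)


def save_model(model: CalibrationModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2)
        fh.write("\n")


def load_model(path) -> CalibrationModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
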