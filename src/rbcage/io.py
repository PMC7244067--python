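"""CSV/JSON readers and writers and tool configuration.

Unit safety: the EC unit is declared by the *column name* — ``ec_umol_ghb``
or ``ec_mg_dl_rbc`` — never by a separate unit column, so a file cannot
silently mix units; a file with both columns is rejected.  Files are UTF-8,
comma-separated, '.' decimal, header mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimator import AgeEstimate
from .exceptions import FormatError, InvalidParameterError
from .units import ConversionConstants, DEFAULT_CONSTANTS, mgdl_to_umol_per_ghb

__all__ = ["ToolConfig", "load_config", "read_cohort_csv", "write_results"]

EC_UMOL_COL = "ec_umol_ghb"
EC_MGDL_COL = "ec_mg_dl_rbc"
OPTIONAL_COLS = ("cr51_halflife_days", "mchc_g_dl", "group", "true_mrbc_days")

RESULT_COLUMNS = [
    "subject_id",
    "ec_umol_ghb",
    "m_rbc_days",
    "lifespan_days",
    "extrapolated",
    "implausible",
    "model_id",
]


@dataclass(frozen=True)
class ToolConfig:
    """Tool-level configuration (conversion constants, Cr factor, model)."""

    constants: ConversionConstants = field(default_factory=ConversionConstants)
    cr_factor: float = 2.61
    model: str = "published"
    kinetic_preset: str = "anchored"
    output_precision: int = 4

    def __post_init__(self) -> None:
        if self.cr_factor <= 0:
            raise InvalidParameterError(f"cr_factor must be positive, got {self.cr_factor}")
        if self.output_precision < 2:
            raise InvalidParameterError(
                f"output_precision must be >= 2, got {self.output_precision}"
            )


def load_config(path) -> ToolConfig:
    """Load a YAML or JSON config file (YAML parses both)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    consts = raw.pop("constants", {})
    constants = ConversionConstants(
        creatine_molecular_weight=consts.get("creatine_molecular_weight", 131.15),
        mchc=consts.get("mchc", 33.0),
    )
    return ToolConfig(constants=constants, **raw)


def read_cohort_csv(path, constants: ConversionConstants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Read a per-subject measurement CSV into a normalized DataFrame.

    Requires ``subject_id`` plus exactly one EC column (``ec_umol_ghb`` or
    ``ec_mg_dl_rbc``); mg/dL values are converted to μmol/g Hb, honouring a
    per-row ``mchc_g_dl`` override when present.  Rows with non-numeric or
    non-positive EC are rejected with their row numbers.  Optional columns
    (``cr51_halflife_days``, ``group``, ``true_mrbc_days``) pass through.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path} is empty (no header)") from None
    if df.empty:
        raise FormatError(f"{path} contains a header but no rows")
    if "subject_id" not in df.columns:
        raise FormatError(f"{path} is missing required column 'subject_id'")
    has_umol = EC_UMOL_COL in df.columns
    has_mgdl = EC_MGDL_COL in df.columns
    if has_umol and has_mgdl:
        raise FormatError(
            f"{path} has both {EC_UMOL_COL} and {EC_MGDL_COL}; declare one unit"
        )
    if not (has_umol or has_mgdl):
        raise FormatError(
            f"{path} needs an EC column named {EC_UMOL_COL} or {EC_MGDL_COL}"
        )
    ec_col = EC_UMOL_COL if has_umol else EC_MGDL_COL
    ec = pd.to_numeric(df[ec_col], errors="coerce")
    bad = ec.isna() | (ec <= 0)
    if bad.any():
        rows = ", ".join(str(i + 1) for i in df.index[bad])
        raise FormatError(
            f"{path}: non-numeric or non-positive EC in data row(s) {rows}"
        )
    out = df.copy()
    if has_mgdl:
        if "mchc_g_dl" in df.columns:
            mchc = pd.to_numeric(df["mchc_g_dl"], errors="coerce")
            converted = [
                mgdl_to_umol_per_ghb(
                    x,
                    constants
                    if np.isnan(m)
                    else ConversionConstants(
                        constants.creatine_molecular_weight, float(m)
                    ),
                )
                for x, m in zip(ec, mchc)
            ]
            out[EC_UMOL_COL] = converted
        else:
            out[EC_UMOL_COL] = mgdl_to_umol_per_ghb(ec.to_numpy(), constants)
        out = out.drop(columns=[EC_MGDL_COL])
    else:
        out[EC_UMOL_COL] = ec.astype(float)
    return out


def write_results(estimates: list[AgeEstimate], path, precision: int = 4) -> None:
    """Write estimates as CSV with deterministic column order and warning
    flags materialized as columns."""
    fmt = lambda v: f"{v:.{precision}g}"
    rows = [
        {
            "subject_id": e.subject_id if e.subject_id is not None else "",
            "ec_umol_ghb": fmt(e.ec),
            "m_rbc_days": fmt(e.m_rbc),
            "lifespan_days": fmt(e.lifespan),
            "extrapolated": e.extrapolated,
            "implausible": e.implausible,
            "model_id": e.model_id,
        }
        for e in estimates
    ]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, index=False)
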