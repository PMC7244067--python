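"""Erythrocyte creatine unit conversion.

Historical assays reported erythrocyte creatine (EC) in mg per dL of packed
red cells; the calibration here works in μmol per gram of hemoglobin.  The
two are related through the molecular weight of creatine (131.15 g/mol) and
the mean cell hemoglobin concentration (MCHC, default 33 g/dL):

    EC [μmol/g Hb] = EC [mg/dL RBC] × 1000 / (MW × MCHC)

With the defaults the divisor MW × MCHC / 1000 is 4.32795 (4.328 at three
decimals).  MCHC is configurable because it falls in iron-deficiency anemia;
batch input supports a per-subject override.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidMeasurementError, InvalidParameterError

__all__ = [
    "ConversionConstants",
    "DEFAULT_CONSTANTS",
    "conversion_divisor",
    "mgdl_to_umol_per_ghb",
    "umol_per_ghb_to_mgdl",
]

#: Recognized unit tags for EC columns and CLI flags.
UNIT_UMOL_GHB = "umol_gHb"
UNIT_MG_DL_RBC = "mg_dl_rbc"


@dataclass(frozen=True)
class ConversionConstants:
    """Constants of the mg/dL-RBC ↔ μmol/g-Hb conversion.

    Parameters
    ----------
    creatine_molecular_weight : float
        Molecular weight of creatine in g/mol.
    mchc : float
        Mean cell hemoglobin concentration in g/dL.
    """

    creatine_molecular_weight: float = 131.15
    mchc: float = 33.0

    def __post_init__(self) -> None:
        if self.creatine_molecular_weight <= 0:
            raise InvalidParameterError(
                f"molecular weight must be positive, got {self.creatine_molecular_weight}"
            )
        if self.mchc <= 0:
            raise InvalidParameterError(f"MCHC must be positive, got {self.mchc}")

    @property
    def derived_divisor(self) -> float:
        """MW × MCHC / 1000, the mg/dL-per-(μmol/g Hb) divisor."""
        return self.creatine_molecular_weight * self.mchc / 1000.0


DEFAULT_CONSTANTS = ConversionConstants()


def conversion_divisor(constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Return the scalar divisor MW × MCHC / 1000 (4.32795 with defaults)."""
    return constants.derived_divisor


def _validate_nonnegative(value, name: str):
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise InvalidMeasurementError(f"{name} must be non-negative, got {value}")
    return arr


def mgdl_to_umol_per_ghb(x, constants: ConversionConstants = DEFAULT_CONSTANTS):
    """Convert EC from mg/dL of red cells to μmol/g Hb.

    Accepts scalars or array-likes; negative input raises
    :class:`~rbcage.exceptions.InvalidMeasurementError`.
    """
    arr = _validate_nonnegative(x, "EC (mg/dL RBC)")
    out = arr * 1000.0 / (constants.creatine_molecular_weight * constants.mchc)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def umol_per_ghb_to_mgdl(y, constants: ConversionConstants = DEFAULT_CONSTANTS):
    """Convert EC from μmol/g Hb to mg/dL of red cells (inverse conversion)."""
    arr = _validate_nonnegative(y, "EC (umol/g Hb)")
    out = arr * constants.creatine_molecular_weight * constants.mchc / 1000.0
    return float(out) if np.isscalar(y) or np.ndim(y) == 0 else out
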