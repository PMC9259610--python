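"""Isotope-delta arithmetic for N2O isotopocules.

N2O is a linear molecule (N-N-O); the 15N substitution can sit on the
central (alpha) or terminal (beta) nitrogen.  Site preference
SP = d15N_alpha - d15N_beta and the bulk d15N (the site mean) are the
derived quantities everything downstream consumes.  This module also
provides the two-point SP calibration against a pair of reference gases
and the oxygen-exchange correction that moves measured d18O (vs VSMOW)
onto the N2O/H2O scale by subtracting the ambient-water d18O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SPCalibrationPair",
    "OExchangeParams",
    "site_preference",
    "bulk_delta",
    "calibrate_sp",
    "o_exchange_correct",
    "annotate_measurements",
]


class InvalidMeasurementError(ValueError):
    """A delta value is missing or non-finite."""


class CalibrationUndefinedError(ValueError):
    """The two calibration standards do not define a line."""


@dataclass(frozen=True)
class SPCalibrationPair:
    """Two SP reference gases, true and measured values in per-mil.

    Defaults are the AK1 (-2 permil) and Mix 1 (+15 permil) standards with
    measured == true (identity calibration).
    """

    standard_a_true: float = -2.0
    standard_a_measured: float = -2.0
    standard_b_true: float = 15.0
    standard_b_measured: float = 15.0

    def __post_init__(self) -> None:
        vals = (
            self.standard_a_true,
            self.standard_a_measured,
            self.standard_b_true,
            self.standard_b_measured,
        )
        if not all(math.isfinite(v) for v in vals):
            raise CalibrationUndefinedError("calibration standards must be finite")
        if self.standard_a_measured == self.standard_b_measured:
            raise CalibrationUndefinedError(
                "identical measured standard values: calibration line undefined"
            )


@dataclass(frozen=True)
class OExchangeParams:
    """Ambient-water d18O used for the oxygen-exchange correction.

    Under (near-)complete O-atom exchange with water during denitrification
    the water d18O sets the oxygen baseline; the default 0.91 permil is a
    literature surface-seawater value (global span roughly -2.98 to 1).
    """

    h2o_d18O: float = 0.91

    def __post_init__(self) -> None:
        if not math.isfinite(self.h2o_d18O):
            raise InvalidMeasurementError("h2o_d18O must be finite")


def _check_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise InvalidMeasurementError(f"non-finite isotope value: {v!r}")


def site_preference(d15N_alpha, d15N_beta):
    """SP = d15N_alpha - d15N_beta (per-mil). Accepts scalars or arrays."""
    a = np.asarray(d15N_alpha, dtype=float)
    b = np.asarray(d15N_beta, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidMeasurementError("non-finite site delta")
    out = a - b
    return float(out) if out.ndim == 0 else out


def bulk_delta(d15N_alpha, d15N_beta):
    """Bulk d15N = (d15N_alpha + d15N_beta)/2 (per-mil)."""
    a = np.asarray(d15N_alpha, dtype=float)
    b = np.asarray(d15N_beta, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidMeasurementError("non-finite site delta")
    out = (a + b) / 2.0
    return float(out) if out.ndim == 0 else out


def calibrate_sp(raw_sp, cal: SPCalibrationPair):
    """Two-point linear calibration of a raw SP value.

    The affine map is fixed by requiring that each standard's measured
    value maps exactly to its true value.
    """
    slope = (cal.standard_b_true - cal.standard_a_true) / (
        cal.standard_b_measured - cal.standard_a_measured
    )
    raw = np.asarray(raw_sp, dtype=float)
    out = cal.standard_a_true + slope * (raw - cal.standard_a_measured)
    return float(out) if out.ndim == 0 else out


def o_exchange_correct(d18O_measured, params: OExchangeParams = OExchangeParams()):
    """Shift measured d18O (vs VSMOW) onto the N2O/H2O scale.

    Pure subtraction of the ambient-water d18O; sample-to-sample
    differences are preserved.
    """
    x = np.asarray(d18O_measured, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidMeasurementError("non-finite d18O")
    _check_finite(params.h2o_d18O)
    out = x - params.h2o_d18O
    return float(out) if out.ndim == 0 else out


def annotate_measurements(
    df: pd.DataFrame,
    cal: SPCalibrationPair | None = None,
    ox: OExchangeParams = OExchangeParams(),
) -> pd.DataFrame:
    """Augment a measurement table with d15N_bulk, sp and d18O_corrected.

    Parameters
    ----------
    df : DataFrame with columns sample_id, group, d15N_alpha, d15N_beta, d18O.
    cal : optional two-point SP calibration applied to the derived SP.
    ox : oxygen-exchange parameters (water d18O to subtract).
    """
    required = {"sample_id", "group", "d15N_alpha", "d15N_beta", "d18O"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"measurement table missing columns: {sorted(missing)}")
    out = df.copy()
    out["d15N_bulk"] = bulk_delta(df["d15N_alpha"].to_numpy(), df["d15N_beta"].to_numpy())
    sp = site_preference(df["d15N_alpha"].to_numpy(), df["d15N_beta"].to_numpy())
    if cal is not None:
        sp = calibrate_sp(sp, cal)
    out["sp"] = sp
    out["d18O_corrected"] = o_exchange_correct(df["d18O"].to_numpy(), ox)
    return out
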