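"""High-throughput qPCR quantity transforms.

Chip qPCR reports threshold cycles (Ct); with a 100%-efficiency standard
curve (slope 3.33 cycles per decade) and the detection limit at Ct = 31,
relative copy number is 10**((31 - Ct) / 3.33).  Functional-gene copies
are normalised per sample to the 16S rRNA reference, and the
(nirS + nirK)/nosZ ratio summarises the genetic balance between N2O
production (nitrite reductases) and consumption (N2O reductase).
Below-detection entries (Ct above the limit) propagate as missing values,
never as zeros: any ratio touching one is itself missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DETECTION_LIMIT_CT",
    "STANDARD_SLOPE",
    "relative_copy_number",
    "ct_table_to_abundance",
    "normalize_to_16S",
    "nir_nos_ratio",
    "cells_from_16S",
]

DETECTION_LIMIT_CT = 31.0
#: Cycles per ten-fold template change for a 100%-efficiency reaction.
STANDARD_SLOPE = 3.33


def relative_copy_number(
    ct, limit: float = DETECTION_LIMIT_CT, slope: float = STANDARD_SLOPE
):
    """Relative copies 10**((limit - ct)/slope); NaN above the limit.

    Scalar in, (value, detected) out; array in, (values, detected) arrays.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    arr = np.asarray(ct, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("Ct values must be positive")
    detected = arr <= limit
    vals = np.where(detected, 10.0 ** ((limit - arr) / slope), np.nan)
    if arr.ndim == 0:
        return float(vals), bool(detected)
    return vals, detected


def ct_table_to_abundance(
    ct_long: pd.DataFrame,
    limit: float = DETECTION_LIMIT_CT,
    slope: float = STANDARD_SLOPE,
) -> pd.DataFrame:
    """Long (sample_id, gene, ct) records -> wide sample x gene copy table.

    Below-detection cells are NaN.
    """
    required = {"sample_id", "gene", "ct"}
    missing = required - set(ct_long.columns)
    if missing:
        raise KeyError(f"Ct table missing columns: {sorted(missing)}")
    vals, _ = relative_copy_number(ct_long["ct"].to_numpy(), limit, slope)
    out = ct_long.assign(copies=vals).pivot_table(
        index="sample_id", columns="gene", values="copies", aggfunc="mean", dropna=False
    )
    out.columns.name = None
    return out


def normalize_to_16S(table: pd.DataFrame, reference: str = "16S") -> pd.DataFrame:
    """Divide each gene's relative copies by the sample's 16S copies.

    Samples with no detected 16S are dropped (the normalisation is
    undefined there); below-detection genes stay NaN.
    """
    if reference not in table.columns:
        raise KeyError(f"reference gene {reference!r} not in table")
    ref = table[reference]
    ok = ref.notna() & (ref > 0)
    out = table.loc[ok].div(ref[ok], axis=0)
    return out.drop(columns=[reference])


def nir_nos_ratio(table: pd.DataFrame) -> pd.Series:
    """(nirS + nirK)/nosZ per sample on normalised abundances.

    NaN wherever any operand is below detection or nosZ is zero.
    """
    for gene in ("nirS", "nirK", "nosZ"):
        if gene not in table.columns:
            raise KeyError(f"gene {gene!r} missing from abundance table")
    nos = table["nosZ"].where(table["nosZ"] > 0)
    return (table["nirS"] + table["nirK"]) / nos


def cells_from_16S(abundance_16S):
    """Cells per volume = absolute 16S copies / 4.1."""
    arr = np.asarray(abundance_16S, dtype=float)
    if np.any(arr < 0):
        raise ValueError("16S abundance must be >= 0")
    out = arr / 4.1
    return float(out) if out.ndim == 0 else out
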