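"""15N isotope-pairing rates and related quotients.

After spiking the nitrate pool to a 15N atom fraction F_n, denitrification
pairs two nitrate-derived N atoms at random, so labelled N2 appears as
30N2 (both heavy) and 29N2 (one heavy) in binomial proportion.  The
denitrification rate follows from the 30N2 production rate T30 as

    rate = T30 * 2 * (1 - F_n) / F_n + 2 * T30  ==  2 * T30 / F_n

Anammox pairs one nitrate-derived and one ammonium-derived N and so only
produces 29N2; its signal is the 29N2 excess over the binomial expectation
2*T30*(1-F_n)/F_n.  The acetylene block (inhibits N2O reductase) yields the
N2O reduction ratio f_R = residual/total N2O.  Cell-number normalisation
divides by 16S copies / 4.1 (median rRNA operon copy number).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "IPTMeasurement",
    "AcetylenePair",
    "CellNormalizer",
    "denitrification_rate",
    "denit_anammox_share",
    "codenitrification_indicator",
    "n2o_reduction_ratio",
    "per_cell",
    "co2_equivalent",
    "RRNA_COPIES_PER_CELL",
]

#: Median 16S rRNA operon copies per cell used to convert copies to cells.
RRNA_COPIES_PER_CELL = 4.1


@dataclass(frozen=True)
class IPTMeasurement:
    """One sample's labelled-N2 production rates.

    t29, t30: production rates of 29N2 and 30N2 (mass N per volume per
    time); fn: 15N atom fraction of the nitrate pool after pre-incubation
    (study value 0.99).
    """

    sample_id: str
    t29: float
    t30: float
    fn: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 < self.fn <= 1.0:
            raise ValueError(f"fn must be in (0, 1], got {self.fn}")
        if self.t29 < 0 or self.t30 < 0:
            raise ValueError("production rates must be >= 0")


@dataclass(frozen=True)
class AcetylenePair:
    """N2O concentrations without (residual) and with (total) acetylene."""

    n2o_without_c2h2: float
    n2o_with_c2h2: float

    def __post_init__(self) -> None:
        if self.n2o_without_c2h2 < 0 or self.n2o_with_c2h2 < 0:
            raise ValueError("concentrations must be >= 0")
        if self.n2o_without_c2h2 > self.n2o_with_c2h2:
            raise ValueError(
                "residual N2O exceeds total N2O: inconsistent acetylene pair"
            )


@dataclass(frozen=True)
class CellNormalizer:
    """Cell count per volume derived from absolute 16S copy numbers."""

    abundance_16S: float

    def __post_init__(self) -> None:
        if self.abundance_16S < 0:
            raise ValueError("16S abundance must be >= 0")

    @property
    def cells(self) -> float:
        return self.abundance_16S / RRNA_COPIES_PER_CELL


def denitrification_rate(m: IPTMeasurement) -> float:
    """Isotope-pairing denitrification rate; equals 2*t30/fn."""
    return m.t30 * 2.0 * (1.0 - m.fn) / m.fn + 2.0 * m.t30


def denit_anammox_share(m: IPTMeasurement) -> dict:
    """Partition N2 production between denitrification and anammox.

    Denitrification N2 = 2*t30/fn; anammox = 29N2 excess over the binomial
    denitrification expectation 2*t30*(1-fn)/fn, clipped at zero (a
    below-expectation t29 is flagged).  Returns shares summing to 1.
    """
    d = 2.0 * m.t30 / m.fn
    expected_29 = 2.0 * m.t30 * (1.0 - m.fn) / m.fn
    excess = m.t29 - expected_29
    clipped = excess < 0.0
    a = max(0.0, excess)
    total = d + a
    if total == 0.0:
        raise ZeroDivisionError("no N2 production: shares undefined")
    return {
        "share_denitrification": d / total,
        "share_anammox": a / total,
        "anammox_29N2_excess": a,
        "excess_clipped": clipped,
    }


def codenitrification_indicator(m: IPTMeasurement) -> float:
    """t30/(t29+t30): near 1 when labelling is denitrification-dominated.

    Codenitrification pairs one labelled with one unlabelled N and thus
    inflates 29N2; a low value of this ratio flags it.
    """
    total = m.t29 + m.t30
    if total == 0.0:
        raise ZeroDivisionError("t29 + t30 = 0: indicator undefined")
    return m.t30 / total


def n2o_reduction_ratio(p: AcetylenePair) -> float:
    """f_R = residual / total N2O, in [0, 1]."""
    if p.n2o_with_c2h2 == 0.0:
        raise ZeroDivisionError("total N2O is zero: ratio undefined")
    return p.n2o_without_c2h2 / p.n2o_with_c2h2


def per_cell(value: float, norm: CellNormalizer) -> float:
    """Normalise a per-volume quantity to per-cell."""
    cells = norm.cells
    if cells <= 0.0:
        raise ZeroDivisionError("zero cells: per-cell value undefined")
    return value / cells


def co2_equivalent(n2o_mass_rate: float, gwp_factor: float = 298.0) -> float:
    """CO2-equivalent of an N2O mass rate via a configurable GWP factor.

    The default factor 298 is a conventional 100-year GWP and is a
    configuration choice, not a measured quantity.
    """
    if n2o_mass_rate < 0:
        raise ValueError("rate must be >= 0")
    if gwp_factor < 0:
        raise ValueError("GWP factor must be >= 0")
    return n2o_mass_rate * gwp_factor
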