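"""Fluorometric amino-acid quantification and protein-depolymerisation rates.

Free amino acids are measured as OPAME (o-phthaldialdehyde / methanol /
3-mercaptopropionic acid) derivatives on a plate reader, calibrated with
leucine standard curves.  Ammonium also forms fluorescent derivatives with
the reagent, so sample fluorescence is corrected by an NH₄⁺ standard curve
before conversion to leucine equivalents.

Protein depolymerisation (proteolytic activity) is measured as amino-acid
accumulation in toluene-inhibited soil slurries: toluene blocks microbial
uptake of the reaction products, so the slurry amino-acid concentration
rises linearly and its slope, scaled by slurry volume per g soil DW, is
the gross amino-acid production rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import UG_N_PER_UMOL, fresh_to_dry


@dataclass(frozen=True)
class StandardCurve:
    """Linear fluorescence response of one analyte, RFU = slope·µM + intercept."""

    analyte: str  # 'leucine' | 'ammonium'
    slope: float  # RFU per µM
    intercept: float  # RFU
    r2: float

    @property
    def valid(self) -> bool:
        return self.slope > 0

    def fluorescence_of(self, conc_uM: float) -> float:
        """Fluorescence attributable to ``conc_uM`` of this analyte.

        The intercept is reagent background already captured by the buffer
        blank, so only the slope term is used (avoids double subtraction).
        """
        return self.slope * conc_uM


@dataclass(frozen=True)
class FluorometryRead:
    """One sample well plus its buffer-amended background well."""

    sample_id: str
    raw_fluorescence: float
    background_fluorescence: float
    nh4_conc_uM: float = 0.0

    def __post_init__(self) -> None:
        if self.raw_fluorescence < 0 or self.background_fluorescence < 0:
            raise ValueError("fluorescence must be nonnegative")


@dataclass(frozen=True)
class PoolConcentrations:
    """Plant-available N pools of one sample, µg N g⁻¹ DW (floored at 0)."""

    sample_id: str
    aa_ugN_per_gDW: float
    nh4_ugN_per_gDW: float
    no3_ugN_per_gDW: float
    extraction_ratio: float = 10.0
    qc_flags: frozenset[str] = frozenset()

    @property
    def total_ugN_per_gDW(self) -> float:
        return self.aa_ugN_per_gDW + self.nh4_ugN_per_gDW + self.no3_ugN_per_gDW


@dataclass(frozen=True)
class SlurryTimecourse:
    """Amino-acid accumulation time course of one toluene-inhibited slurry.

    Concentrations are on the slurry basis, i.e. the 1:1 TCA-stop dilution
    of the 1 mL subsamples has already been undone (see
    :func:`measured_to_slurry`).
    """

    sample_id: str
    times_h: tuple[float, ...] = (0.25, 4.0, 6.0)
    aa_conc_slurry_ugN_per_mL: tuple[float, ...] = ()
    soil_fw_g: float = 4.0
    water_mL: float = 40.0
    tca_dilution_factor: float = 2.0

    def __post_init__(self) -> None:
        if len(self.times_h) < 2:
            raise ValueError("need at least two timepoints")
        if len(self.times_h) != len(self.aa_conc_slurry_ugN_per_mL):
            raise ValueError("times and concentrations must have equal length")
        if any(b <= a for a, b in zip(self.times_h, self.times_h[1:])):
            raise ValueError("times must be strictly increasing")


def measured_to_slurry(conc_measured: float, tca_dilution_factor: float = 2.0) -> float:
    """Undo the TCA-stop dilution: supernatant reading → slurry concentration."""
    return conc_measured * tca_dilution_factor


def fit_standard_curve(
    concentrations_uM: Sequence[float],
    fluorescence: Sequence[float],
    analyte: str,
) -> StandardCurve:
    """Ordinary least-squares standard curve for one analyte.

    Raises ``ValueError`` if all concentrations are identical (no spread to
    fit a slope).  A non-positive slope is returned but flagged invalid via
    :attr:`StandardCurve.valid`.
    """
    x = np.asarray(concentrations_uM, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need at least two distinct standard concentrations")
    res = stats.linregress(x, y)
    return StandardCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
    )


def amino_acid_concentration(
    read: FluorometryRead,
    leu_curve: StandardCurve,
    nh4_curve: StandardCurve,
) -> tuple[float, bool]:
    """Amino-acid concentration in the measured solution, µM leucine equivalents.

    ``AA = (raw − background − nh4_slope·[NH4+]) / leu_slope``.  Negative
    results are floored to 0; the second return value is True when flooring
    occurred (QC flag).
    """
    if not leu_curve.valid:
        raise ValueError("leucine standard curve has non-positive slope")
    corrected = (
        read.raw_fluorescence
        - read.background_fluorescence
        - nh4_curve.fluorescence_of(read.nh4_conc_uM)
    )
    aa = corrected / leu_curve.slope
    if aa < 0:
        return 0.0, True
    return float(aa), False


def extract_to_soil_basis(
    conc_in_extract_ugN_per_mL: float,
    extraction_ratio: float,
    moisture_frac: float,
) -> float:
    """Convert an extract concentration to a soil-DW basis.

    The 1:10 (w/w) extraction gives ``extraction_ratio`` mL extractant per
    g fresh soil (density 1 assumed), so

    ``µg N g⁻¹ DW = conc × extraction_ratio / (1 − moisture_frac)``.
    """
    if extraction_ratio <= 0:
        raise ValueError("extraction_ratio must be positive")
    if not 0.0 <= moisture_frac < 1.0:
        raise ValueError("moisture_frac must be in [0,1)")
    return conc_in_extract_ugN_per_mL * extraction_ratio / (1.0 - moisture_frac)


def soil_basis_to_extract(
    conc_ugN_per_gDW: float, extraction_ratio: float, moisture_frac: float
) -> float:
    """Inverse of :func:`extract_to_soil_basis` (used by the simulator)."""
    return conc_ugN_per_gDW * (1.0 - moisture_frac) / extraction_ratio


def uM_to_ugN_per_mL(conc_uM: float) -> float:
    """µM of a 1-N-atom analyte (leucine equivalents) → µg N mL⁻¹."""
    return conc_uM * UG_N_PER_UMOL / 1000.0


def ugN_per_mL_to_uM(conc_ugN_per_mL: float) -> float:
    return conc_ugN_per_mL * 1000.0 / UG_N_PER_UMOL


def depolymerisation_rate(
    tc: SlurryTimecourse, moisture_frac: float
) -> tuple[float, bool]:
    """Gross amino-acid production rate, µg N g⁻¹ DW h⁻¹.

    OLS slope of the slurry amino-acid concentration (µg N mL⁻¹) against
    time (h), scaled by slurry water volume and divided by soil dry weight.
    A negative slope is reported as-is with the QC flag (second return
    value) set; flooring is left to the reporting layer.
    """
    t = np.asarray(tc.times_h, dtype=float)
    y = np.asarray(tc.aa_conc_slurry_ugN_per_mL, dtype=float)
    slope = float(stats.linregress(t, y).slope)
    dw = fresh_to_dry(tc.soil_fw_g, moisture_frac)
    if dw <= 0:
        raise ValueError("soil dry weight must be positive")
    rate = slope * tc.water_mL / dw
    return rate, rate < 0


__all__ = [
    "StandardCurve", "FluorometryRead", "PoolConcentrations",
    "SlurryTimecourse", "measured_to_slurry", "fit_standard_curve",
    "amino_acid_concentration", "extract_to_soil_basis",
    "soil_basis_to_extract", "uM_to_ugN_per_mL", "ugN_per_mL_to_uM",
    "depolymerisation_rate",
]
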