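"""Colorimetric formaldehyde quantification and translation-assay ratios.

Formaldehyde in culture supernatants is measured with the Nash assay
(read at 432 nm) and in cell lysates with the Purpald assay (550 nm),
each calibrated against a same-day standard curve.  Lysate
concentrations are converted to intracellular concentrations by
normalizing to the total cell volume harvested:

    C_int = C_lysate * V_extraction / (CFU/mL * V_culture * v_cell)

with v_cell the average single-cell volume (2.63 fL/CFU).  New protein
synthesis is tracked by the GC/MS peak-area ratio of heavy-labeled
(13CD3, 222 m/z) to unlabeled (218 m/z) methionine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

ASSAYS = {"nash": 432, "purpald": 550}


@dataclass
class Calibration:
    """Linear standard curve: absorbance = slope * concentration + intercept."""

    assay: str
    slope: float  # absorbance per mM
    intercept: float
    r_squared: float
    n_standards: int


@dataclass
class BackCalculated:
    """A back-calculated concentration; below-blank readings floor at 0."""

    conc_mM: float
    below_blank: bool = False


@dataclass
class LysateProtocol:
    """Volumes of the lysate-preparation protocol used for normalization."""

    extraction_volume_ml: float = 1.5
    culture_volume_ml: float = 50.0
    cell_volume_fl: float = 2.63

    def __post_init__(self) -> None:
        if min(self.extraction_volume_ml, self.culture_volume_ml, self.cell_volume_fl) <= 0:
            raise ValidationError("lysate protocol volumes must be positive")


def fit_standard_curve(
    concentrations_mM: Sequence[float],
    absorbances: Sequence[float],
    assay: str = "nash",
) -> Calibration:
    """OLS standard curve from >= 3 standards at distinct concentrations."""
    if assay not in ASSAYS:
        raise ValidationError(f"assay must be one of {sorted(ASSAYS)}")
    c = np.asarray(concentrations_mM, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if len(c) != len(a):
        raise ValidationError("standards and absorbances must match in length")
    if len(np.unique(c)) < 3:
        raise ValidationError("need at least 3 standards at distinct concentrations")
    res = stats.linregress(c, a)
    return Calibration(assay, float(res.slope), float(res.intercept),
                       float(res.rvalue**2), len(c))


def conc_from_absorbance(
    cal: Calibration,
    absorbance: float,
    dilution_factor: float = 1.0,
) -> BackCalculated:
    """Back-calculate a sample concentration (mM) from its absorbance.

    Readings below the calibration intercept (the blank) floor at 0 mM
    with ``below_blank`` set.
    """
    if cal.slope <= 0:
        raise ValidationError("invalid calibration: slope must be positive")
    if dilution_factor < 1:
        raise ValidationError("dilution factor must be >= 1")
    conc = dilution_factor * (absorbance - cal.intercept) / cal.slope
    if conc < 0:
        return BackCalculated(0.0, below_blank=True)
    return BackCalculated(float(conc))


def intracellular_concentration(
    lysate_conc_mM: float,
    cfu_per_ml: float,
    protocol: LysateProtocol | None = None,
) -> float:
    """Intracellular formaldehyde concentration (mM) from a lysate reading.

    The lysate concentration is scaled by the ratio of extraction volume
    to total cell volume in the harvested culture (CFU/mL x culture
    volume x per-cell volume, with 1 fL = 1e-12 mL).  Both sides are
    molar concentrations, so the result is in mM directly.
    """
    protocol = protocol or LysateProtocol()
    if lysate_conc_mM < 0:
        raise ValidationError("lysate concentration must be nonnegative")
    if cfu_per_ml <= 0:
        raise ValidationError("CFU/mL must be positive to normalize to cell volume")
    total_cell_volume_ml = (
        cfu_per_ml * protocol.culture_volume_ml * protocol.cell_volume_fl * 1e-12
    )
    return lysate_conc_mM * protocol.extraction_volume_ml / total_cell_volume_ml


def met_incorporation(peak_218: float, peak_222: float) -> float:
    """Labeled/unlabeled methionine ratio (222 m/z over 218 m/z peak areas).

    Rises with incorporation of heavy-labeled Met into new protein; 0
    means no incorporation.
    """
    if peak_218 <= 0:
        raise ValidationError("218 m/z (unlabeled Met) peak area must be positive")
    if peak_222 < 0:
        raise ValidationError("peak areas must be nonnegative")
    return peak_222 / peak_218


def met_incorporation_series(
    peaks_218: Sequence[float],
    peaks_222: Sequence[float],
) -> np.ndarray:
    """Per-timepoint incorporation ratios for a translation trajectory."""
    a218 = np.asarray(peaks_218, dtype=float)
    a222 = np.asarray(peaks_222, dtype=float)
    if a218.shape != a222.shape:
        raise ValidationError("peak-area series must have matching shapes")
    return np.array([met_incorporation(a, b) for a, b in zip(a218, a222)])
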