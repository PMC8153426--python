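"""Formaldehyde tolerance distributions from dilution-plating data.

Tolerance is a per-cell, nongenetic trait: the highest formaldehyde
concentration at which a given cell can found a colony.  Plating a
clonal population on agar at increasing formaldehyde concentrations and
expressing CFU(c) relative to CFU on formaldehyde-free medium yields a
frequency distribution of tolerant cells.  This module builds those
curves, computes the assay's limit of detection, fits the log-linear
decline slope of the tail, and compares slopes between genotypes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .dilution import CfuEstimate, detection_limit_density
from .errors import DegenerateFitWarning, UndefinedBaselineError, ValidationError


@dataclass
class ToleranceCurve:
    """Tolerant-cell frequency versus formaldehyde concentration (mM).

    Frequencies are CFU(c)/CFU(0 mM); the value at 0 mM is 1 by
    construction.  ``below_lod`` marks concentrations where no colonies
    were seen (frequency stored as 0, plotted against the detection
    limit by convention).
    """

    concentrations: tuple[float, ...]
    frequency_mean: tuple[float, ...]
    frequency_sd: tuple[float, ...]
    n_replicates: int
    lod_frequency: float
    below_lod: tuple[bool, ...]

    def frequency_at(self, c: float) -> float:
        return self.frequency_mean[self.concentrations.index(c)]


@dataclass
class SlopeFit:
    """OLS fit of log10(frequency) on concentration over selected points."""

    slope: float  # log10 frequency per mM
    intercept: float
    slope_se: float
    n_points: int
    points_used: tuple[float, ...]


@dataclass
class SlopeComparison:
    statistic: float
    df: float
    p_value: float


@dataclass
class DetectionLimit:
    min_density_cfu_per_ml: int
    min_frequency: float


def frequency_curve(
    estimates_by_conc: Mapping[float, CfuEstimate | Sequence[CfuEstimate]],
    lod_frequency: float = float("nan"),
) -> ToleranceCurve:
    """Build a tolerance curve from per-concentration replicate estimates.

    The baseline is the mean CFU over the 0 mM replicates; every
    replicate estimate at concentration c is divided by it, and the
    per-concentration mean and sample SD of those replicate frequencies
    are reported.  Censored (all-zero) replicates contribute frequency 0
    and are flagged below the detection limit.
    """
    groups: dict[float, list[CfuEstimate]] = {}
    for c, est in estimates_by_conc.items():
        groups[float(c)] = list(est) if isinstance(est, Sequence) else [est]
    if 0.0 not in groups:
        raise ValidationError("a 0 mM (formaldehyde-free) baseline is required")
    base = groups[0.0]
    base_mean = float(np.mean([e.cfu_per_ml for e in base]))
    if base_mean <= 0 or all(e.censored for e in base):
        raise UndefinedBaselineError("baseline CFU at 0 mM is zero or censored")

    concs = tuple(sorted(groups))
    means, sds, flags = [], [], []
    n_rep = max(len(g) for g in groups.values())
    for c in concs:
        freqs = np.array([e.cfu_per_ml / base_mean for e in groups[c]])
        means.append(float(freqs.mean()))
        sds.append(float(freqs.std(ddof=1)) if len(freqs) > 1 else 0.0)
        flags.append(bool(freqs.mean() == 0.0))
    return ToleranceCurve(concs, tuple(means), tuple(sds), n_rep, lod_frequency, tuple(flags))


def detection_limit(
    spot_volume_ml: float,
    spots_per_sample: int,
    population_density: float,
    rounding: str = "floor",
) -> DetectionLimit:
    """Limit of detection of the spot-plating tolerance assay.

    ``min_density`` is the smallest density giving one expected colony
    across the plated volume, rounded up to a whole CFU/mL.  The
    frequency limit divides a density threshold by the total population
    density; ``rounding`` selects the threshold basis used for it:
    ``"unrounded"`` (1/(v*s)), ``"floor"`` or ``"ceil"``.  The floor
    basis is the default (33/(2e8) = 1.65e-7 at the standard 3 x 10 uL
    geometry and 2e8 CFU/mL population).
    """
    if population_density <= 0:
        raise ValidationError("population density must be positive")
    min_density = detection_limit_density(spot_volume_ml, spots_per_sample)
    raw = 1.0 / (spot_volume_ml * spots_per_sample)
    basis = {"unrounded": raw, "floor": math.floor(raw), "ceil": math.ceil(raw)}
    try:
        threshold = basis[rounding]
    except KeyError:
        raise ValidationError(f"rounding must be one of {sorted(basis)}, got {rounding!r}")
    return DetectionLimit(min_density, threshold / population_density)


def decline_slope(
    curve: ToleranceCurve,
    selection: str = "last_k_nonzero",
    k: int = 4,
    points: Sequence[float] | None = None,
) -> SlopeFit:
    """Fit the log-linear decline of tolerant-cell frequency.

    ``selection`` picks the concentrations entering the fit:
    ``"last_k_nonzero"`` the k highest concentrations with frequency > 0
    (the rule used for wild-type-shaped curves); ``"last_k"`` the k
    highest concentrations outright (mutant-shaped curves, which stay
    nonzero); ``"explicit"`` the ``points`` list.  Ordinary least
    squares of log10(frequency) on concentration (mM).
    """
    concs = np.array(curve.concentrations)
    freqs = np.array(curve.frequency_mean)
    if selection == "explicit":
        if points is None:
            raise ValidationError("selection='explicit' requires points")
        sel = np.array([c in set(points) for c in concs])
        if sel.sum() != len(points):
            raise ValidationError("explicit points must be a subset of curve concentrations")
    elif selection == "last_k":
        sel = np.zeros(len(concs), bool)
        sel[-k:] = True
        if np.any(freqs[sel] <= 0):
            raise ValidationError(
                "zero frequency inside a last_k selection; use selection='last_k_nonzero'"
            )
    elif selection == "last_k_nonzero":
        nz = np.flatnonzero(freqs > 0)
        sel = np.zeros(len(concs), bool)
        sel[nz[-k:]] = True
    else:
        raise ValidationError(f"unknown selection rule {selection!r}")

    x = concs[sel]
    y = freqs[sel]
    if len(x) < 2:
        raise ValidationError("slope fit needs at least 2 points")
    if np.any(y <= 0):
        raise ValidationError("selected frequencies must be positive for the log transform")
    logy = np.log10(y)
    if np.allclose(logy, logy[0]):
        return SlopeFit(0.0, float(logy[0]), 0.0, len(x), tuple(float(c) for c in x))
    res = stats.linregress(x, logy)
    return SlopeFit(
        float(res.slope), float(res.intercept), float(res.stderr),
        len(x), tuple(float(c) for c in x),
    )


def compare_slopes(a: SlopeFit, b: SlopeFit) -> SlopeComparison:
    """Two-sided Welch t test on the difference of two OLS slopes.

    t = (b_a - b_b)/sqrt(se_a^2 + se_b^2) with Welch-Satterthwaite
    degrees of freedom built from each fit's residual df (n_points - 2).
    """
    if a.n_points < 3 or b.n_points < 3:
        raise ValidationError("slope comparison needs fits with >= 3 points each")
    se2 = a.slope_se**2 + b.slope_se**2
    if se2 == 0.0:
        if a.slope == b.slope:
            return SlopeComparison(0.0, float("inf"), 1.0)
        warnings.warn(
            "both slope fits have zero standard error with unequal slopes",
            DegenerateFitWarning,
        )
        return SlopeComparison(float("inf"), float("inf"), 0.0)
    df_a, df_b = a.n_points - 2, b.n_points - 2
    num = se2**2
    den = 0.0
    if a.slope_se > 0:
        den += a.slope_se**4 / df_a
    if b.slope_se > 0:
        den += b.slope_se**4 / df_b
    df = num / den
    t = (a.slope - b.slope) / math.sqrt(se2)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return SlopeComparison(float(t), float(df), min(p, 1.0))
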