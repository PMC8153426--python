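"""Growth-curve metrics and formaldehyde-resistance summaries.

Lag time, exponential rate and maximum density are extracted from
OD600 time series with a sliding-window log-linear fit: the rate is the
steepest OLS slope of ln(OD) over any window, and the lag is where that
tangent crosses the initial OD level.  Resistance panels reduce a set
of growth fits across formaldehyde concentrations to presence/absence
of growth and the highest permissive concentration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import NoGrowthWarning, ValidationError


@dataclass
class GrowthFit:
    """Lag (h), exponential rate (per h), and maximum OD of one curve."""

    lag_h: float
    rate_per_h: float
    max_od: float
    window: tuple[float, float]
    init_od: float
    no_growth: bool = False


@dataclass
class ResistancePanel:
    """Presence/absence of growth across a formaldehyde panel."""

    concentrations: tuple[float, ...]
    grew: tuple[bool, ...]
    max_permissive_mM: float | None
    right_censored: bool = False  # growth even at the highest tested dose


def fit_growth(
    times_h: Sequence[float],
    od: Sequence[float],
    window_length: int = 5,
    od_floor: float = 1e-3,
    max_ln_rmse: float = 0.05,
) -> GrowthFit:
    """Sliding-window log-linear growth fit.

    The rate is the steepest OLS slope of ln(OD) over contiguous
    windows of ``window_length`` points (ln(OD) is smoothed with a
    3-point moving average first; readings are floored at ``od_floor``
    before the log).  Near-blank ODs carry huge relative noise after
    the log transform, so windows whose residual RMSE exceeds
    ``max_ln_rmse`` (5% relative scatter) are ignored unless no window
    qualifies.  All steps are exact on noise-free exponentials.  The
    lag is where the winning tangent intersects the initial OD level
    (clipped at 0).  A curve with no positive-slope window gets rate 0,
    lag NaN and the ``no_growth`` flag.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(od, dtype=float)
    if len(t) != len(y):
        raise ValidationError("time and OD arrays must match")
    if len(t) < 5:
        raise ValidationError("need at least 5 timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("timepoints must be strictly increasing")
    if window_length < 3 or window_length > len(t) - 2:
        raise ValidationError("window_length must be in [3, n_points - 2]")

    lny = np.log(np.clip(y, od_floor, None))
    lny_s = np.convolve(lny, np.ones(3) / 3.0, mode="valid")
    t_s = t[1:-1]
    windows = []
    for i in range(len(t_s) - window_length + 1):
        tw = t_s[i : i + window_length]
        yw = lny_s[i : i + window_length]
        sl, ic = np.polyfit(tw, yw, 1)
        # quality is judged against the raw (unsmoothed) points: the
        # moving average hides noise-floor scatter from the residuals
        raw = lny[i + 1 : i + 1 + window_length]
        rmse = float(np.sqrt(np.mean((raw - (sl * tw + ic)) ** 2)))
        windows.append((sl, ic, rmse, (float(tw[0]), float(tw[-1]))))
    clean = [w for w in windows if w[2] <= max_ln_rmse]
    best_slope, best_icpt, _, best_win = max(clean or windows, key=lambda w: w[0])

    smoothed = np.convolve(y, np.ones(3) / 3.0, mode="valid")
    max_od = float(smoothed.max())
    init_od = float(y[0])

    if best_slope <= 1e-9:  # numerically flat counts as no growth
        warnings.warn("no positive-slope window found; flagging no growth", NoGrowthWarning)
        return GrowthFit(float("nan"), 0.0, max_od, best_win, init_od, no_growth=True)

    lag = (math.log(max(init_od, 1e-6)) - best_icpt) / best_slope
    lag = min(max(lag, 0.0), float(t[-1]))
    return GrowthFit(float(lag), float(best_slope), max_od, best_win, init_od)


def resistance_summary(
    fits_by_conc: Mapping[float, GrowthFit],
    growth_threshold: float = 0.05,
) -> ResistancePanel:
    """Reduce per-concentration growth fits to a resistance panel.

    A concentration counts as permissive when the OD gain
    (max_od - init_od) reaches ``growth_threshold`` and the fit is not
    flagged no-growth.  ``max_permissive_mM`` is the largest such
    concentration (None if none grew; right-censored if all grew).
    """
    if len(fits_by_conc) < 2:
        raise ValidationError("a resistance panel needs at least 2 concentrations")
    fits = {float(c): f for c, f in fits_by_conc.items()}
    concs = tuple(sorted(fits))
    grew = tuple(
        (not fits[c].no_growth) and (fits[c].max_od - fits[c].init_od) >= growth_threshold
        for c in concs
    )
    permissive = [c for c, g in zip(concs, grew) if g]
    if not permissive:
        return ResistancePanel(concs, grew, None)
    return ResistancePanel(
        concs, grew, max(permissive), right_censored=all(grew)
    )
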