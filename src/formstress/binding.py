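"""Ligand-binding model fitting for calorimetry and thermophoresis data.

Two independent biophysical readouts of protein:ligand affinity are
supported:

* **ITC** — per-injection heats from titrating ligand into protein are
  blank-subtracted (buffer:ligand heats of dilution) and fitted with the
  single-set-of-identical-sites (Wiseman) isotherm for stoichiometry n,
  dissociation constant Kd and molar enthalpy dH.  The cumulative heat
  after the i-th injection is

      Q_i = n*Mt_i*dH*V0/2 * [1 + r + k - sqrt((1 + r + k)^2 - 4r)]

  with r = Lt/(n*Mt), k = Kd/(n*Mt) and the usual displaced-volume
  corrections for the running totals Mt_i (cell protein) and Lt_i
  (titrant).  Per-injection heats include the perfusion term
  dQ_i = Q_i - Q_{i-1} + (dV_i/V0)(Q_i + Q_{i-1})/2.

* **MST** — normalized fluorescence versus titrant concentration fitted
  with the Hill equation

      F(c) = F_min + (F_max - F_min) * c^n / (c^n + Kd^n)

  (a ``strict_printed_form`` flag drops the F_min baseline for parity
  with literature fits that force F(0) = 0).

Units: heats are handled in uJ internally; dH is reported in kcal/mol
(1 cal = 4.184 J).  Concentrations are mM, volumes uL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    FitConvergenceError,
    FlatCurveError,
    UnitMismatchError,
    UnidentifiableKdWarning,
    ValidationError,
)

CAL_TO_J = 4.184


def ucal_to_uj(x):
    """Convert microcalories to microjoules."""
    return np.asarray(x, dtype=float) * CAL_TO_J


@dataclass
class ItcProtocol:
    """Injection schedule and cell contents of a microcalorimetry run.

    ``n_injections`` counts every injection including the initial
    throw-away: the first injection delivers ``discard_first_ul`` and is
    flagged ``excluded`` from all fits, the remaining n-1 deliver
    ``injection_volume_ul`` each.
    """

    cell_volume_ul: float = 400.0
    n_injections: int = 20
    injection_volume_ul: float = 2.0
    discard_first_ul: float = 0.3
    interval_s: float = 200.0
    syringe_ligand_mM: float = 25.0
    cell_protein_uM: float = 50.0
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        if min(
            self.cell_volume_ul, self.injection_volume_ul, self.discard_first_ul,
            self.syringe_ligand_mM, self.cell_protein_uM,
        ) <= 0:
            raise ValidationError("ITC protocol volumes and concentrations must be positive")
        if self.n_injections < 2:
            raise ValidationError("need at least 2 injections (throw-away + 1)")

    @property
    def injection_volumes_ul(self) -> np.ndarray:
        v = np.full(self.n_injections, self.injection_volume_ul)
        v[0] = self.discard_first_ul
        return v

    @property
    def excluded(self) -> np.ndarray:
        """Mask of injections excluded from fitting (the throw-away)."""
        mask = np.zeros(self.n_injections, dtype=bool)
        mask[0] = True
        return mask


@dataclass
class ItcExperiment:
    """Per-injection heats of a sample run and its buffer:ligand blank."""

    protocol: ItcProtocol
    sample_heats: Sequence[float]
    blank_heats: Sequence[float]
    sample_units: str = "uJ"
    blank_units: str = "uJ"

    def __post_init__(self) -> None:
        self.sample_heats = np.asarray(self.sample_heats, dtype=float)
        self.blank_heats = np.asarray(self.blank_heats, dtype=float)
        n = self.protocol.n_injections
        if len(self.sample_heats) != n or len(self.blank_heats) != n:
            raise ValidationError("heat arrays must match the protocol's injection count")
        for u in (self.sample_units, self.blank_units):
            if u not in ("uJ", "ucal"):
                raise ValidationError(f"units must be 'uJ' or 'ucal', got {u!r}")


@dataclass
class ItcModel:
    """Single-set-of-sites binding model: stoichiometry, affinity, enthalpy."""

    n_sites: float
    Kd_mM: float
    dH_kcal_per_mol: float

    def __post_init__(self) -> None:
        if self.Kd_mM <= 0:
            raise ValidationError("Kd must be positive")
        if self.n_sites <= 0:
            raise ValidationError("stoichiometry must be positive")


@dataclass
class ItcFit:
    model: ItcModel
    se_n: float
    se_Kd: float
    se_dH: float
    residuals_uJ: np.ndarray = field(repr=False, default=None)


@dataclass
class HillModel:
    """Hill dose-response model for normalized fluorescence (per-mil)."""

    F_max: float
    F_min: float
    Kd_mM: float
    n: float

    def __post_init__(self) -> None:
        if self.Kd_mM <= 0:
            raise ValidationError("Kd must be positive")
        if self.n <= 0:
            raise ValidationError("Hill coefficient must be positive")
        if self.F_max < self.F_min:
            raise ValidationError("F_max must be >= F_min")


@dataclass
class HillFit:
    model: HillModel
    se_F_max: float
    se_F_min: float
    se_Kd: float
    se_n: float
    residuals: np.ndarray = field(repr=False, default=None)


def hill_response(c, F_max, F_min, Kd, n):
    """Hill equation with baseline: F_min + (F_max - F_min) c^n/(c^n + Kd^n)."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(c > 0, c**n / (c**n + Kd**n), 0.0)
    return F_min + (F_max - F_min) * frac


def subtract_blank(exp: ItcExperiment) -> np.ndarray:
    """Blank-corrected heats (uJ) with the throw-away injection removed.

    Subtracting the buffer:ligand titration removes the heat of dilution
    of ligand into the cell.  Units must match; no silent conversion.
    """
    if exp.sample_units != exp.blank_units:
        raise UnitMismatchError(
            f"sample heats in {exp.sample_units}, blank in {exp.blank_units}: convert first"
        )
    corrected = exp.sample_heats - exp.blank_heats
    if exp.sample_units == "ucal":
        corrected = ucal_to_uj(corrected)
    return corrected[~exp.protocol.excluded]


def itc_forward(model: ItcModel, protocol: ItcProtocol) -> np.ndarray:
    """Per-injection heats (uJ) for every injection, throw-away included.

    Running totals use the standard overfill displacement correction
    Mt_i = M0 (1 - dV/2V0)/(1 + dV/2V0), Lt_i = L_syr (dV/V0)(1 - dV/2V0)
    with dV the cumulative injected volume.
    """
    v = protocol.injection_volumes_ul
    V0 = protocol.cell_volume_ul
    dV = np.cumsum(v)
    M0 = protocol.cell_protein_uM * 1e-6  # mol/L
    Lsyr = protocol.syringe_ligand_mM * 1e-3
    Kd = model.Kd_mM * 1e-3
    dH = model.dH_kcal_per_mol * 1e3 * CAL_TO_J  # J/mol
    n = model.n_sites

    Mt = M0 * (1 - dV / (2 * V0)) / (1 + dV / (2 * V0))
    Lt = Lsyr * (dV / V0) * (1 - dV / (2 * V0))
    r = Lt / (n * Mt)
    k = Kd / (n * Mt)
    b = 1.0 + r + k
    Q = n * Mt * dH * (V0 * 1e-6) / 2.0 * (b - np.sqrt(b * b - 4.0 * r))  # J
    Qprev = np.concatenate(([0.0], Q[:-1]))
    dQ = Q - Qprev + (v / V0) * (Q + Qprev) / 2.0
    return dQ * 1e6


def fit_itc(
    corrected_heats: Sequence[float],
    protocol: ItcProtocol,
    fix_n: float | None = None,
    p0: tuple[float, float, float] | None = None,
) -> ItcFit:
    """Nonlinear least squares of the one-site isotherm on corrected heats.

    ``corrected_heats`` (uJ) cover the fitted injections only (the
    throw-away excluded, as returned by :func:`subtract_blank`).  At low
    Wiseman c (= n*M0/Kd << 1, weak binding or dilute protein) n and dH
    are strongly anti-correlated; fix the stoichiometry via ``fix_n``
    there, per standard calorimetric practice.
    """
    q = np.asarray(corrected_heats, dtype=float)
    n_fit = protocol.n_injections - int(protocol.excluded.sum())
    if len(q) != n_fit:
        raise ValidationError(f"expected {n_fit} fitted heats, got {len(q)}")
    if n_fit < 6:
        raise ValidationError("need at least 6 fitted injections")

    keep = ~protocol.excluded
    if np.max(np.abs(q)) < 1e-9:
        warnings.warn(
            "all heats are zero: no binding signal, Kd unidentifiable",
            UnidentifiableKdWarning,
        )
        return ItcFit(ItcModel(fix_n or 1.0, 1.0, 0.0), 0.0, float("inf"),
                      float("inf"), q.copy())

    # tight-binding estimate of dH from the first fitted injection
    mol_inj = protocol.injection_volume_ul * 1e-6 * protocol.syringe_ligand_mM * 1e-3
    dH0 = q[0] * 1e-6 / mol_inj / (1e3 * CAL_TO_J) if mol_inj > 0 else -1.0
    if not np.isfinite(dH0) or dH0 == 0:
        dH0 = -1.0
    # stoichiometry guess from the molar ratio at the steepest heat change
    # (informative only when the titration actually saturates)
    v = protocol.injection_volumes_ul
    dV = np.cumsum(v)
    V0 = protocol.cell_volume_ul
    ratio = (protocol.syringe_ligand_mM * 1e-3 * (dV / V0) * (1 - dV / (2 * V0))) / (
        protocol.cell_protein_uM * 1e-6 * (1 - dV / (2 * V0)) / (1 + dV / (2 * V0)))
    ratio = ratio[keep]
    n0 = 1.0
    if np.abs(q[-1]) < 0.25 * np.abs(q[0]):
        n0 = float(np.clip(ratio[np.argmax(np.abs(np.diff(q)))], 0.05, 100.0))

    if fix_n is None:
        def predict(_x, n_sites, Kd, dH):
            return itc_forward(ItcModel(n_sites, Kd, dH), protocol)[keep]
        starts = [p0] if p0 else [
            (n0, kd0, dH0) for kd0 in (0.01, 1.0, 100.0)
        ] + [(1.0, 1.0, dH0)]
        bounds = ([1e-3, 1e-9, -1e6], [1e3, 1e4, 1e6])
    else:
        def predict(_x, Kd, dH):
            return itc_forward(ItcModel(fix_n, Kd, dH), protocol)[keep]
        starts = [p0] if p0 else [(kd0, dH0) for kd0 in (0.01, 1.0, 100.0)]
        bounds = ([1e-9, -1e6], [1e4, 1e6])

    x = np.arange(n_fit)
    best = None
    last_err: Exception | None = None
    for start in starts:
        try:
            popt, pcov = curve_fit(
                predict, x, q, p0=start, bounds=bounds, maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except RuntimeError as err:
            last_err = err
            continue
        ssr = float(np.sum((q - predict(x, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise FitConvergenceError(f"ITC fit did not converge: {last_err}")
    _, popt, pcov = best

    se = np.sqrt(np.diag(pcov))
    if fix_n is None:
        model = ItcModel(popt[0], popt[1], popt[2])
        fit = ItcFit(model, float(se[0]), float(se[1]), float(se[2]))
    else:
        model = ItcModel(fix_n, popt[0], popt[1])
        fit = ItcFit(model, 0.0, float(se[0]), float(se[1]))
    fit.residuals_uJ = q - predict(x, *popt)

    if not np.isfinite(fit.se_Kd) or fit.se_Kd > 10 * model.Kd_mM:
        warnings.warn(
            "Kd is effectively unconstrained by these heats (flat or saturated isotherm)",
            UnidentifiableKdWarning,
        )
    return fit


def fit_hill(
    concentrations: Sequence[float],
    f_norm: Sequence[float],
    strict_printed_form: bool = False,
) -> HillFit:
    """Fit the Hill equation to a normalized-fluorescence dose response.

    Initial guesses come from the data: F_min/F_max from the extreme
    responses, Kd from the concentration nearest half-response, n = 1.
    ``strict_printed_form`` omits the F_min baseline so that F(0) = 0.
    """
    c = np.asarray(concentrations, dtype=float)
    f = np.asarray(f_norm, dtype=float)
    if len(c) != len(f):
        raise ValidationError("concentration and response arrays must match")
    if np.any(c < 0):
        raise ValidationError("concentrations must be nonnegative")
    if len(np.unique(c)) < 5:
        raise ValidationError("need at least 5 distinct concentrations")
    if np.ptp(f) == 0:
        raise FlatCurveError("constant response: no binding signal to fit")

    fmin0, fmax0 = float(f.min()), float(f.max())
    half = (fmin0 + fmax0) / 2.0
    kd0 = float(c[np.argmin(np.abs(f - half))])
    if kd0 <= 0:
        kd0 = float(np.median(c[c > 0]))

    # Fit (baseline, amplitude >= 0, Kd, n): F_max = F_min + amplitude is
    # then >= F_min by construction.  The strict printed form drops the
    # baseline so that F(0) = 0.
    def _frac(cc, Kd, n):
        cc = np.asarray(cc, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(cc > 0, cc**n / (cc**n + Kd**n), 0.0)

    if strict_printed_form:
        def predict(cc, amplitude, Kd, n):
            return amplitude * _frac(cc, Kd, n)
        start = (max(fmax0 - fmin0, 1e-9), kd0, 1.0)
        bounds = ([0.0, 1e-12, 0.05], [np.inf, 1e6, 20.0])
    else:
        def predict(cc, F_min, amplitude, Kd, n):
            return F_min + amplitude * _frac(cc, Kd, n)
        start = (fmin0, max(fmax0 - fmin0, 1e-9), kd0, 1.0)
        bounds = ([-np.inf, 0.0, 1e-12, 0.05], [np.inf, np.inf, 1e6, 20.0])

    try:
        popt, pcov = curve_fit(
            predict, c, f, p0=start, bounds=bounds,
            maxfev=20000, xtol=1e-14, ftol=1e-14,
        )
    except RuntimeError as err:
        raise FitConvergenceError(f"Hill fit did not converge: {err}") from err

    se = np.sqrt(np.diag(pcov))
    if strict_printed_form:
        amp, kd, nn = popt
        model = HillModel(F_max=amp, F_min=0.0, Kd_mM=kd, n=nn)
        fit = HillFit(model, float(se[0]), 0.0, float(se[1]), float(se[2]))
    else:
        fmin, amp, kd, nn = popt
        # var(F_max) = var(F_min) + var(A) + 2 cov(F_min, A)
        var_fmax = pcov[0, 0] + pcov[1, 1] + 2.0 * pcov[0, 1]
        model = HillModel(F_max=fmin + amp, F_min=fmin, Kd_mM=kd, n=nn)
        fit = HillFit(
            model, float(np.sqrt(max(var_fmax, 0.0))), float(se[0]),
            float(se[2]), float(se[3]),
        )
    fit.residuals = f - predict(c, *popt)
    if not np.isfinite(fit.se_Kd) or fit.se_Kd > 10 * model.Kd_mM:
        warnings.warn("Kd poorly constrained by this dose response", UnidentifiableKdWarning)
    return fit
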