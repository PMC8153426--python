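"""Seeded synthetic-data generators emulating each assay's noise model.

Every generator takes an explicit :class:`SeededConfig`; a fixed seed
gives bit-identical output and there is no global random state.  Noise
models follow the measurement class: colony counts are Poisson,
cytometry positives are binomial, instrument signals (calorimeter
heats, MST fluorescence, OD) carry additive Gaussian noise.

The tolerance-distribution generator uses a flat-then-log-linear model
with a floor: every cell tolerates concentrations up to a breakpoint
c0, beyond which the tolerant fraction falls tenfold per
1/|slope| mM down to a floor frequency.  The log-linear tail mirrors
the summary statistic the assay reports (a log10-frequency-per-mM
slope); it is an operational form, not a mechanistic claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import HillModel, ItcModel, ItcProtocol, ItcExperiment, hill_response, itc_forward
from .dilution import SpotSeries
from .errors import ValidationError
from .fitness import CompetitionRaw


@dataclass
class SeededConfig:
    """Seed, replicate count and instrument-noise SD for a generator.

    ``noise_sd`` is in the unit of the simulated signal (uJ for ITC
    heats, response units for MST, OD units for growth curves); it is
    ignored by the purely counting-noise generators.
    """

    seed: int
    replicates: int = 3
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("need at least 1 replicate")
        if self.noise_sd < 0:
            raise ValidationError("noise SD must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class ToleranceModel:
    """Flat-then-log-linear tolerance distribution with a floor.

    frequency(c) = 1 for c <= breakpoint_c0, otherwise
    max(10**(decline_slope * (c - c0)), floor_frequency).
    """

    breakpoint_c0: float
    decline_slope: float  # log10 frequency per mM, negative
    floor_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.decline_slope >= 0:
            raise ValidationError("decline slope must be negative")
        if not (0.0 <= self.floor_frequency <= 1.0):
            raise ValidationError("floor frequency must lie in [0, 1]")

    def frequency(self, c: float) -> float:
        if c <= self.breakpoint_c0:
            return 1.0
        return max(10.0 ** (self.decline_slope * (c - self.breakpoint_c0)),
                   self.floor_frequency)


@dataclass
class PlateGeometry:
    """Spot-plating geometry: dilution series and per-spot volume."""

    dilution_exponents: tuple[int, ...] = (0, -1, -2, -3, -4, -5, -6)
    spot_volume_ml: float = 0.010


def _spot_counts(rng, true_density, exponents, volume_ml):
    means = true_density * volume_ml * np.power(10.0, np.asarray(exponents, dtype=float))
    return rng.poisson(means)


def gen_spot_series(
    true_density: float,
    dilution_exponents: Sequence[int],
    spot_volume_ml: float,
    cfg: SeededConfig,
    sample_id: str = "synthetic",
) -> list[SpotSeries]:
    """Replicate dilution-spot series with Poisson colony counts.

    Each spot count is Poisson with mean density x volume x 10**exponent.
    """
    if true_density < 0:
        raise ValidationError("true density must be nonnegative")
    if spot_volume_ml <= 0:
        raise ValidationError("spot volume must be positive")
    rng = cfg.rng()
    return [
        SpotSeries(
            sample_id, f"r{i + 1}", tuple(dilution_exponents),
            tuple(int(c) for c in _spot_counts(rng, true_density, dilution_exponents, spot_volume_ml)),
            spot_volume_ml,
        )
        for i in range(cfg.replicates)
    ]


def gen_tolerance_counts(
    model: ToleranceModel,
    concentrations: Sequence[float],
    base_density: float,
    plating: PlateGeometry,
    cfg: SeededConfig,
) -> dict[float, list[SpotSeries]]:
    """Simulated spot counts across a formaldehyde concentration panel.

    The expected tolerant density at concentration c is
    base_density * model.frequency(c); counts at 0 mM reflect the full
    population.
    """
    concs = [float(c) for c in concentrations]
    if concs != sorted(concs):
        raise ValidationError("concentrations must be sorted ascending")
    if 0.0 not in concs:
        raise ValidationError("the 0 mM baseline concentration is required")
    if base_density < 0:
        raise ValidationError("base density must be nonnegative")
    rng = cfg.rng()
    out: dict[float, list[SpotSeries]] = {}
    for c in concs:
        density = base_density * model.frequency(c)
        out[c] = [
            SpotSeries(
                f"c{c:g}mM", f"r{i + 1}", plating.dilution_exponents,
                tuple(int(x) for x in _spot_counts(
                    rng, density, plating.dilution_exponents, plating.spot_volume_ml)),
                plating.spot_volume_ml,
            )
            for i in range(cfg.replicates)
        ]
    return out


def competition_truth(F0: float, fold_test: float, fold_ref: float) -> tuple[float, float]:
    """Exact final fraction and fitness for given strain expansions.

    F1 = F0*a / (F0*a + (1-F0)*b) and W = log(a)/log(b) for test and
    reference expansions a, b.
    """
    f1 = F0 * fold_test / (F0 * fold_test + (1.0 - F0) * fold_ref)
    return f1, np.log(fold_test) / np.log(fold_ref)


def gen_competition(
    F0: float,
    fold_test: float,
    fold_ref: float,
    n_events: int,
    cfg: SeededConfig,
) -> CompetitionRaw:
    """Binomially sampled cytometry counts for one competition.

    Positives are fluorescent *reference* events (the tagged strain), so
    the default gating orientation recovers the test-strain fractions.
    """
    if not (0.0 < F0 < 1.0):
        raise ValidationError("F0 must lie strictly inside (0, 1)")
    if fold_test <= 1.0 or fold_ref <= 1.0:
        raise ValidationError("expansion folds must exceed 1")
    if n_events < 1000:
        raise ValidationError("the assay counts at least 1,000 events")
    f1, _ = competition_truth(F0, fold_test, fold_ref)
    rng = cfg.rng()
    pos0 = int(np.clip(rng.binomial(n_events, 1.0 - F0), 1, n_events - 1))
    pos1 = int(np.clip(rng.binomial(n_events, 1.0 - f1), 1, n_events - 1))
    return CompetitionRaw(pos0, n_events, pos1, n_events)


def gen_mst_curve(
    model: HillModel,
    concentrations: Sequence[float],
    cfg: SeededConfig,
) -> pd.DataFrame:
    """Replicate Hill dose-response table with additive Gaussian noise.

    Columns: concentration_mM, replicate, f_norm.
    """
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise ValidationError("concentrations must be nonnegative")
    rng = cfg.rng()
    clean = hill_response(c, model.F_max, model.F_min, model.Kd_mM, model.n)
    rows = []
    for rep in range(cfg.replicates):
        noisy = clean + rng.normal(0.0, cfg.noise_sd, size=len(c)) if cfg.noise_sd > 0 else clean.copy()
        rows.append(pd.DataFrame({
            "concentration_mM": c, "replicate": rep + 1, "f_norm": noisy,
        }))
    return pd.concat(rows, ignore_index=True)


def gen_itc_thermogram(
    protocol: ItcProtocol,
    n_sites: float,
    Kd_mM: float,
    dH_kcal_per_mol: float,
    dilution_heat_uJ: float,
    cfg: SeededConfig,
) -> ItcExperiment:
    """Synthetic sample + blank thermogram for one titration.

    Sample heats are the one-site forward model plus a constant
    per-injection dilution heat plus Gaussian noise; blank heats are the
    dilution heat plus independent noise.  The throw-away first
    injection is generated too (it is flagged excluded by the protocol).
    """
    if dH_kcal_per_mol == 0.0:
        binding_heats = np.zeros(protocol.n_injections)
    else:
        binding_heats = itc_forward(ItcModel(n_sites, Kd_mM, dH_kcal_per_mol), protocol)
    rng = cfg.rng()
    n = protocol.n_injections
    noise_s = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
    noise_b = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
    return ItcExperiment(
        protocol,
        binding_heats + dilution_heat_uJ + noise_s,
        dilution_heat_uJ + noise_b,
    )


def gen_growth_curve(
    lag_h: float,
    rate_per_h: float,
    K: float,
    times_h: Sequence[float],
    cfg: SeededConfig,
    od0: float = 0.005,
) -> pd.DataFrame:
    """Replicate lagged-logistic OD600 trajectories with Gaussian noise.

    OD stays at ``od0`` until the lag, then follows logistic growth
    toward carrying capacity K.  Columns: time_h, replicate, od600.
    """
    t = np.asarray(times_h, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    if rate_per_h <= 0:
        raise ValidationError("growth rate must be positive")
    if K <= od0:
        raise ValidationError("carrying capacity must exceed the initial OD")
    if lag_h < 0:
        raise ValidationError("lag must be nonnegative")
    te = np.clip(t - lag_h, 0.0, None)
    grow = np.exp(rate_per_h * te)
    clean = K * od0 * grow / (K + od0 * (grow - 1.0))
    rng = cfg.rng()
    rows = []
    for rep in range(cfg.replicates):
        noisy = clean + rng.normal(0.0, cfg.noise_sd, size=len(t)) if cfg.noise_sd > 0 else clean.copy()
        rows.append(pd.DataFrame({
            "time_h": t, "replicate": rep + 1, "od600": np.clip(noisy, 1e-4, None),
        }))
    return pd.concat(rows, ignore_index=True)
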