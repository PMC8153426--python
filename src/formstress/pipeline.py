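"""Configuration-driven orchestration of the assay analysis stages.

A run is described by a YAML/dict config naming an ordered list of
stages with parameters, an output directory and a global seed.  Stages
exchange data through an in-memory context and write CSV/JSON
artifacts; the run produces a JSON report with per-stage status,
timing and summaries.  Identical config + seed give identical report
payloads (timestamps aside).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import binding, dilution, fitness, growthkin, io, synthgen, tolerance
from .errors import ConfigError

log = logging.getLogger("formstress.pipeline")


@dataclass
class StageSpec:
    name: str
    params: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    stages: list[StageSpec]
    output_dir: str = "formstress_run"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        stages = [
            StageSpec(s["name"], dict(s.get("params", {}))) for s in d.get("stages", [])
        ]
        return cls(stages, d.get("output_dir", "formstress_run"), int(d.get("seed", 0)))

    def to_dict(self) -> dict:
        return {
            "stages": [{"name": s.name, "params": s.params} for s in self.stages],
            "output_dir": self.output_dir,
            "seed": self.seed,
        }


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _stage_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence(base, spawn_key=(index,)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------- stages

def _synth_tolerance(params, ctx, seed, outdir):
    model = synthgen.ToleranceModel(
        params.get("breakpoint_c0", 2.0),
        params.get("decline_slope", -1.0),
        params.get("floor_frequency", 0.0),
    )
    concs = params.get("concentrations", [0, 1, 2, 3, 4, 5, 6])
    cfg = synthgen.SeededConfig(seed, params.get("replicates", 3))
    counts = synthgen.gen_tolerance_counts(
        model, concs, params.get("base_density", 2e8), synthgen.PlateGeometry(), cfg
    )
    ctx["tolerance_counts"] = counts
    ctx["generating_slope"] = model.decline_slope
    io.write_spot_counts(counts, outdir / "spot_counts.csv")
    return {"concentrations": list(map(float, concs)), "generating_slope": model.decline_slope}


def _cfu(params, ctx, seed, outdir):
    counts = ctx.get("tolerance_counts")
    if counts is None:
        counts = io.read_spot_counts(params["input"], params.get("spot_volume_ml", 0.010))
    rng_range = tuple(params.get("countable_range", (3, 150)))
    estimates = {
        c: [dilution.estimate_cfu(s, rng_range) for s in series]
        for c, series in counts.items()
    }
    ctx["cfu_estimates"] = estimates
    io.write_cfu_estimates(estimates, outdir / "cfu_estimates.csv")
    pooled0 = dilution.pool_replicates(estimates[0.0]) if 0.0 in estimates else None
    return {"n_conditions": len(estimates),
            "baseline_cfu_per_ml": pooled0.mean if pooled0 else None}


def _tolerance(params, ctx, seed, outdir):
    estimates = ctx.get("cfu_estimates")
    if estimates is None:
        estimates = io.read_cfu_estimates(params["input"])
    lod = tolerance.detection_limit(
        params.get("spot_volume_ml", 0.010), params.get("spots_per_sample", 3),
        params.get("population_density", 2e8), params.get("lod_rounding", "floor"),
    )
    curve = tolerance.frequency_curve(estimates, lod.min_frequency)
    fit = tolerance.decline_slope(
        curve, params.get("selection", "last_k_nonzero"), params.get("k", 4)
    )
    ctx["tolerance_curve"] = curve
    ctx["slope_fit"] = fit
    summary = {
        "lod_frequency": lod.min_frequency,
        "slope": fit.slope, "slope_se": fit.slope_se,
        "points_used": list(fit.points_used),
    }
    (outdir / "tolerance.json").write_text(json.dumps(summary, indent=2))
    return summary


def _synth_competition(params, ctx, seed, outdir):
    cfg = synthgen.SeededConfig(seed, params.get("replicates", 3))
    raws = []
    rng = cfg.rng()
    for i in range(cfg.replicates):
        sub = synthgen.SeededConfig(int(rng.integers(2**31)), 1)
        raws.append(synthgen.gen_competition(
            params.get("F0", 0.5), params.get("fold_test", 64.0),
            params.get("fold_ref", 64.0), params.get("n_events", 10000), sub,
        ))
    ctx["competitions"] = raws
    ctx["competition_expansion"] = params.get("expansion", 64.0)
    _, true_w = synthgen.competition_truth(
        params.get("F0", 0.5), params.get("fold_test", 64.0), params.get("fold_ref", 64.0))
    return {"replicates": len(raws), "true_W": true_w}


def _fitness(params, ctx, seed, outdir):
    raws = ctx.get("competitions")
    expansion = params.get("expansion", ctx.get("competition_expansion", 64.0))
    if raws is None:
        df = io.read_competition(params["input"])
        raws = [
            fitness.CompetitionRaw(int(r.positives_t0), int(r.total_t0),
                                   int(r.positives_t1), int(r.total_t1))
            for r in df.itertuples()
        ]
    results = [fitness.estimate_competition(r, expansion) for r in raws]
    mean_w, sem, n = fitness.fitness_summary(results)
    summary = {"mean_W": mean_w, "sem_W": sem, "n": n}
    (outdir / "fitness.json").write_text(json.dumps(summary, indent=2))
    return summary


def _synth_mst(params, ctx, seed, outdir):
    model = binding.HillModel(
        params.get("F_max", 1.0), params.get("F_min", 0.0),
        params.get("Kd_mM", 8.01), params.get("n", 1.0),
    )
    concs = params.get("concentrations") or list(100.0 / 2 ** np.arange(16))
    cfg = synthgen.SeededConfig(seed, params.get("replicates", 3),
                                params.get("noise_sd", 0.02))
    df = synthgen.gen_mst_curve(model, concs, cfg)
    df.to_csv(outdir / "mst_curve.csv", index=False)
    ctx["mst_curve"] = df
    return {"n_points": len(df), "generating_Kd_mM": model.Kd_mM}


def _mst(params, ctx, seed, outdir):
    df = ctx.get("mst_curve")
    if df is None:
        c, f = io.read_mst(params["input"])
    else:
        c, f = df["concentration_mM"].to_numpy(), df["f_norm"].to_numpy()
    fit = binding.fit_hill(c, f, params.get("strict_printed_form", False))
    summary = {"Kd_mM": fit.model.Kd_mM, "Kd_se": fit.se_Kd,
               "n": fit.model.n, "F_max": fit.model.F_max, "F_min": fit.model.F_min}
    (outdir / "mst_fit.json").write_text(json.dumps(summary, indent=2))
    return summary


def _synth_itc(params, ctx, seed, outdir):
    protocol = binding.ItcProtocol()
    cfg = synthgen.SeededConfig(seed, 1, params.get("noise_sd", 1.0))
    exp = synthgen.gen_itc_thermogram(
        protocol, params.get("n_sites", 1.0), params.get("Kd_mM", 8.0),
        params.get("dH_kcal_per_mol", -22.65), params.get("dilution_heat_uJ", -2.0), cfg,
    )
    ctx["itc_experiment"] = exp
    return {"n_injections": protocol.n_injections,
            "generating_dH_kcal_per_mol": params.get("dH_kcal_per_mol", -22.65)}


def _itc(params, ctx, seed, outdir):
    exp = ctx.get("itc_experiment")
    if exp is None:
        sample, blank = io.read_itc_heats(params["input"])
        exp = binding.ItcExperiment(binding.ItcProtocol(), sample, blank)
    corrected = binding.subtract_blank(exp)
    fit = binding.fit_itc(corrected, exp.protocol, fix_n=params.get("fix_n"))
    summary = {"n_sites": fit.model.n_sites, "Kd_mM": fit.model.Kd_mM,
               "dH_kcal_per_mol": fit.model.dH_kcal_per_mol,
               "se_Kd": fit.se_Kd, "se_dH": fit.se_dH}
    (outdir / "itc_fit.json").write_text(json.dumps(summary, indent=2))
    return summary


def _synth_growth(params, ctx, seed, outdir):
    times = params.get("times_h") or list(np.arange(0, 30.25, 0.25))
    cfg = synthgen.SeededConfig(seed, params.get("replicates", 1),
                                params.get("noise_sd", 0.0))
    df = synthgen.gen_growth_curve(
        params.get("lag_h", 5.0), params.get("rate_per_h", 0.25),
        params.get("K", 1.0), times, cfg,
    )
    df.to_csv(outdir / "growth_curve.csv", index=False)
    ctx["growth_curve"] = df
    return {"n_points": len(df)}


def _growth(params, ctx, seed, outdir):
    df = ctx.get("growth_curve")
    if df is None:
        df = io.read_growth(params["input"])
    rep1 = df[df.get("replicate", 1) == 1] if "replicate" in df.columns else df
    fit = growthkin.fit_growth(
        rep1["time_h"].to_numpy(), rep1["od600"].to_numpy(),
        params.get("window_length", 5),
    )
    summary = {"lag_h": fit.lag_h, "rate_per_h": fit.rate_per_h,
               "max_od": fit.max_od, "no_growth": fit.no_growth}
    (outdir / "growth_fit.json").write_text(json.dumps(summary, indent=2))
    return summary


#: name -> (function, context keys it can consume when no file input given)
STAGES = {
    "synth_tolerance": (_synth_tolerance, set()),
    "cfu": (_cfu, {"tolerance_counts"}),
    "tolerance": (_tolerance, {"cfu_estimates"}),
    "synth_competition": (_synth_competition, set()),
    "fitness": (_fitness, {"competitions"}),
    "synth_mst": (_synth_mst, set()),
    "mst": (_mst, {"mst_curve"}),
    "synth_itc": (_synth_itc, set()),
    "itc": (_itc, {"itc_experiment"}),
    "synth_growth": (_synth_growth, set()),
    "growth": (_growth, {"growth_curve"}),
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write a JSON report.

    Unknown stage names fail validation before anything runs.  A failed
    stage is recorded and any later stage that would have consumed its
    in-memory output (and names no file input) is skipped.
    """
    unknown = [s.name for s in config.stages if s.name not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stage(s): {unknown}; known: {sorted(STAGES)}")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx: dict = {}
    failed_keys: set[str] = set()
    report: dict = {"package": "formstress", "version": __version__,
                    "seed": config.seed, "config": config.to_dict(), "stages": []}

    for i, spec in enumerate(config.stages):
        func, consumes = STAGES[spec.name]
        entry = {"name": spec.name, "params": spec.params}
        needs_ctx = consumes and "input" not in spec.params
        if needs_ctx and consumes & failed_keys:
            entry.update(status="skipped", reason="upstream stage failed")
            report["stages"].append(entry)
            log.warning("stage %s skipped (upstream failure)", spec.name)
            continue
        t0 = time.perf_counter()
        try:
            summary = func(spec.params, ctx, _stage_seed(config.seed, i), outdir)
            entry.update(status="ok", summary=summary)
        except Exception as err:  # noqa: BLE001 - report and continue
            entry.update(status="failed", error=f"{type(err).__name__}: {err}")
            # mark everything this stage would have provided as failed
            provides = {
                "synth_tolerance": {"tolerance_counts"},
                "cfu": {"cfu_estimates"},
                "tolerance": {"tolerance_curve", "slope_fit"},
                "synth_competition": {"competitions"},
                "synth_mst": {"mst_curve"},
                "synth_itc": {"itc_experiment"},
                "synth_growth": {"growth_curve"},
            }.get(spec.name, set())
            failed_keys |= provides
            log.error("stage %s failed: %s", spec.name, err)
        entry["seconds"] = round(time.perf_counter() - t0, 4)
        report["stages"].append(entry)
        log.info("stage %s: %s (%.3fs)", spec.name, entry["status"], entry["seconds"])

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
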