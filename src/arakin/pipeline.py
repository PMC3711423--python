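"""End-to-end orchestration: simulate -> (render/quantify) -> detect ->
stats -> fit -> transient, from one config and one global seed.

Every stage draws its randomness from a seed derived deterministically
from the global seed and the stage name, so stages can be re-run in
isolation on persisted intermediates and reproduce the full run exactly.
All intermediates are TSV (images TIFF); the run summary is JSON.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as aio
from .event_detection import detect_population
from .interval_statistics import (WindowConfig, choose_window, ks_two_sample,
                                  pearson_windowed, sample_stats)
from .step_model import estimate_tdiff, fit_hypoexp, ks_gof
from .synthetic_data import (ImageGeometry, PopulationParams, default_geometry,
                             population_traces, render_frames,
                             simulate_cell_events, write_mask, write_stack)
from .transient_dynamics import CMEModel, equilibrium_time, ssa_population

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

_STAGES = ("simulate", "render", "quantify", "detect", "stats", "fit",
           "transient")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(global_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    population: PopulationParams
    seed: int = 1
    use_images: bool = False
    alpha: float = 0.01
    max_segments: int = 12
    window: float | str = "auto"          # seconds or "auto"
    fit_d_dt: int = 3
    fit_d_t0: int = 5
    transient_kd: float = 1.0 / 300.0
    transient_n_cells: int = 10_000
    transient_horizon: float = 21_600.0
    transient_grid_s: float = 60.0
    transient_rates: str = "population"   # "population" or "fitted"

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        pop = PopulationParams(**d.pop("population"))
        return cls(population=pop, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _stats_block(values) -> dict[str, float]:
    s = sample_stats(values)
    return {"n": s.n, "mean_s": s.mean, "sd_s": s.sd,
            "normalized_variance": s.normalized_variance}


def run_pipeline(config: RunConfig, outdir) -> dict[str, Any]:
    """Execute all stages, persist intermediates under ``outdir`` and
    return (and write) the machine-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("arakin.pipeline")
    handler = logging.FileHandler(outdir / "log.txt")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict[str, Any] = {"seed": config.seed,
                               "stage_seeds": {s: stage_seed(config.seed, s)
                                               for s in _STAGES}}
    t_start = time.perf_counter()
    stage = "simulate"
    try:
        # --- simulate -----------------------------------------------------
        pop = config.population
        events = simulate_cell_events(pop, seed=stage_seed(config.seed, "simulate"))
        aio.write_truth(outdir / "truth.tsv", events)
        traces = population_traces(events, pop,
                                   seed=stage_seed(config.seed, "simulate") + 1)
        aio.write_traces(outdir / "traces.tsv", traces)
        log.info("simulate: %d cells", pop.n_cells)

        # --- render + quantify (optional image route) ---------------------
        if config.use_images:
            stage = "render"
            from .spot_quantification import quantify_stack

            geom = default_geometry(pop.n_cells)
            stack, mask = render_frames(events, pop, geom,
                                        seed=stage_seed(config.seed, "render"))
            write_stack(outdir / "stack.tif", stack)
            write_mask(outdir / "mask.tif", mask)
            stage = "quantify"
            traces, spot_table = quantify_stack(
                stack, mask, frame_interval=pop.frame_interval,
                smoothing_sigma=geom.spot_sigma)
            spot_table.to_csv(outdir / "spots.tsv", sep="\t", index=False,
                              float_format="%.6g")
            aio.write_traces(outdir / "traces_from_images.tsv", traces)
            log.info("quantify: %d spots", len(spot_table))

        # --- detect -------------------------------------------------------
        stage = "detect"
        series = detect_population(traces, max_segments=config.max_segments,
                                   alpha=config.alpha,
                                   unit_intensity=pop.unit_intensity)
        aio.write_events(outdir / "events.tsv", series)
        aio.write_series(outdir / "series.tsv", series)
        aio.write_intervals(outdir / "intervals.tsv", series)
        t0 = np.array([s.t0 for s in series if s.t0 is not None])
        dts = np.concatenate([s.intervals for s in series]
                             ) if series else np.array([])
        log.info("detect: %d t0, %d intervals", t0.size, dts.size)

        # --- stats ----------------------------------------------------------
        stage = "stats"
        summary["t0"] = _stats_block(t0)
        summary["dt"] = _stats_block(dts)
        d, p = ks_two_sample(t0, dts)
        summary["ks_t0_vs_dt"] = {"D": d, "p": p}
        if config.window == "auto":
            w = choose_window(series, pop.t_total, pop.frame_interval)
        else:
            w = float(config.window)
        try:
            r, pr, npairs = pearson_windowed(
                series, WindowConfig(w, pop.t_total))
            summary["correlation_t0_dt"] = {"window_s": w, "r": r, "p": pr,
                                            "n_pairs": npairs}
        except ValueError as exc:
            summary["correlation_t0_dt"] = {"window_s": w, "error": str(exc)}

        # --- fit ------------------------------------------------------------
        stage = "fit"
        fit_seed = stage_seed(config.seed, "fit")
        model_dt = fit_hypoexp(dts, config.fit_d_dt, seed=fit_seed)
        model_t0 = fit_hypoexp(t0, config.fit_d_t0, seed=fit_seed + 1)
        for name, model, data in (("dt", model_dt, dts), ("t0", model_t0, t0)):
            dks, pks = ks_gof(data, model)
            summary[f"model_{name}"] = {
                "d": model.d, "rates_per_s": list(model.rates),
                "mean_s": model.mean, "sd_s": model.sd,
                "loglik": model.loglik, "ks_D": dks, "ks_p": pks}
        td = estimate_tdiff(sample_stats(t0), sample_stats(dts))
        summary["tdiff"] = {"mean_s": td.mean, "sd_s": td.sd, "valid": td.valid}
        _write_model_block(outdir / "models.txt", summary)

        # --- transient ------------------------------------------------------
        stage = "transient"
        if config.transient_rates == "fitted":
            # split the fitted 5-step t0 model: slowest 2 rates as intake
            intake_rates = tuple(model_t0.rates[:2])
            init_rates = tuple(model_dt.rates)
        else:
            intake_rates = tuple(pop.intake_rates)
            init_rates = tuple(pop.initiation_rates)
        grid = np.arange(0.0, config.transient_horizon + config.transient_grid_s,
                         config.transient_grid_s)
        tr_seed = stage_seed(config.seed, "transient")
        out_transient = {}
        summaries = []
        for label, ir in (("full", intake_rates), ("fast_intake", ())):
            model = CMEModel(intake_rates=ir, initiation_rates=init_rates,
                             degradation_rate=config.transient_kd)
            summ = ssa_population(model, config.transient_n_cells, grid,
                                  seed=tr_seed)
            _write_transient(outdir / f"transient_{label}.tsv", summ)
            summaries.append(summ)
            out_transient[label] = {
                "equilibrium_time_s": equilibrium_time(summ),
                "steady_state_mean": float(summ.mean[-len(grid) // 10:].mean()),
            }
        from .transient_dynamics import plot_transient_summaries

        plot_transient_summaries(summaries, ["with intake", "instant intake"],
                                 outdir / "transient.png")
        summary["transient"] = out_transient
        summary["wall_time_s"] = time.perf_counter() - t_start
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        log.info("done in %.1f s", summary["wall_time_s"])
        return summary
    except Exception as exc:
        log.exception("stage %s failed", stage)
        with open(outdir / "summary.json", "w") as fh:
            json.dump({**summary, "failed_stage": stage}, fh, indent=2)
        raise RuntimeError(f"pipeline stage {stage!r} failed") from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_transient(path, summ) -> None:
    import pandas as pd

    pd.DataFrame({"time_s": summ.times, "mean": summ.mean, "var": summ.var,
                  "fano": summ.fano}).to_csv(path, sep="\t", index=False,
                                             float_format="%.6g")


def _write_model_block(path, summary: dict[str, Any]) -> None:
    lines = []
    for name in ("dt", "t0"):
        m = summary[f"model_{name}"]
        lines.append(f"model_{name}:")
        lines.append(f"  d: {m['d']}")
        lines.append("  rates_per_s: [" +
                     ", ".join(f"{r:.6g}" for r in m["rates_per_s"]) + "]")
        for k in ("mean_s", "sd_s", "loglik", "ks_D", "ks_p"):
            lines.append(f"  {k}: {m[k]:.6g}")
    td = summary["tdiff"]
    lines.append("tdiff:")
    lines.append(f"  mean_s: {td['mean_s']:.6g}")
    lines.append(f"  sd_s: {td['sd_s']:.6g}")
    lines.append(f"  valid: {td['valid']}")
    Path(path).write_text("\n".join(lines) + "\n")
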