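"""End-to-end pipeline: synthetic domain → metrics → health → efficiency → pathway.

Each stage writes its outputs into the run directory and later stages read
them back, so stages are independently re-runnable.  A JSON manifest records
the config hash, seeds and package version; identical config + seed yields
byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemistry import ChemParams, generate_background
from .config import PipelineConfig
from .costs import generate_cost_curves
from .demography import generate_population_mortality
from .efficiency import instant_efficiency, interpolate_levels
from .emissions import generate_emissions
from .grid import generate_domain
from .health import load_gemm_params, monte_carlo_ci
from .io import (
    efficiency_to_frame,
    pathway_to_frame,
    read_age_structure,
    read_ensemble,
    write_age_structure,
    write_csv,
    write_ensemble,
)
from .metrics import (
    annual_guideline_achievement,
    daily_exceedance_fraction,
    n_share,
    synthesize_daily,
)
from .pathway import (
    cost_effectiveness_surface,
    cost_optimal_path,
    cost_surface,
    fit_response_surface,
    steepest_descent_path,
)
from .regime import g_ratio, tipping_from_betas
from .scenarios import ScenarioSpec, generate_scenario_ensemble

log = logging.getLogger("nrpathways")

STAGES = ("generate", "metrics", "health", "efficiency", "pathway")
REGIONS = ("West", "East")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _seed_for(config: PipelineConfig, purpose: str) -> int:
    """Stable per-purpose sub-seed derived from the config seed (< 2^31)."""
    h = hashlib.sha256(f"{config.seed}:{purpose}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def chem_params(
    config: PipelineConfig, grid=None, background=None, inv=None
) -> ChemParams:
    if background is None and grid is not None:
        background = generate_background(grid, seed=_seed_for(config, "background"))
    s_fix = config.s_fix
    if inv is not None:
        # sulfate tracks the combustion (NOx) pattern: clean cells carry less
        # sulfate, source regions more, with the configured domain mean
        pattern = (inv.e_nox / inv.e_nox.mean()) ** 0.7
        s_fix = config.s_fix * pattern / pattern.mean()
    return ChemParams(
        a_tot=config.a_tot,
        n_tot=config.n_tot,
        p_ox=config.p_ox,
        s_fix=s_fix,
        eps=dict(config.eps),
        sharpness=config.sharpness,
        background=background if background is not None else 5.0,
    )


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", stage, dt)
            else:
                log.error("stage %s: FAILED after %.2fs (%s)", stage, dt, exc)
            return False

    return _Timer()


def stage_generate(config: PipelineConfig, outdir: Path) -> None:
    grid = generate_domain(config.n_lat, config.n_lon, config.n_level, seed=config.seed)
    inv = generate_emissions(
        grid, config.total_nh3, config.total_nox, seed=_seed_for(config, "emissions")
    )
    params = chem_params(config, grid, inv=inv)
    ensemble = generate_scenario_ensemble(inv, params, config.levels, n_level=config.n_level)
    write_ensemble(outdir / "ensemble.nc", ensemble, grid)
    ages = generate_population_mortality(
        grid, config.total_pop, seed=_seed_for(config, "population")
    )
    write_age_structure(outdir / "population.nc", ages, grid)
    pd.DataFrame(
        {
            "species": ["NH3", "NOx"],
            "total_tg_n": [inv.total_nh3, inv.total_nox],
        }
    ).pipe(lambda df: write_csv(outdir / "emission_totals.csv", df))


def _load_ensemble(outdir: Path):
    path = outdir / "ensemble.nc"
    if not path.exists():
        raise FileNotFoundError(f"missing {path}; run the generate stage first")
    return read_ensemble(path)


def stage_metrics(config: PipelineConfig, outdir: Path) -> None:
    grid, ensemble = _load_ensemble(outdir)
    base = ensemble[ScenarioSpec(0.0, 0.0)].annual_mean_pm25()
    rows = []
    for spec, state in ensemble.items():
        annual = state.annual_mean_pm25()
        for region in REGIONS:
            share = float(grid.area_weighted_mean(n_share(base, annual), region))
            achiev = annual_guideline_achievement(annual, grid, region, config.annual_guideline)
            monthly_region = grid.area_weighted_mean(state.pm25[:, 0], region)
            daily = synthesize_daily(
                monthly_region, cv=config.daily_cv, seed=_seed_for(config, f"daily:{region}")
            )
            rows.append(
                {
                    "scenario": spec.label,
                    "reduction_nh3": spec.x,
                    "reduction_nox": spec.y,
                    "region": region,
                    "n_share_vs_base": share,
                    "annual_achieving_area_frac": achiev,
                    "daily_exceedance_frac": daily_exceedance_fraction(
                        daily, config.daily_guideline
                    ),
                }
            )
    write_csv(outdir / "attainment.csv", pd.DataFrame(rows))


def stage_health(config: PipelineConfig, outdir: Path) -> None:
    grid, ensemble = _load_ensemble(outdir)
    ages = read_age_structure(outdir / "population.nc")
    params = load_gemm_params(config.gemm_params_file)
    base = ensemble[ScenarioSpec(0.0, 0.0)].annual_mean_pm25()
    rows = []
    for spec, state in ensemble.items():
        annual = state.annual_mean_pm25()
        res = monte_carlo_ci(
            base,
            ages,
            params,
            scenario_field=None if spec.x == spec.y == 0 else annual,
            n_draws=config.n_draws,
            seed=_seed_for(config, "health"),
            grid=grid,
        )
        row = {
            "scenario": spec.label,
            "reduction_nh3": spec.x,
            "reduction_nox": spec.y,
            "kind": "attributable" if spec.x == spec.y == 0 else "avoided",
            "deaths": res.deaths,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "n_draws": res.n_draws,
        }
        row.update({f"deaths_{k}": v for k, v in (res.by_region or {}).items()})
        rows.append(row)
    write_csv(outdir / "health_burden.csv", pd.DataFrame(rows))


def _regional_curves(config: PipelineConfig, outdir: Path):
    grid, ensemble = _load_ensemble(outdir)
    curves: dict[tuple[str, str], object] = {}
    for region in REGIONS:
        regional = {
            spec: float(grid.area_weighted_mean(state.annual_mean_pm25(), region))
            for spec, state in ensemble.items()
        }
        for mode in ("Nr", "NOx", "NH3"):
            if mode == "Nr":
                pts = {s: v for s, v in regional.items() if s.x == s.y}
                base_emi = config.total_nh3 + config.total_nox
            elif mode == "NOx":
                pts = {s: v for s, v in regional.items() if s.x == 0}
                base_emi = config.total_nox
            else:
                pts = {s: v for s, v in regional.items() if s.y == 0}
                base_emi = config.total_nh3
            levels = sorted(max(s.x, s.y) for s in pts)
            pm = [pts[s] for s in sorted(pts, key=lambda s: max(s.x, s.y))]
            curves[(region, mode)] = interpolate_levels(
                np.array(levels), np.array(pm), base_emi, mode=mode
            )
    return grid, ensemble, curves


def stage_efficiency(config: PipelineConfig, outdir: Path) -> None:
    grid, ensemble, curves = _regional_curves(config, outdir)
    frames, tip_rows = [], []
    for region in REGIONS:
        series = {
            mode: instant_efficiency(curves[(region, mode)]) for mode in ("Nr", "NOx", "NH3")
        }
        frames.append(efficiency_to_frame(series, region))
        tp = tipping_from_betas(series["NH3"], series["NOx"])
        tip_rows.append(
            {
                "region": region,
                "criterion": tp.criterion,
                "reduction_frac": tp.reduction_frac,
                "reachable": tp.reachable,
            }
        )
        base_state = ensemble[ScenarioSpec(0.0, 0.0)]
        gfield = g_ratio(base_state, eps=config.eps)
        gmean, gsd = gfield.regional_stats(grid, region)
        tip_rows.append(
            {
                "region": region,
                "criterion": "g_base_mean",
                "reduction_frac": float(np.nanmean(gmean)),
                "reachable": True,
            }
        )
    write_csv(outdir / "efficiency.csv", pd.concat(frames, ignore_index=True))
    write_csv(outdir / "tipping_points.csv", pd.DataFrame(tip_rows))


def stage_pathway(config: PipelineConfig, outdir: Path) -> None:
    grid, ensemble = _load_ensemble(outdir)
    curves = generate_cost_curves(config.cost_anchor_scenarios())
    for region in REGIONS:
        regional = {
            spec: float(grid.area_weighted_mean(state.annual_mean_pm25(), region))
            for spec, state in ensemble.items()
        }
        surface = fit_response_surface(regional)
        opt = steepest_descent_path(surface)
        write_csv(outdir / f"pathway_pm_{region}.csv", pathway_to_frame(opt))
        csfc = cost_surface(curves[("NH3", region)], curves[("NOx", region)])
        ratio = cost_effectiveness_surface(surface, csfc)
        cpath = cost_optimal_path(surface, csfc)
        write_csv(outdir / f"pathway_cost_{region}.csv", pathway_to_frame(cpath))
        ratio_df = pd.DataFrame(
            ratio.value, index=pd.Index(ratio.x_grid, name="reduction_nh3"),
            columns=ratio.y_grid,
        ).reset_index()
        write_csv(outdir / f"ratio_surface_{region}.csv", ratio_df)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> Path:
    """Run all stages; returns the run directory containing outputs + manifest."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    completed = []
    stage_fns = {
        "generate": stage_generate,
        "metrics": stage_metrics,
        "health": stage_health,
        "efficiency": stage_efficiency,
        "pathway": stage_pathway,
    }
    try:
        for stage in STAGES:
            with _timed(stage):
                stage_fns[stage](config, outdir)
            completed.append(stage)
    except Exception as exc:
        _write_manifest(config, outdir, completed, failed=stage)
        raise StageError(stage, exc) from exc
    _write_manifest(config, outdir, completed, failed=None)
    return outdir


def _write_manifest(config, outdir: Path, completed: list[str], failed: str | None) -> None:
    cfg = config.to_dict()
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    manifest = {
        "package": "nrpathways",
        "version": __version__,
        "config_sha256": cfg_hash,
        "seed": config.seed,
        "stages_completed": completed,
        "stage_failed": failed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
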