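"""Gridded and tabular I/O: NetCDF ensembles, CSV tables.

NetCDF files use CF-style dimensions (scenario, month, level, lat, lon) with
the region mask stored as integer flag values and cell areas as an auxiliary
variable.  Round-tripping preserves values to full float precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .chemistry import SpeciesState
from .demography import AgeStructure
from .efficiency import EfficiencySeries
from .grid import DomainGrid, REGION_CODES
from .pathway import Pathway
from .scenarios import ScenarioSpec

_NC_ENGINE = "scipy"  # NetCDF3; portable and dependency-light

_SPECIES_VARS = ("nh3", "nh4", "so4", "hno3", "no3", "background_mass", "pm25")


def _grid_coords(grid: DomainGrid) -> dict:
    return {
        "month": list(grid.months),
        "level": grid.level.astype(np.int32),
        "lat": grid.lat,
        "lon": grid.lon,
    }


def ensemble_to_dataset(
    ensemble: dict[ScenarioSpec, SpeciesState], grid: DomainGrid
) -> xr.Dataset:
    specs = list(ensemble)
    dims = ("scenario", "month", "level", "lat", "lon")
    data = {
        var: (dims, np.stack([getattr(ensemble[s], var) for s in specs]))
        for var in _SPECIES_VARS
    }
    ds = xr.Dataset(
        data_vars={
            **data,
            "region_mask": (("lat", "lon"), grid.region_mask.astype(np.int8)),
            "cell_area": (("lat", "lon"), grid.cell_area),
        },
        coords={
            **_grid_coords(grid),
            "scenario": [s.label or f"x{s.x:g}_y{s.y:g}" for s in specs],
            "reduction_nh3": ("scenario", [s.x for s in specs]),
            "reduction_nox": ("scenario", [s.y for s in specs]),
        },
    )
    ds["region_mask"].attrs.update(
        flag_values=list(REGION_CODES.values()),
        flag_meanings=" ".join(REGION_CODES),
    )
    ds["cell_area"].attrs["units"] = "km2"
    for var in ("nh3", "nh4", "so4", "hno3", "no3"):
        ds[var].attrs["units"] = "umol m-3"
    for var in ("background_mass", "pm25"):
        ds[var].attrs["units"] = "ug m-3"
    return ds


def write_ensemble(
    path: str | Path, ensemble: dict[ScenarioSpec, SpeciesState], grid: DomainGrid
) -> None:
    ensemble_to_dataset(ensemble, grid).to_netcdf(path, engine=_NC_ENGINE)


def dataset_to_ensemble(ds: xr.Dataset) -> tuple[DomainGrid, dict[ScenarioSpec, SpeciesState]]:
    grid = DomainGrid(
        lat=ds["lat"].values,
        lon=ds["lon"].values,
        region_mask=ds["region_mask"].values,
        cell_area=ds["cell_area"].values,
        level=ds["level"].values,
        months=tuple(str(m) for m in ds["month"].values),
    )
    ensemble = {}
    for i, label in enumerate(ds["scenario"].values):
        spec = ScenarioSpec(
            float(ds["reduction_nh3"].values[i]),
            float(ds["reduction_nox"].values[i]),
            str(label),
        )
        ensemble[spec] = SpeciesState(
            **{var: ds[var].values[i] for var in _SPECIES_VARS}, months=grid.months
        )
    return grid, ensemble


def read_ensemble(path: str | Path):
    try:
        with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
            return dataset_to_ensemble(ds.load())
    except Exception as exc:
        raise ValueError(f"malformed ensemble file {path}: {exc}") from exc


def write_age_structure(path: str | Path, ages: AgeStructure, grid: DomainGrid) -> None:
    ds = xr.Dataset(
        data_vars={
            "pop": (("age_group", "lat", "lon"), ages.pop),
            "base_rate": (("age_group", "lat", "lon"), ages.base_rate),
        },
        coords={"age_group": list(ages.age_groups), "lat": grid.lat, "lon": grid.lon},
    )
    ds["pop"].attrs["units"] = "persons"
    ds["base_rate"].attrs["units"] = "deaths person-1 yr-1"
    ds.to_netcdf(path, engine=_NC_ENGINE)


def read_age_structure(path: str | Path) -> AgeStructure:
    try:
        with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
            ds = ds.load()
            return AgeStructure(
                age_groups=tuple(str(a) for a in ds["age_group"].values),
                pop=ds["pop"].values,
                base_rate=ds["base_rate"].values,
            )
    except Exception as exc:
        raise ValueError(f"malformed age-structure file {path}: {exc}") from exc


def efficiency_to_frame(series: dict[str, EfficiencySeries], region: str) -> pd.DataFrame:
    rows = []
    for mode, s in series.items():
        for i, level in enumerate(s.levels):
            rows.append(
                {
                    "region": region,
                    "mode": mode,
                    "level": float(level),
                    "beta": float(s.beta[i]),
                    "beta_spatial_sd": float(s.spatial_sd[i]) if s.spatial_sd is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def pathway_to_frame(path: Pathway) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "step": np.arange(len(path.nodes)),
            "reduction_nh3": [n[0] for n in path.nodes],
            "reduction_nox": [n[1] for n in path.nodes],
            "cumulative_abatement": path.cumulative_abatement,
        }
    )
    if path.cumulative_cost is not None:
        df["cumulative_cost"] = path.cumulative_cost
    return df


def write_csv(path: str | Path, df: pd.DataFrame) -> None:
    """Locale-independent CSV (dot decimal, fixed float formatting)."""
    df.to_csv(path, index=False, float_format="%.10g")
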