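import numpy as np
import pytest

from nrpathways import (
    ChemParams,
    EmissionInventory,
    PipelineConfig,
    generate_domain,
    generate_emissions,
    generate_scenario_ensemble,
)
from nrpathways.pipeline import _seed_for, chem_params


def make_box_inventory(e_nh3: float, e_nox: float) -> EmissionInventory:
    """Single-cell inventory with flat monthly factors (a box model)."""
    return EmissionInventory(
        e_nh3=np.full((1, 1), e_nh3),
        e_nox=np.full((1, 1), e_nox),
        monthly_factor={"NH3": np.ones(4), "NOx": np.ones(4)},
    )


def box_params(**kwargs) -> ChemParams:
    """ChemParams for box-model tests: unit conversions, exact min, no background."""
    defaults = dict(
        a_tot=1.0,
        n_tot=1.0,
        p_ox=1.0,
        s_fix=0.0,
        eps={m: 1.0 for m in ("Jan", "Apr", "Jul", "Oct")},
        sharpness=None,
        background=0.0,
    )
    defaults.update(kwargs)
    return ChemParams(**defaults)


@pytest.fixture(scope="session")
def default_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def domain(default_cfg):
    """Default synthetic study domain: grid, inventory, chemistry parameters."""
    grid = generate_domain(default_cfg.n_lat, default_cfg.n_lon, seed=default_cfg.seed)
    inv = generate_emissions(
        grid,
        default_cfg.total_nh3,
        default_cfg.total_nox,
        seed=_seed_for(default_cfg, "emissions"),
    )
    params = chem_params(default_cfg, grid, inv=inv)
    return grid, inv, params


@pytest.fixture(scope="session")
def ensemble(domain, default_cfg):
    grid, inv, params = domain
    return generate_scenario_ensemble(inv, params, default_cfg.levels)
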