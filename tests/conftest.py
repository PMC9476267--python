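import numpy as np
import pandas as pd
import pytest

from grazekit.config import PipelineConfig, SimulationConfig
from grazekit import cli, simulate


@pytest.fixture(scope="session")
def small_config():
    """A small herd: 4 mobs x 8 cows, 8 days — fast but structurally complete."""
    return SimulationConfig(seed=7, n_farms=2, n_years=2, n_mobs=4,
                            cows_per_mob=8, days=8)


@pytest.fixture(scope="session")
def small_dem(small_config):
    return simulate.generate_dem(small_config)


@pytest.fixture(scope="session")
def small_herd(small_config):
    return simulate.simulate_herd(small_config)


@pytest.fixture(scope="session")
def small_sim(small_config, small_dem, small_herd):
    fixes, gt = simulate.simulate_trajectories(small_herd, small_dem, small_config)
    return fixes, gt


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory, small_config):
    """Full simulate -> metrics run shared across tests."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(outdir=str(out), seed=small_config.seed)
    cfg.simulation = small_config
    cli.run_simulate(cfg)
    res = cli.run_metrics(cfg)
    res["cfg"] = cfg
    return res


def straight_walk(n=10, step=100.0, dt=300.0, cow="c1"):
    t = pd.date_range("2020-06-01", periods=n, freq=f"{int(dt)}s", tz="UTC")
    return pd.DataFrame({
        "cow_id": cow, "timestamp": t,
        "x": np.arange(n) * step, "y": np.zeros(n),
    })
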