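import numpy as np
import pandas as pd
import pytest

from daphnegain import (ClimateConfig, demo_config, generate_climate,
                        run_pipeline)
from daphnegain.synthetic import reference_surface


@pytest.fixture(scope="session")
def ref_surface():
    return reference_surface()


@pytest.fixture(scope="session")
def year_climate():
    """One deterministic year of 2-min understory climate, default settings."""
    return generate_climate(ClimateConfig(seed=0))


@pytest.fixture(scope="session")
def demo_artifacts(tmp_path_factory):
    """One full demo-pipeline run shared across pipeline/integration tests."""
    out = tmp_path_factory.mktemp("demo_out")
    cfg = demo_config(seed=0, out_dir=str(out))
    return run_pipeline(cfg)


def constant_day_climate(date: str, par: float, temp: float) -> pd.DataFrame:
    """A single 720-step day with constant PAR and air temperature."""
    idx = pd.date_range(date, periods=720, freq="120s")
    return pd.DataFrame({"timestamp": idx,
                         "par": np.full(720, float(par)),
                         "temp_air": np.full(720, float(temp))})
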