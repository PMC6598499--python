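import numpy as np
import pytest

from thermoniche.phylo_comparative import read_tree
from thermoniche.synthetic_data import PanelSpec, generate_strain_panel, write_panel
from thermoniche.thermal_response import ThermalCurveParams


@pytest.fixture
def example_params():
    return ThermalCurveParams(mu_max=1.5, t_opt=20.0, t_max=30.0, beta=2.0)


@pytest.fixture
def three_tip_tree():
    return read_tree("((A:1.0,B:1.0):1.0,C:2.0);", from_path=False)


@pytest.fixture
def nonclock_tree():
    return read_tree("((A:0.8,B:1.2):0.5,C:1.9);", from_path=False)


@pytest.fixture(scope="session")
def small_panel():
    """8-strain synthetic panel (kept small so thermal fits stay fast)."""
    return generate_strain_panel(PanelSpec(n_strains=8, seed=3))


@pytest.fixture(scope="session")
def small_panel_dir(small_panel, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("panel")
    paths = write_panel(small_panel, outdir)
    return paths


def random_valid_params(rng, n):
    """Random valid Blanchard parameter sets for property checks."""
    mu = rng.uniform(0.2, 3.0, n)
    topt = rng.uniform(0.0, 30.0, n)
    span = rng.uniform(2.0, 20.0, n)
    beta = rng.uniform(0.2, 8.0, n)
    return [
        ThermalCurveParams(mu_max=float(m), t_opt=float(t), t_max=float(t + s), beta=float(b))
        for m, t, s, b in zip(mu, topt, span, beta)
    ]
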