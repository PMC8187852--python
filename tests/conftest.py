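import numpy as np
import pytest

import mmkit
from mmkit.dynamics import IntegratorConfig
from mmkit.metad import MetaDConfig, default_grid_range


@pytest.fixture(scope="session")
def three_well():
    return mmkit.three_well_2d()


@pytest.fixture(scope="session")
def two_state():
    return mmkit.two_state_1d((0.5, 0.5))


@pytest.fixture(scope="session")
def double_well():
    return mmkit.double_well_1d()


def metad_config_for(system, cv_names, mode="pb", sigma=0.12, height=1.0,
                     pace=250, biasfactor=10.0):
    """One-stop MetaDConfig with grid ranges derived from the potential."""
    cvs = tuple(system.cv(n) for n in cv_names)
    ranges = [default_grid_range(system.spec, cv) for cv in cvs]
    return MetaDConfig(
        cvs=cvs,
        sigma=tuple(np.broadcast_to(sigma, len(cvs))),
        grid_min=tuple(r[0] for r in ranges),
        grid_max=tuple(r[1] for r in ranges),
        mode=mode,
        height=height,
        pace=pace,
        biasfactor=biasfactor,
    )


@pytest.fixture(scope="session")
def short_dw_metad_run(double_well):
    """A short biased double-well run shared by several tests."""
    from mmkit.metad import run_metad

    cfg = metad_config_for(double_well, ["x"], mode="joint", sigma=0.1,
                           pace=100)
    integ = IntegratorConfig(dt=0.004, n_steps=30_000, seed=7, save_stride=10)
    return run_metad(double_well.spec, cfg, integ, n_walkers=2)
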