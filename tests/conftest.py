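import numpy as np
import pytest

import protomem as pm


@pytest.fixture(scope="session")
def tiny_run():
    """Small full-featured run: 4 protomers, mixed lipids, 40 frames."""
    params = pm.GeneratorParams(patch_nm=20.0, n_proteins=4, n_frames=40, seed=11)
    topo, f0 = pm.build_system(params)
    traj, truth = pm.simulate(topo, f0, params)
    return params, topo, f0, traj, truth


@pytest.fixture(scope="session")
def chol_run():
    """Protein-free sterol-rich membrane for flip-flop statistics.

    ~390 CHOL at a planted 5e6 1/s flip rate over 3 us.
    """
    comp = {"CHOL": 1.0}
    params = pm.GeneratorParams(
        patch_nm=12.5, n_proteins=0, n_frames=3000, seed=7,
        upper_composition=dict(comp), lower_composition=dict(comp),
        flip_rates_per_s={"CHOL": 5e6}, sm_coupling=0.0,
        helix_order_bias={}, store_chi=False)
    topo, f0 = pm.build_system(params)
    traj, truth = pm.simulate(topo, f0, params)
    return params, topo, traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
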