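import numpy as np
import pytest

import gefa
from gefa.synthetic import SAHEL_SCENARIO_GROUPS, SAHEL_SCENARIO_NAMES

#: names of the truly coupled forcings in the bundled Sahel scenario, with their
#: ground-truth coefficients (sqrt of the per-forcing signal fraction)
SAHEL_SCENARIO_TRUE = {
    "sst_basin1_eof1": np.sqrt(0.15),
    "sst_basin1_eof2": np.sqrt(0.15),
    "ndvi_sahel": np.sqrt(0.15),
}


def prepare_sahel_scenario(seed, n_years=30, season="SON", tau=1):
    """Generate, preprocess and pool one bundled Sahel scenario realization."""
    truth = gefa.sahel_scenario_truth(seed=seed)
    n_months = 12 * n_years
    O_raw = gefa.generate_forcings(truth, n_months)
    A_raw = gefa.generate_atmosphere(truth, O_raw)
    O_anom = gefa.to_anomalies(O_raw)
    A = gefa.to_anomalies(A_raw)[:, 0]
    fm = gefa.ForcingMatrix.from_series(
        {n: O_anom[:, j] for j, n in enumerate(SAHEL_SCENARIO_NAMES)},
        dict(zip(SAHEL_SCENARIO_NAMES, SAHEL_SCENARIO_GROUPS)),
    )
    pooling = gefa.pool_season(n_months, season, tau)
    return A, fm, pooling, truth


def simple_truth(b, ar1=0.85, noise_sd=1.0, n_forcings=None, seed=0, **kw):
    """One-response scenario with independent unit-variance AR(1) forcings."""
    b = np.atleast_1d(np.asarray(b, dtype=float))
    k = n_forcings or b.size
    return gefa.SyntheticTruth(
        B_true=b[None, :], forcing_ar1=np.full(k, ar1),
        forcing_crosscov=np.eye(k), noise_sd=[noise_sd], seed=seed, **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
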