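import numpy as np
import pandas as pd
import pytest

import ttbfrail as tb


@pytest.fixture
def toy_frame():
    """Four subjects in two clusters, both arms present."""
    return pd.DataFrame({
        "id": ["s1", "s2", "s3", "s4"],
        "cluster": ["c1", "c1", "c2", "c2"],
        "arm": [0, 1, 0, 1],
        "time": [1.0, 2.0, 3.0, 4.0],
        "event": [1, 0, 1, 0],
    })


@pytest.fixture
def toy_exponential_results():
    """No-frailty exponential arms h0=0.2, h1=0.1 as a fitted-results object.

    The marginal survival difference has the closed form
    D(t) = x - x^2 with x = exp(-0.1 t), maximal at 0.25.
    """
    return tb.SharedFrailtyResults(
        params=np.log([0.2, 0.1]),
        layout=["arm0.log_alpha", "arm1.log_alpha"],
        cov=np.eye(2) * 0.04,
        llf=0.0, llf_penalized=0.0, smoothing={}, convergence={},
        baseline_family="weibull", frailty_family="none", fix_shape=True,
    )


@pytest.fixture(scope="session")
def sim_small():
    """One moderate clustered dataset from the Weibull-truth scenario."""
    return tb.generate(tb.scenario_one(n_total=2000, n_clusters=40, seed=11))


@pytest.fixture(scope="session")
def wf_results(sim_small):
    """Weibull + gamma-frailty fit on the session dataset."""
    model = tb.SharedFrailtySurvivalModel(
        sim_small.data, baseline="weibull", frailty="gamma")
    return model.fit(seed=0)
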