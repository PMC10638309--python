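import numpy as np
import pytest

from selstop.exgauss import RunnerParams
from selstop.sis import SISParams
from selstop.synth import DesignConfig, default_group_truth, generate_behaviour, sample_group


def make_params(go=(400.0, 50.0, 50.0), stop=(150.0, 30.0, 30.0),
                sel=(270.0, 35.0, 45.0), gf=0.0, tf=0.0, eps=0.0,
                go_proactive=None, sel_proactive=None) -> SISParams:
    """Convenience constructor for study-scale SIS parameter sets."""
    go_p = go_proactive or go
    sel_p = sel_proactive or sel
    mk = lambda t: RunnerParams(*t)
    return SISParams(
        dual_go={"reactive": mk(go), "proactive": mk(go_p)},
        dual_stop={c: mk(stop) for c in ("reactive", "proactive")},
        sel_left={"reactive": mk(sel), "proactive": mk(sel_p)},
        sel_right={"reactive": mk(sel), "proactive": mk(sel_p)},
        gf=gf, tf=tf, eps_wrong=eps,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_params():
    """Study-scale parameter set with small failure probabilities."""
    return make_params(
        go=(391.0, 45.0, 60.0), go_proactive=(421.0, 45.0, 60.0),
        stop=(145.0, 25.0, 30.0),
        sel=(266.0, 35.0, 50.0), sel_proactive=(239.0, 35.0, 50.0),
        gf=0.02, tf=0.05, eps=0.01,
    )


@pytest.fixture(scope="session")
def small_study():
    """Small synthetic study shared across tests (2 subjects, 144 trials per
    condition) with observed, latent and staircase tables."""
    cohort = sample_group(default_group_truth(), 2, seed=7)
    obs, lat, stair = generate_behaviour(
        cohort, DesignConfig(n_trials_per_condition=144), seed=8
    )
    return {"cohort": cohort, "observed": obs, "latent": lat, "staircase": stair}
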