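import numpy as np
import pandas as pd
import pytest

from bstask.config import tot_config
from bstask.responders import SimulatedParticipant, generate_cohort, tot_preset


@pytest.fixture(scope="session")
def tot_cfg():
    return tot_config()


@pytest.fixture(scope="session")
def small_cohort(tot_cfg):
    """A 6-participant fatigue-induction cohort shared across tests."""
    return generate_cohort(6, protocol_config=tot_cfg, seed=301)


@pytest.fixture(scope="session")
def one_tot_log(tot_cfg):
    from bstask.engine import run_tot_protocol

    responder = SimulatedParticipant(tot_preset(), seed=11)
    return run_tot_protocol(responder, tot_cfg, seed=12, participant_id="p0")


def make_clean_observations(
    n_participants=20,
    trials_per_condition=30,
    means=(1800.0, 2400.0, 2100.0, 2250.0),
    seed=0,
):
    """Synthetic unlimited-time RT table: all correct, no 3 SD outliers.

    Participants get evenly spaced speed offsets (+/- 100 ms) and trials get
    bounded uniform noise (+/- 50 ms), so neither preprocessing stage can
    remove anything by construction: within-cell deviations stay under 2 SD
    of the cell and between-participant deviations under 2 SD of the group.
    """
    rng = np.random.default_rng(seed)
    offsets = np.linspace(-100.0, 100.0, n_participants)
    rows = []
    for p in range(n_participants):
        for cond, mean in zip((1, 2, 3, 4), means):
            rts = mean + offsets[p] + rng.uniform(-50.0, 50.0, size=trials_per_condition)
            for rt in rts:
                rows.append({"participant_id": f"p{p:03d}", "condition": cond, "rt_ms": rt, "correct": True})
    return pd.DataFrame(rows)
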