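import numpy as np
import pandas as pd
import pytest

from leapfrog import AgentConfig, EnvConfig, run_agent
from leapfrog.metrics import label_explore


def make_trials(choices, rewards, participant_id="p1", group="g", condition="independent"):
    """Build a minimal hand-written trial table."""
    n = len(choices)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "group": group,
            "condition": condition,
            "trial": np.arange(1, n + 1),
            "choice": choices,
            "reward": rewards,
        }
    )


def simulate_pool(kind, n_agents, seed0, env=None, **agent_kwargs):
    """Pool of labeled single-agent episodes with distinct participant ids."""
    env = env or EnvConfig()
    cfg = AgentConfig(kind=kind, **agent_kwargs)
    frames = []
    for i in range(n_agents):
        df = run_agent(env, cfg, seed=seed0 + i, participant_id=f"{kind}_{i:03d}", group=kind)
        frames.append(df)
    return label_explore(pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def reflexive_pool():
    """200 reflexive agents (epsilon=0.17), 200 trials each."""
    return simulate_pool("reflexive", 200, 1_000, epsilon=0.17)


@pytest.fixture(scope="session")
def ideal_pool():
    """200 ideal reflective agents, 200 trials each."""
    return simulate_pool("reflective_ideal", 200, 2_000)
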