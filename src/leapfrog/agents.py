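"""Generative choice models for the leapfrog task.

Three agent kinds:

* ``reflexive`` — exploits the best-seen option, exploring with a constant
  probability ``epsilon`` on every trial (flat exploration hazard).
* ``reflective_ideal`` — tracks the probability ``q`` that its favorite
  option has been overtaken, assuming a constant jump hazard, and explores
  when ``q`` crosses a threshold ``theta`` (rising exploration hazard).
* ``reflective_fallacy`` — same machinery, but believes the jump hazard
  ramps up with the number of trials since it last *observed* a jump
  (negative-autocorrelation belief).

Because jumps always hit the currently lower option, the favorite has been
overtaken exactly when an odd number of unobserved jumps has occurred, so
``q`` follows a parity recursion: ``q <- q*(1-h) + (1-q)*h``.  An exploratory
observation discloses the current state and collapses ``q`` back to the
one-step believed hazard.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .env import ConfigurationError, EnvConfig, initial_state, step

__all__ = [
    "AgentConfig",
    "BeliefState",
    "parity_update",
    "believed_hazard",
    "observe",
    "choose",
    "run_agent",
    "calibrate_theta",
    "DEFAULT_THETA_IDEAL",
    "DEFAULT_THETA_FALLACY",
]

AGENT_KINDS = ("reflexive", "reflective_ideal", "reflective_fallacy")
REFLECTIVE_KINDS = ("reflective_ideal", "reflective_fallacy")

# Threshold defaults frozen from calibrate_theta() grid searches targeting an
# exploration rate of ~0.17 in the default independent environment (the rate
# produced by both human groups).
DEFAULT_THETA_IDEAL = 0.32
DEFAULT_THETA_FALLACY = 0.32


class BeliefDataError(ValueError):
    """A reward inconsistent with leapfrog dynamics was observed."""


@dataclass(frozen=True)
class AgentConfig:
    kind: str = "reflective_ideal"
    epsilon: float = 0.02
    theta: Optional[float] = None
    believed_p: Optional[float] = None
    believed_h0: float = 0.01
    believed_dh: float = 0.01
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ConfigurationError(
                f"unknown agent kind {self.kind!r}; expected one of {AGENT_KINDS}"
            )
        if not 0.0 <= self.epsilon < 1.0:
            raise ConfigurationError("epsilon must lie in [0, 1)")
        if self.theta is not None and not 0.0 < self.theta < 0.5:
            raise ConfigurationError("theta must lie in (0, 0.5)")
        if self.believed_p is not None and not 0.0 < self.believed_p <= 1.0:
            raise ConfigurationError("believed_p must lie in (0, 1]")
        if not 0.0 < self.believed_h0 <= 1.0:
            raise ConfigurationError("believed_h0 must lie in (0, 1]")
        if self.believed_dh < 0.0:
            raise ConfigurationError("believed_dh must be nonnegative")

    @property
    def effective_theta(self) -> float:
        if self.theta is not None:
            return self.theta
        if self.kind == "reflective_fallacy":
            return DEFAULT_THETA_FALLACY
        return DEFAULT_THETA_IDEAL

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AgentConfig":
        return cls(**d)


@dataclass(frozen=True)
class BeliefState:
    """An agent's memory of the task.

    ``last_obs`` holds the last reward seen for each option (``None`` if the
    option has never been sampled); ``favorite`` is the option currently
    believed higher; ``q`` the probability the favorite has been overtaken;
    ``ell`` counts trials since the agent's last exploratory choice and
    ``s_obs`` trials since it last observed a jump.
    """

    last_obs: tuple[Optional[float], Optional[float]] = (None, None)
    favorite: Optional[int] = None
    q: float = 0.0
    ell: int = 0
    s_obs: int = 0


def parity_update(q: float, h: float) -> float:
    """One-step update of the odd-number-of-unobserved-jumps probability.

    Given the current probability ``q`` that an odd number of unobserved
    jumps has occurred and a per-trial jump hazard ``h``, returns the
    probability of odd parity after one more trial.
    """
    return q * (1.0 - h) + (1.0 - q) * h


def believed_hazard(belief: BeliefState, config: AgentConfig) -> float:
    """The jump hazard the agent believes applies to the upcoming trial."""
    if config.kind == "reflective_ideal":
        if config.believed_p is None:
            raise ConfigurationError(
                "believed_p unset; run_agent resolves it from the environment"
            )
        return config.believed_p
    if config.kind == "reflective_fallacy":
        return min(config.believed_h0 + config.believed_dh * belief.s_obs, 1.0)
    raise ConfigurationError(
        f"believed_hazard is not applicable to agent kind {config.kind!r}"
    )


def observe(
    belief: BeliefState,
    choice: int,
    reward: float,
    config: AgentConfig,
) -> BeliefState:
    """Fold one reward observation into the belief state.

    A reward exceeding the option's last observed value reveals a jump and
    resets ``s_obs``.  An exploratory observation (choice of the non-favorite)
    discloses the current state of both options, so for reflective agents it
    collapses ``q`` to the one-step believed hazard.  Jumps revealed while
    exploiting update the value memory and ``s_obs`` but leave ``q`` alone:
    collapsing it there would make even the ideal agent's exploration depend
    on the time since an observed jump, a signature reserved for the fallacy
    belief.  A first observation of an option is never counted as an observed
    jump.
    """
    prev = belief.last_obs[choice]
    if prev is not None and reward < prev:
        raise BeliefDataError(
            f"reward {reward} below last observed value {prev} for option "
            f"{choice}; leapfrog values never decrease"
        )
    explored = belief.favorite is not None and choice != belief.favorite
    jump_seen = prev is not None and reward > prev

    last_obs = list(belief.last_obs)
    last_obs[choice] = reward
    observed = [i for i, v in enumerate(last_obs) if v is not None]
    favorite = max(observed, key=lambda i: last_obs[i]) if observed else None

    s_obs = 0 if jump_seen else belief.s_obs + 1
    ell = 0 if explored else belief.ell + 1

    new = BeliefState(
        last_obs=tuple(last_obs), favorite=favorite, q=belief.q, ell=ell, s_obs=s_obs
    )
    if config.kind in REFLECTIVE_KINDS and explored:
        new = replace(new, q=believed_hazard(new, config))
    return new


def choose(
    belief: BeliefState, config: AgentConfig, rng: np.random.Generator
) -> int:
    """Pick an option: exploit the favorite or explore the alternative."""
    if belief.favorite is None:
        return int(rng.integers(2))
    if config.kind == "reflexive":
        explore = rng.random() < config.epsilon
    else:
        explore = belief.q >= config.effective_theta
        if rng.random() < config.epsilon:  # lapse: invert the decision
            explore = not explore
    return 1 - belief.favorite if explore else belief.favorite


def _resolve_believed_p(env_config: EnvConfig, agent_config: AgentConfig) -> AgentConfig:
    if agent_config.kind == "reflective_ideal" and agent_config.believed_p is None:
        return replace(agent_config, believed_p=env_config.p_jump)
    return agent_config


def run_agent(
    env_config: EnvConfig,
    agent_config: AgentConfig,
    seed: Optional[int] = None,
    participant_id: str = "sim",
    group: str = "",
) -> pd.DataFrame:
    """Play one full episode and return a trial table.

    One RNG stream drives both the environment's jumps and the agent's
    choices, so an episode is fully reproducible from ``seed``.  The returned
    frame carries the canonical trial columns (``participant_id``, ``group``,
    ``condition``, ``trial``, ``choice``, ``reward``, ``rt_ms``) plus
    ground-truth columns (``v0``, ``v1``, ``jumped``, ``best``, ``correct``).
    """
    if seed is None:
        seed = agent_config.seed if agent_config.seed is not None else env_config.seed
    rng = np.random.default_rng(seed)
    agent_config = _resolve_believed_p(env_config, agent_config)

    state = initial_state(env_config)
    belief = BeliefState()
    records = []
    for _ in range(env_config.n_trials):
        if agent_config.kind in REFLECTIVE_KINDS and belief.favorite is not None:
            belief = replace(
                belief, q=parity_update(belief.q, believed_hazard(belief, agent_config))
            )
        choice = choose(belief, agent_config, rng)
        outcome, state = step(state, choice, env_config, rng)
        belief = observe(belief, choice, outcome.reward, agent_config)
        records.append(
            (
                outcome.t,
                choice,
                outcome.reward,
                state.values[0],
                state.values[1],
                outcome.jumped,
                outcome.best,
                outcome.correct,
            )
        )

    df = pd.DataFrame.from_records(
        records,
        columns=["trial", "choice", "reward", "v0", "v1", "jumped", "best", "correct"],
    )
    df.insert(0, "participant_id", participant_id)
    df.insert(1, "group", group)
    df.insert(2, "condition", env_config.condition)
    df["rt_ms"] = np.nan
    df["correct"] = df["correct"].astype(int)
    df["jumped"] = df["jumped"].astype(int)
    return df


def calibrate_theta(
    env_config: Optional[EnvConfig] = None,
    kind: str = "reflective_ideal",
    target_rate: float = 0.17,
    thetas: Optional[np.ndarray] = None,
    n_agents: int = 50,
    seed: int = 0,
) -> float:
    """Grid-search the explore threshold matching a target exploration rate.

    Simulates ``n_agents`` episodes per candidate ``theta`` and returns the
    candidate whose mean empirical exploration rate (fraction of non-favorite
    choices) is closest to ``target_rate``.
    """
    from .metrics import exploration_rate, label_explore

    if env_config is None:
        env_config = EnvConfig()
    if thetas is None:
        thetas = np.round(np.arange(0.10, 0.46, 0.02), 3)
    best_theta, best_err = None, np.inf
    ss = np.random.SeedSequence(seed)
    for theta in thetas:
        cfg = AgentConfig(kind=kind, theta=float(theta))
        rates = []
        for i, child in enumerate(ss.spawn(n_agents)):
            df = run_agent(
                env_config,
                cfg,
                seed=child.generate_state(1)[0],
                participant_id=f"cal{i}",
            )
            rates.append(exploration_rate(label_explore(df)))
        err = abs(float(np.mean(rates)) - target_rate)
        if err < best_err:
            best_theta, best_err = float(theta), err
    return best_theta
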