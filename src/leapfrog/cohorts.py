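"""Synthetic cohort and study generation.

Builds age-group-like cohorts as mixtures of reflexive, ideal-reflective and
fallacy-reflective agents playing the leapfrog environment, with lognormal
reaction times attached.  Default mixtures and RT medians are calibration
choices tuned to echo the two-group design (58 + 52 participants in the
single-condition study; 70/68/69/69 across the 2x2 study), not estimates of
any individual.

Every participant draws an independent RNG stream from one global seed, so a
whole study is reproducible from its spec.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agents import AgentConfig, run_agent
from .env import ConfigurationError, EnvConfig

__all__ = [
    "CohortSpec",
    "StudySpec",
    "young_like_mixture",
    "old_like_mixture",
    "exp1_like_study",
    "exp2_like_study",
    "generate_cohort",
    "generate_study",
]

#: Default exploration probability for reflexive mixture members.  The
#: old-like value is lower so the old-like cohort's mean exploration rate
#: lands near the young-like cohort's ~0.17 despite the fallacy agents'
#: higher rate (both human groups explored on ~17% of trials).
REFLEXIVE_EPSILON_YOUNG = 0.17
REFLEXIVE_EPSILON_OLD = 0.10

YOUNG_RT_MEDIAN_MS = 432.0
OLD_RT_MEDIAN_MS = 593.0


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic age-group cohort."""

    group: str
    n_participants: int
    env: EnvConfig
    mixture: tuple[tuple[AgentConfig, float], ...]
    rt_median_ms: float = 500.0
    rt_sigma: float = 0.25
    jitter: float = 0.0  # sd of per-agent perturbation of epsilon and theta
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.rt_median_ms <= 0:
            raise ConfigurationError("rt_median_ms must be positive")
        weights = [w for _, w in self.mixture]
        if not weights or any(w < 0 for w in weights):
            raise ConfigurationError("mixture weights must be nonnegative")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ConfigurationError("mixture weights must sum to 1")

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_participants": self.n_participants,
            "env": self.env.to_dict(),
            "mixture": [[a.to_dict(), w] for a, w in self.mixture],
            "rt_median_ms": self.rt_median_ms,
            "rt_sigma": self.rt_sigma,
            "jitter": self.jitter,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["env"] = EnvConfig.from_dict(d["env"])
        d["mixture"] = tuple(
            (AgentConfig.from_dict(a), float(w)) for a, w in d["mixture"]
        )
        return cls(**d)


@dataclass(frozen=True)
class StudySpec:
    name: str
    cohorts: tuple[CohortSpec, ...]

    def to_dict(self) -> dict:
        return {"name": self.name, "cohorts": [c.to_dict() for c in self.cohorts]}

    @classmethod
    def from_dict(cls, d: dict) -> "StudySpec":
        return cls(
            name=d["name"],
            cohorts=tuple(CohortSpec.from_dict(c) for c in d["cohorts"]),
        )


def young_like_mixture() -> tuple[tuple[AgentConfig, float], ...]:
    """86% ideal reflective + 14% reflexive (echoes 50-of-58 linear winners)."""
    return (
        (AgentConfig(kind="reflective_ideal"), 0.86),
        (AgentConfig(kind="reflexive", epsilon=REFLEXIVE_EPSILON_YOUNG), 0.14),
    )


def old_like_mixture() -> tuple[tuple[AgentConfig, float], ...]:
    """67% fallacy reflective + 33% reflexive.

    The fallacy members carry a milder believed ramp (0.04 base, 0.004/trial)
    than the class default: a steep believed ramp makes exploration collapse
    into bursts, whereas the human signature is a modest positive effect of
    time-since-observed-jump layered on an otherwise rising hazard curve.
    """
    return (
        (
            AgentConfig(
                kind="reflective_fallacy", believed_h0=0.04, believed_dh=0.004
            ),
            0.67,
        ),
        (AgentConfig(kind="reflexive", epsilon=REFLEXIVE_EPSILON_OLD), 0.33),
    )


def exp1_like_study(
    seed: Optional[int] = None,
    n_young: int = 58,
    n_old: int = 52,
    n_trials: int = 200,
) -> StudySpec:
    """Two cohorts in the independent environment (single-condition design)."""
    env = EnvConfig(condition="independent", n_trials=n_trials)
    root = np.random.SeedSequence(seed)
    s_young, s_old = (int(c.generate_state(1)[0]) for c in root.spawn(2))
    return StudySpec(
        name="exp1_like",
        cohorts=(
            CohortSpec(
                group="younger", n_participants=n_young, env=env,
                mixture=young_like_mixture(),
                rt_median_ms=YOUNG_RT_MEDIAN_MS, seed=s_young,
            ),
            CohortSpec(
                group="older", n_participants=n_old, env=env,
                mixture=old_like_mixture(),
                rt_median_ms=OLD_RT_MEDIAN_MS, seed=s_old,
            ),
        ),
    )


def exp2_like_study(
    seed: Optional[int] = None,
    cell_sizes: tuple[int, int, int, int] = (70, 68, 69, 69),
    n_trials: int = 200,
) -> StudySpec:
    """Four cohorts crossing group x condition.

    ``cell_sizes`` orders the cells (young-independent, old-independent,
    young-dependent, old-dependent), defaulting to 70/68/69/69.
    """
    root = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0]) for c in root.spawn(4)]
    cohorts = []
    cells = [
        ("younger", "independent", young_like_mixture(), YOUNG_RT_MEDIAN_MS),
        ("older", "independent", old_like_mixture(), OLD_RT_MEDIAN_MS),
        ("younger", "dependent", young_like_mixture(), YOUNG_RT_MEDIAN_MS),
        ("older", "dependent", old_like_mixture(), OLD_RT_MEDIAN_MS),
    ]
    for (group, cond, mixture, rt), n, s in zip(cells, cell_sizes, seeds):
        cohorts.append(
            CohortSpec(
                group=group, n_participants=n,
                env=EnvConfig(condition=cond, n_trials=n_trials),
                mixture=mixture, rt_median_ms=rt, seed=s,
            )
        )
    return StudySpec(name="exp2_like", cohorts=tuple(cohorts))


def _jitter_agent(
    agent: AgentConfig, scale: float, rng: np.random.Generator
) -> AgentConfig:
    if scale <= 0:
        return agent
    eps = float(np.clip(agent.epsilon + rng.normal(0.0, scale), 0.0, 0.95))
    updated = replace(agent, epsilon=eps)
    if agent.kind != "reflexive":
        theta = float(np.clip(
            agent.effective_theta + rng.normal(0.0, scale), 0.05, 0.45
        ))
        updated = replace(updated, theta=theta)
    return updated


def generate_cohort(spec: CohortSpec, id_prefix: str = "") -> pd.DataFrame:
    """Simulate every participant of a cohort and return one trial table.

    Each participant draws an agent kind from the mixture, gets jittered
    parameters, plays a fresh environment episode, and receives lognormal
    reaction times with the configured median and dispersion.
    """
    root = np.random.SeedSequence(spec.seed)
    weights = np.array([w for _, w in spec.mixture])
    agents = [a for a, _ in spec.mixture]
    frames = []
    for i, child in enumerate(root.spawn(spec.n_participants)):
        rng = np.random.default_rng(child)
        agent = agents[int(rng.choice(len(agents), p=weights))]
        agent = _jitter_agent(agent, spec.jitter, rng)
        pid = f"{id_prefix}{spec.group}_{spec.env.condition[:3]}_{i:03d}"
        df = run_agent(
            spec.env,
            agent,
            seed=int(rng.integers(2**63)),
            participant_id=pid,
            group=spec.group,
        )
        df["rt_ms"] = np.round(
            rng.lognormal(np.log(spec.rt_median_ms), spec.rt_sigma, len(df)), 1
        )
        df["agent_kind"] = agent.kind
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_study(spec: StudySpec) -> pd.DataFrame:
    """Concatenate all cohorts of a study into one trial table."""
    frames = [generate_cohort(c) for c in spec.cohorts]
    return pd.concat(frames, ignore_index=True)
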