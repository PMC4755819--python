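"""Leapfrog reward environment.

Two options whose point values alternate in superiority: at random times the
currently lower option permanently "jumps" up by a fixed increment, overtaking
the other.  Two hazard regimes are supported:

* ``independent`` — a constant per-trial jump probability.
* ``dependent`` — the jump probability starts low and ramps up linearly on
  every trial without a jump; it resets when a jump occurs.

Jumps are resolved at the start of each trial, before the choice, so the
reward paid on a trial always reflects the post-jump values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "EnvConfig",
    "EnvState",
    "TrialOutcome",
    "initial_state",
    "jump_hazard",
    "advance",
    "step",
    "simulate_values",
]

CONDITIONS = ("independent", "dependent")


class ConfigurationError(ValueError):
    """Raised for invalid environment or agent configuration."""


@dataclass(frozen=True)
class EnvConfig:
    """Parameters of a leapfrog environment episode.

    Parameters
    ----------
    condition:
        ``"independent"`` (constant hazard ``p_jump``) or ``"dependent"``
        (hazard ``h0 + dh*(s-1)`` where ``s`` counts trials since the last
        jump, capped at 1).
    p_jump:
        Constant per-trial jump probability in the independent condition.
    h0, dh:
        Base and per-trial increment of the dependent-condition hazard ramp.
    n_trials:
        Episode length.
    v_init:
        Starting point values of the two options; they must differ by
        ``jump_size / 2``.
    jump_size:
        Points added to the lower option when it jumps.
    seed:
        Seed for :func:`simulate_values`; ignored when an external RNG is
        supplied to the stepping functions.
    """

    condition: str = "independent"
    p_jump: float = 0.075
    h0: float = 0.01
    dh: float = 0.01
    n_trials: int = 200
    v_init: tuple[float, float] = (10.0, 20.0)
    jump_size: float = 20.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigurationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if not 0.0 < self.p_jump < 1.0:
            raise ConfigurationError("p_jump must lie in (0, 1)")
        if self.h0 <= 0.0:
            raise ConfigurationError("h0 must be positive")
        if self.dh < 0.0:
            raise ConfigurationError("dh must be nonnegative")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be at least 1")
        if self.jump_size <= 0.0:
            raise ConfigurationError("jump_size must be positive")
        if abs(abs(self.v_init[0] - self.v_init[1]) - self.jump_size / 2.0) > 1e-9:
            raise ConfigurationError(
                "v_init values must differ by jump_size / 2"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["v_init"] = list(self.v_init)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnvConfig":
        d = dict(d)
        if "v_init" in d:
            d["v_init"] = tuple(d["v_init"])
        return cls(**d)


@dataclass(frozen=True)
class EnvState:
    """Environment state at the *start* of trial ``t`` (pre-jump-resolution).

    ``s`` counts trials since the last jump; it equals 1 on the trial
    immediately after a jump (and on trial 1, before any jump has occurred),
    so the first post-jump trial of the dependent condition has hazard ``h0``.
    """

    t: int
    values: tuple[float, float]
    s: int
    total_jumps: int


@dataclass(frozen=True)
class TrialOutcome:
    t: int
    jumped: bool
    best: int
    choice: int
    reward: float
    correct: bool


def initial_state(config: EnvConfig) -> EnvState:
    return EnvState(t=1, values=tuple(config.v_init), s=1, total_jumps=0)


def jump_hazard(state: EnvState, config: EnvConfig) -> float:
    """Probability that a jump occurs on the current trial."""
    if config.condition == "independent":
        return config.p_jump
    if config.condition == "dependent":
        return min(config.h0 + config.dh * (state.s - 1), 1.0)
    raise ConfigurationError(f"unknown condition {config.condition!r}")


def advance(state: EnvState, config: EnvConfig, rng: np.random.Generator) -> EnvState:
    """Resolve the current trial's (possible) jump and move to the next trial.

    The returned state carries the post-resolution values; whether a jump
    occurred can be read off ``total_jumps``.
    """
    h = jump_hazard(state, config)
    jumped = bool(rng.random() < h)
    values = state.values
    if jumped:
        lo = 0 if values[0] < values[1] else 1
        values = (
            values[0] + config.jump_size * (lo == 0),
            values[1] + config.jump_size * (lo == 1),
        )
    return EnvState(
        t=state.t + 1,
        values=values,
        s=1 if jumped else state.s + 1,
        total_jumps=state.total_jumps + jumped,
    )


def step(
    state: EnvState,
    choice: int,
    config: EnvConfig,
    rng: np.random.Generator,
) -> tuple[TrialOutcome, EnvState]:
    """Play one trial: resolve the jump, pay out the chosen option."""
    if choice not in (0, 1):
        raise ValueError(f"choice must be 0 or 1, got {choice!r}")
    nxt = advance(state, config, rng)
    jumped = nxt.total_jumps > state.total_jumps
    best = int(np.argmax(nxt.values))
    outcome = TrialOutcome(
        t=state.t,
        jumped=jumped,
        best=best,
        choice=choice,
        reward=nxt.values[choice],
        correct=choice == best,
    )
    return outcome, nxt


def iter_values(
    config: EnvConfig, rng: Optional[np.random.Generator] = None
) -> Iterator[tuple[tuple[float, float], bool]]:
    """Yield ``(values, jumped)`` per trial, values post-jump-resolution."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = initial_state(config)
    for _ in range(config.n_trials):
        nxt = advance(state, config, rng)
        yield nxt.values, nxt.total_jumps > state.total_jumps
        state = nxt


def simulate_values(
    config: EnvConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Simulate a full reward trajectory.

    Returns a frame with columns ``trial`` (1-based), ``v0``, ``v1``,
    ``jumped`` — the true option values on each trial after jump resolution.
    Reproducible from ``config.seed``.
    """
    rows = list(iter_values(config, rng))
    return pd.DataFrame(
        {
            "trial": np.arange(1, config.n_trials + 1),
            "v0": [v[0] for v, _ in rows],
            "v1": [v[1] for v, _ in rows],
            "jumped": [j for _, j in rows],
        }
    )


def dependent_interval_pmf(config: EnvConfig, max_k: int = 10_000) -> np.ndarray:
    """Closed-form pmf of inter-jump intervals under the dependent ramp.

    ``pmf[k-1]`` is the probability the next jump lands exactly ``k`` trials
    after the previous one (hazard ``h0`` on the first post-jump trial).
    """
    ks = np.arange(1, max_k + 1)
    h = np.minimum(config.h0 + config.dh * (ks - 1), 1.0)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - h)[:-1]])
    return surv * h
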