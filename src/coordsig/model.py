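"""Core types for the generalized Bach-or-Stravinsky identity-signalling game.

A population of agents repeatedly plays a dyadic coordination game.  Each agent
has a fixed *preference type* giving its payoff for coordinating on each action
(miscoordination always pays 0), and a heritable *strategy profile* consisting
of a broadcast signal vector plus a contingent action for every signal
combination it can perceive.  Signalling and attending are coupled per
dimension: broadcasting the null signal 0 in dimension k means the agent
neither signals nor attends in k, and perceives every partner as silent there.
Attending to a dimension costs ``c`` per interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PreferenceType",
    "SignalSpace",
    "StrategyProfile",
    "ScenarioConfig",
    "perceived_combination",
    "interaction_payoff",
    "ConfigurationError",
    "DimensionalityError",
]


class ConfigurationError(ValueError):
    """Invalid scenario configuration or profile/payoff mismatch."""


class DimensionalityError(ValueError):
    """Profiles defined over incompatible signal spaces."""


@dataclass(frozen=True)
class PreferenceType:
    """A coordination-preference class of agents.

    ``payoffs[a]`` is the payoff pi_T(a) an agent of this type receives when
    both partners in a dyad resolve to action ``a``.  Failing to coordinate
    always pays 0.
    """

    id: int
    label: str
    payoffs: tuple[float, ...]
    proportion: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "payoffs", tuple(float(p) for p in self.payoffs))
        if any(p < 0 for p in self.payoffs):
            raise ConfigurationError(f"negative payoff for type {self.label!r}")

    @property
    def preferred_action(self) -> int:
        return int(np.argmax(self.payoffs))


@dataclass(frozen=True)
class SignalSpace:
    """D signalling dimensions, each with a null symbol 0 plus real signals.

    Dimension k offers symbols {0, 1, ..., alphabet_sizes[k]}.  Signal vectors
    and receivable combinations share a single mixed-radix enumeration with
    dimension 1 most significant and 0 sorting first, so serialized profiles
    are stable.
    """

    alphabet_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphabet_sizes", tuple(int(a) for a in self.alphabet_sizes))
        if any(a < 1 for a in self.alphabet_sizes):
            raise ConfigurationError("each dimension needs at least one real signal")

    @property
    def dims(self) -> int:
        return len(self.alphabet_sizes)

    @property
    def radices(self) -> tuple[int, ...]:
        return tuple(a + 1 for a in self.alphabet_sizes)

    @property
    def n_vectors(self) -> int:
        return int(np.prod(self.radices, dtype=np.int64)) if self.dims else 1

    @cached_property
    def vectors(self) -> np.ndarray:
        """All signal vectors / receivable combinations, enumeration order."""
        if self.dims == 0:
            return np.zeros((1, 0), dtype=np.int64)
        grids = np.meshgrid(*[np.arange(r) for r in self.radices], indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def vector_index(self, vec: Sequence[int]) -> int:
        vec = tuple(int(v) for v in vec)
        if len(vec) != self.dims:
            raise DimensionalityError(
                f"signal vector of length {len(vec)} in a {self.dims}-dimensional space"
            )
        idx = 0
        for v, r in zip(vec, self.radices):
            if not 0 <= v < r:
                raise ConfigurationError(f"signal symbol {v} outside alphabet (radix {r})")
            idx = idx * r + v
        return idx

    @property
    def combinations(self) -> list[tuple[int, ...]]:
        return [tuple(int(v) for v in row) for row in self.vectors]


def perceived_combination(
    observer: "StrategyProfile | Sequence[int]", partner: "StrategyProfile | Sequence[int]"
) -> tuple[int, ...]:
    """The partner's signal vector as the observer perceives it.

    Dimension k is replaced by the null symbol 0 whenever the observer itself
    broadcasts 0 in k (attention and broadcast are coupled per dimension).
    """
    obs = observer.signal if isinstance(observer, StrategyProfile) else tuple(observer)
    par = partner.signal if isinstance(partner, StrategyProfile) else tuple(partner)
    if len(obs) != len(par):
        raise DimensionalityError(
            f"observer has {len(obs)} signal dimensions, partner has {len(par)}"
        )
    return tuple(p if o != 0 else 0 for o, p in zip(obs, par))


@dataclass(frozen=True)
class StrategyProfile:
    """Broadcast signal vector plus a contingent action per receivable combination.

    ``actions`` is indexed by the space's combination enumeration; the
    canonical serialization is the D signal symbols followed by one action
    digit per combination.
    """

    space: SignalSpace
    signal: tuple[int, ...]
    actions: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "signal", tuple(int(s) for s in self.signal))
        object.__setattr__(self, "actions", tuple(int(a) for a in self.actions))
        if len(self.signal) != self.space.dims:
            raise DimensionalityError("signal length does not match signal-space dimensions")
        if len(self.actions) != self.space.n_vectors:
            raise ConfigurationError(
                f"profile needs an action for each of {self.space.n_vectors} combinations"
            )
        self.space.vector_index(self.signal)  # validates symbols

    @property
    def attended_dims(self) -> int:
        return sum(1 for s in self.signal if s != 0)

    def action_against(self, partner: "StrategyProfile") -> int:
        """Resolved action when meeting ``partner``: respond to the perceived combination."""
        combo = perceived_combination(self, partner)
        return self.actions[self.space.vector_index(combo)]

    def to_string(self) -> str:
        return "".join(str(s) for s in self.signal) + "".join(str(a) for a in self.actions)

    @classmethod
    def from_string(cls, space: SignalSpace, s: str) -> "StrategyProfile":
        d = space.dims
        if len(s) != d + space.n_vectors:
            raise ConfigurationError(f"serialized profile has wrong length {len(s)}")
        return cls(space, tuple(int(ch) for ch in s[:d]), tuple(int(ch) for ch in s[d:]))


def interaction_payoff(
    ego_type: PreferenceType,
    ego: StrategyProfile,
    partner: StrategyProfile,
    cost: float = 0.0,
) -> float:
    """Ego's payoff from one dyadic interaction.

    Both sides resolve their action through :func:`perceived_combination`; ego
    earns pi_T(a) if the resolved actions agree on ``a`` and 0 otherwise, minus
    ``cost`` for each non-null dimension of its own signal.  May be negative
    when costs exceed coordination payoffs.
    """
    a_ego = ego.action_against(partner)
    a_partner = partner.action_against(ego)
    if a_ego >= len(ego_type.payoffs):
        raise ConfigurationError(
            f"action {a_ego} outside payoff vector of type {ego_type.label!r}"
        )
    base = ego_type.payoffs[a_ego] if a_ego == a_partner else 0.0
    return base - cost * ego.attended_dims


@dataclass
class ScenarioConfig:
    """A fully specified simulation scenario."""

    types: list[PreferenceType]
    action_labels: tuple[str, ...]
    space: SignalSpace
    signal_cost: float = 0.0
    N: int = 1000
    mu1: float = 0.05
    mu2: float = 0.05
    steps: int = 6000
    convergence_tol: float = 1e-6
    convergence_window: int = 25
    mutation_mode: str = "sampled"
    seed: int = 0
    family: str = "custom"
    name: str = "custom"
    params: dict = field(default_factory=dict)

    @property
    def n_actions(self) -> int:
        return len(self.action_labels)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([t.proportion for t in self.types], dtype=float)

    def type_counts(self) -> np.ndarray:
        """Integer per-type agent counts; largest-remainder rounding to sum N."""
        raw = self.proportions * self.N
        counts = np.floor(raw).astype(int)
        short = self.N - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
        return counts

    def validate(self) -> "ScenarioConfig":
        if not self.types:
            raise ConfigurationError("scenario needs at least one preference type")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ConfigurationError("type proportions must sum to 1")
        for t in self.types:
            if len(t.payoffs) != self.n_actions:
                raise ConfigurationError(
                    f"type {t.label!r} has {len(t.payoffs)} payoffs for "
                    f"{self.n_actions} actions"
                )
        for rate in (self.mu1, self.mu2):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("mutation rates must lie in [0, 1]")
        if self.signal_cost < 0:
            raise ConfigurationError("signal cost must be non-negative")
        if self.N < 1 or self.steps < 1:
            raise ConfigurationError("N and steps must be positive")
        if not 0 <= self.seed < 2**31:
            raise ConfigurationError("seed must fit in a signed 32-bit integer")
        if self.mutation_mode not in ("sampled", "expected"):
            raise ConfigurationError(f"unknown mutation mode {self.mutation_mode!r}")
        return self

    def profile_length(self) -> int:
        return self.space.dims + self.space.n_vectors
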