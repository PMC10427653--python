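"""Simulated decision-makers for validating subjective-value recovery.

An :class:`Agent` assigns each strategy a euro-equivalent utility; the
total worth of an on-screen option is displayed money plus strategy
utility.  Choices are deterministic (argmax) at infinite inverse
temperature, logistic in the utility difference otherwise, with an
optional lapse: with probability ``lapse_rate`` the agent responds
uniformly at random, applied as an independent mixture after the
logistic draw (the standard psychometric lapse convention).

For a deterministic agent the titration reduces to a threshold rule:
facing flexible offer ``x`` against the 2 EUR anchor, it chooses the
flexible strategy iff ``x >= m*`` with indifference point
``m* = 2 + u_fixed - u_flexible``.  :class:`CyclicAgent` implements an
intransitive pairwise preference (A over B, B over C, C over A) used to
exercise the inconsistent response pattern in which no strategy attains
an aggregated subjective value of 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .strategies import Strategy, CANONICAL_ORDER, canonical_sort
from .titration import Offer, run_session

__all__ = [
    "Agent",
    "CyclicAgent",
    "AgentDistribution",
    "simulate_cohort",
    "deterministic_threshold_agent",
]


#: Utility differences below this are treated as exact ties.  Displayed
#: money and indifference points are multiples of 0.01 EUR, so genuine
#: differences are never this small; float round-off can be.
_TIE_EPS = 1e-9


def _tie_break(offer: Offer) -> Strategy:
    """Deterministic tie-break: the flexible strategy if one is titrated,
    else the canonically first strategy (used in the equal round)."""
    if offer.flexible is not None:
        return offer.flexible
    return canonical_sort(offer.strategies)[0]


@dataclass(frozen=True)
class Agent:
    """Parametric chooser: utilities in EUR, softmax noise, lapse."""

    utilities: dict
    inverse_temperature: float = math.inf  # 1/EUR; inf = deterministic
    lapse_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse rate must lie in [0, 0.5)")
        if self.inverse_temperature < 0:
            raise ValueError("inverse temperature must be non-negative")

    def option_value(self, offer: Offer, strategy: Strategy) -> float:
        return offer.value_of(strategy) + self.utilities[strategy]

    def choose(self, offer: Offer, rng: np.random.Generator) -> Strategy:
        left, right = offer.strategies
        d = self.option_value(offer, left) - self.option_value(offer, right)
        if math.isinf(self.inverse_temperature):
            if d > _TIE_EPS:
                picked = left
            elif d < -_TIE_EPS:
                picked = right
            else:
                picked = _tie_break(offer)
        else:
            p_left = 1.0 / (1.0 + math.exp(-self.inverse_temperature * d))
            picked = left if rng.random() < p_left else right
        if self.lapse_rate > 0.0 and rng.random() < self.lapse_rate:
            picked = left if rng.integers(2) else right
        return picked


def deterministic_threshold_agent(flexible: Strategy, fixed: Strategy, m_star: float) -> Agent:
    """Deterministic agent whose titration indifference point is ``m_star``.

    Chooses the flexible option iff its displayed value is >= ``m_star``
    (flexible on the exact tie).  Utilities are chosen so that the
    flexible strategy also wins the equal round.
    """
    if not 0.0 < m_star <= 2.0:
        raise ValueError("indifference point must lie in (0, 2]")
    return Agent(utilities={flexible: m_star, fixed: 2.0 * m_star - 2.0})


@dataclass(frozen=True)
class CyclicAgent:
    """Intransitive deterministic chooser defined by a preference cycle.

    ``cycle`` lists the strategies so that each is preferred to the next
    (and the last to the first) whenever money amounts are equal; with
    unequal money the preferred-strategy bonus ``strength`` (EUR) is
    added before comparing.
    """

    cycle: tuple = CANONICAL_ORDER
    strength: float = 10.0  # large enough to dominate any money difference

    def _prefers(self, a: Strategy, b: Strategy) -> bool:
        i = self.cycle.index(a)
        return self.cycle[(i + 1) % len(self.cycle)] == b

    def choose(self, offer: Offer, rng: np.random.Generator) -> Strategy:
        left, right = offer.strategies
        bonus_left = self.strength if self._prefers(left, right) else 0.0
        bonus_right = self.strength if self._prefers(right, left) else 0.0
        d = (offer.left_value + bonus_left) - (offer.right_value + bonus_right)
        if d > _TIE_EPS:
            return left
        if d < -_TIE_EPS:
            return right
        return _tie_break(offer)


@dataclass(frozen=True)
class AgentDistribution:
    """Population distribution from which cohort agents are drawn.

    Utilities are sampled per strategy as ``N(mean, sd)`` and then scaled
    by a per-agent dispersion factor ``exp(N(0, dispersion_log_sd))``,
    which models how strongly an individual differentiates between
    strategies (a purely additive shift common to all three strategies
    cancels in pairwise discounting and would be unidentifiable).
    """

    utility_means: dict = field(
        default_factory=lambda: {s: 0.0 for s in CANONICAL_ORDER}
    )
    utility_sd: float = 0.5
    dispersion_log_sd: float = 0.0
    inverse_temperature: float = math.inf
    lapse_rate: float = 0.0

    def draw(self, rng: np.random.Generator) -> Agent:
        scale = math.exp(rng.normal(0.0, self.dispersion_log_sd)) if self.dispersion_log_sd else 1.0
        utils = {
            s: scale * (self.utility_means[s] + rng.normal(0.0, self.utility_sd))
            for s in CANONICAL_ORDER
        }
        return Agent(
            utilities=utils,
            inverse_temperature=self.inverse_temperature,
            lapse_rate=self.lapse_rate,
        )


def simulate_cohort(n: int, agent_distribution: AgentDistribution, seed):
    """Draw ``n`` agents and run each through a full session.

    Returns ``(session_logs, agents)`` with the ground-truth agents
    aligned to the logs for recovery scoring.  Deterministic given
    ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    rng = np.random.default_rng(seed)
    agents, logs = [], []
    for i in range(n):
        agent = agent_distribution.draw(rng)
        agents.append(agent)
        logs.append(run_session(f"P{i + 1:03d}", agent, rng))
    return logs, agents
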