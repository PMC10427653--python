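"""Adaptive titration engine for the CAD discounting session.

One session compares the three strategy pairs.  Each pairing starts with
an *equal-value round*: three presentations offering 1.00 EUR for either
strategy.  The strategy chosen on at least two of the three becomes the
*flexible* strategy (its offer is titrated, starting at 1.00 EUR); the
other is anchored at the *fixed* reward of 2.00 EUR.  The pairing is then
presented six consecutive times.  After each of the first five choices
the flexible offer is lowered (flexible chosen) or raised (fixed chosen)
by an adjustment that starts at 0.50 EUR and halves at every step; the
sixth choice is only recorded — its 0.02 EUR effect is applied at the
valuation stage.

The internal offer is kept exact (a multiple of 1/32 EUR, exactly
representable in binary floating point); only the on-screen value is
rounded, half away from zero, to two decimals.  Rounding the adjustments
themselves would end the always-fixed path at 1.96 or 1.99 EUR instead
of the 1.97 EUR the display actually shows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .strategies import Strategy, ALL_PAIRS, canonical_sort

#: Fixed anchor reward in EUR.
FIXED_VALUE = 2.00
#: Starting offer of the flexible strategy in EUR.
START_VALUE = 1.00
#: First adjustment magnitude in EUR; halves after every applied step.
START_ADJUSTMENT = 0.50
#: Number of equal-value presentations per pairing.
N_EQUAL = 3
#: Number of titration presentations per pairing (five adjustments between them).
N_TITRATION = 6

PHASE_EQUAL = "equal"
PHASE_TITRATION = "titration"


def display_value(internal_value: float) -> float:
    """Round an exact internal offer to the 2-decimal on-screen value.

    Rounding is half away from zero: 1.875 -> 1.88 and 0.125 -> 0.13,
    the unique 2-decimal rule under which the extreme titration paths
    end at the displayed 1.97 and 0.03 EUR.
    """
    if not 0.0 < internal_value < FIXED_VALUE:
        raise ValueError(f"internal value {internal_value} outside (0, {FIXED_VALUE})")
    # internal values are multiples of 1/32 EUR, so 100 * value is exact
    return math.floor(internal_value * 100.0 + 0.5) / 100.0


@dataclass(frozen=True)
class Offer:
    """One on-screen presentation of a strategy pair with money amounts."""

    pair: frozenset
    presentation_index: int  # 1..3 equal round, 4..9 titration
    left_strategy: Strategy
    right_strategy: Strategy
    left_value: float  # displayed EUR, 2 decimals
    right_value: float
    phase: str = PHASE_EQUAL
    flexible: Strategy | None = None  # set during titration

    def __post_init__(self):
        if self.left_strategy == self.right_strategy:
            raise ValueError("offer must present two distinct strategies")
        if not 1 <= self.presentation_index <= N_EQUAL + N_TITRATION:
            raise ValueError(f"presentation index {self.presentation_index} out of range")

    def value_of(self, strategy: Strategy) -> float:
        if strategy == self.left_strategy:
            return self.left_value
        if strategy == self.right_strategy:
            return self.right_value
        raise ValueError(f"{strategy} not offered in this presentation")

    @property
    def strategies(self) -> tuple[Strategy, Strategy]:
        return (self.left_strategy, self.right_strategy)


@dataclass(frozen=True)
class ChoiceRecord:
    """One logged decision."""

    participant_id: str
    offer: Offer
    chosen: Strategy

    def __post_init__(self):
        if self.chosen not in self.offer.strategies:
            raise ValueError("chosen strategy was not on offer")

    @property
    def phase(self) -> str:
        return self.offer.phase


@dataclass(frozen=True)
class TitrationState:
    """Exact state of one pairing's staircase between presentations."""

    flexible: Strategy
    fixed: Strategy
    internal_value: float = START_VALUE  # exact multiple of 1/32 EUR
    adjustment: float = START_ADJUSTMENT
    step: int = 0  # adjustments applied so far, 0..5

    @property
    def displayed(self) -> float:
        return display_value(self.internal_value)


def titration_step(state: TitrationState, choice: Strategy) -> TitrationState:
    """Apply one staircase adjustment after a recorded choice.

    Choosing the flexible strategy lowers its offer by the current
    adjustment; choosing the fixed strategy raises it.  The adjustment
    then halves exactly.
    """
    if state.step >= N_TITRATION - 1:
        raise ValueError("all five adjustments of this pairing already applied")
    if choice == state.flexible:
        new_value = state.internal_value - state.adjustment
    elif choice == state.fixed:
        new_value = state.internal_value + state.adjustment
    else:
        raise ValueError(f"{choice} is not part of this pairing")
    return replace(
        state,
        internal_value=new_value,
        adjustment=state.adjustment / 2.0,
        step=state.step + 1,
    )


@dataclass(frozen=True)
class PairingResult:
    """Outcome of one pairing: equal-round votes and the final titration point."""

    flexible: Strategy
    fixed: Strategy
    last_display_value: float
    last_choice: Strategy
    equal_round_votes: tuple[Strategy, Strategy, Strategy]

    def __post_init__(self):
        if not 0.03 <= self.last_display_value <= 1.97:
            raise ValueError(
                f"last displayed value {self.last_display_value} outside [0.03, 1.97]"
            )


@dataclass
class SessionLog:
    """All choice records and pairing outcomes of one participant's session."""

    participant_id: str
    records: list[ChoiceRecord] = field(default_factory=list)
    pairing_results: list[PairingResult] = field(default_factory=list)


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _sided(pair, idx, rng, left_first: bool, values, phase, flexible=None) -> Offer:
    a, b = canonical_sort(pair)
    left, right = (a, b) if left_first else (b, a)
    vals = {a: values[a], b: values[b]}
    return Offer(
        pair=frozenset(pair),
        presentation_index=idx,
        left_strategy=left,
        right_strategy=right,
        left_value=vals[left],
        right_value=vals[right],
        phase=phase,
        flexible=flexible,
    )


def run_equal_round(pair, agent, rng_seed, participant_id="sim", start_index=1, log=None):
    """Present the pair three times at 1 EUR each; the majority winner becomes flexible.

    Returns ``(flexible, fixed, votes)``.  Three binary votes can never
    tie, so a strict majority always exists.  Side assignment is
    randomized per presentation from the session generator.
    """
    a, b = canonical_sort(pair)
    if a == b:
        raise ValueError("equal round needs two distinct strategies")
    rng = _as_rng(rng_seed)
    votes = []
    for i in range(N_EQUAL):
        offer = _sided(
            pair,
            start_index + i,
            rng,
            left_first=bool(rng.integers(2)),
            values={a: START_VALUE, b: START_VALUE},
            phase=PHASE_EQUAL,
        )
        choice = agent.choose(offer, rng)
        votes.append(choice)
        if log is not None:
            log.append(ChoiceRecord(participant_id, offer, choice))
    flexible = a if votes.count(a) >= 2 else b
    fixed = b if flexible == a else a
    return flexible, fixed, tuple(votes)


def run_pairing(pair, agent, rng_seed, participant_id="sim", log=None) -> PairingResult:
    """Run the equal round and six titration presentations of one pairing."""
    rng = _as_rng(rng_seed)
    if log is None:
        log = []
    flexible, fixed, votes = run_equal_round(
        pair, agent, rng, participant_id=participant_id, log=log
    )
    state = TitrationState(flexible=flexible, fixed=fixed)
    last_choice = None
    for i in range(N_TITRATION):
        offer = _sided(
            pair,
            N_EQUAL + 1 + i,
            rng,
            left_first=bool(rng.integers(2)),
            values={flexible: state.displayed, fixed: FIXED_VALUE},
            phase=PHASE_TITRATION,
            flexible=flexible,
        )
        last_choice = agent.choose(offer, rng)
        log.append(ChoiceRecord(participant_id, offer, last_choice))
        if i < N_TITRATION - 1:
            state = titration_step(state, last_choice)
    return PairingResult(
        flexible=flexible,
        fixed=fixed,
        last_display_value=state.displayed,
        last_choice=last_choice,
        equal_round_votes=votes,
    )


def run_session(participant_id, agent, rng_seed) -> SessionLog:
    """Run all three pairings in randomized order; 27 choice records total.

    Replayable bit-exactly: pair order, side assignment and any agent
    stochasticity all consume the single generator seeded by
    ``rng_seed``.
    """
    rng = _as_rng(rng_seed)
    session = SessionLog(participant_id=str(participant_id))
    order = rng.permutation(len(ALL_PAIRS))
    for k in order:
        result = run_pairing(
            ALL_PAIRS[k], agent, rng, participant_id=str(participant_id), log=session.records
        )
        session.pairing_results.append(result)
    return session
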