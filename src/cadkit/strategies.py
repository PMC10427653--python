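"""Emotion-regulation strategy labels and pairings.

Three strategies are compared pairwise in the discounting task:
distraction (attentional deployment), distancing (cognitive change) and
expressive suppression (response modulation).  Everything downstream is
keyed on these labels.  The canonical order (alphabetical) is used only
for deterministic tie-breaking and bookkeeping; it carries no claim
about difficulty or preference.
"""

from __future__ import annotations

import enum
import itertools


class Strategy(str, enum.Enum):
    """One of the three emotion-regulation strategies."""

    DISTANCING = "distancing"
    DISTRACTION = "distraction"
    SUPPRESSION = "suppression"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical (alphabetical) order, used for tie-breaking only.
CANONICAL_ORDER: tuple[Strategy, ...] = (
    Strategy.DISTANCING,
    Strategy.DISTRACTION,
    Strategy.SUPPRESSION,
)

#: The three unordered strategy pairings of one discounting session.
ALL_PAIRS: tuple[frozenset[Strategy], ...] = tuple(
    frozenset(p) for p in itertools.combinations(CANONICAL_ORDER, 2)
)


def canonical_sort(strategies) -> list[Strategy]:
    """Sort strategies into the canonical (alphabetical) order."""
    return sorted(strategies, key=CANONICAL_ORDER.index)


def pair_id(pair) -> str:
    """Stable identifier for an unordered strategy pair, e.g. ``distancing~distraction``."""
    a, b = canonical_sort(pair)
    return f"{a.value}~{b.value}"


def parse_strategy(label: str) -> Strategy:
    """Parse a strategy label, raising ``ValueError`` with the offending text."""
    try:
        return Strategy(label.strip().lower())
    except ValueError:
        raise ValueError(f"unknown strategy label: {label!r}") from None


#: Viewing conditions of the block design (no titration, ratings only).
VIEW_NEUTRAL = "view_neu"
VIEW_NEGATIVE = "view_neg"

#: All five block conditions in presentation order of the paradigm.
ALL_CONDITIONS: tuple[str, ...] = (
    VIEW_NEUTRAL,
    VIEW_NEGATIVE,
    Strategy.DISTRACTION.value,
    Strategy.DISTANCING.value,
    Strategy.SUPPRESSION.value,
)
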