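"""Subjective values (SVs) from titration outcomes.

Within one pairing the flexible strategy's SV is set to 1 (it was
preferred at equal money).  The fixed strategy's SV is derived from the
flexible strategy's last on-screen value: 0.02 EUR is subtracted if the
last choice was the flexible strategy, added if it was the fixed one
(the "sixth adjustment" applied at analysis time), and the result is
divided by the 2 EUR anchor.  Each strategy takes part in two of the
three pairings; its final SV is the mean of its two per-pairing SVs.

SV arithmetic deliberately uses the rounded on-screen value, not the
exact internal one: (0.03 - 0.02) / 2 = 0.005 reproduces the observable
minimum, whereas the exact internal endpoint would give 0.005625.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .strategies import Strategy, CANONICAL_ORDER, canonical_sort
from .titration import FIXED_VALUE, PairingResult, SessionLog

#: Post-hoc adjustment applied to the last displayed value (EUR).
FINAL_ADJUSTMENT = 0.02

#: Attainable range of a per-pairing fixed-strategy SV.
SV_MIN = (0.03 - FINAL_ADJUSTMENT) / FIXED_VALUE  # 0.005
SV_MAX_FIXED = (1.97 + FINAL_ADJUSTMENT) / FIXED_VALUE  # 0.995


@dataclass(frozen=True)
class SVProfile:
    """Per-participant aggregated subjective values and derived summaries.

    ``rank_code`` recodes the strategies by their SV rank: highest -1,
    middle 0, lowest 1 (a centered ordinal predictor).  The ordered-SV
    least-squares line over codes (-1, 0, 1) has intercept equal to the
    mean SV (how valuable regulation is overall) and a non-positive
    slope (how strongly one strategy is preferred; 0 = indifferent).
    """

    participant_id: str
    sv: dict
    rank_code: dict
    ordered_intercept: float
    ordered_slope: float
    predicted_choice: Strategy

    def __post_init__(self):
        if sorted(self.rank_code.values()) != [-1, 0, 1]:
            raise ValueError("rank codes must be a permutation of {-1, 0, 1}")
        if self.ordered_slope > 1e-12:
            raise ValueError("ordered-SV slope cannot be positive")


def pairing_sv(result: PairingResult) -> dict:
    """Per-pairing SVs: flexible -> 1.0, fixed -> (last display +/- 0.02) / 2."""
    v = result.last_display_value
    if result.last_choice == result.flexible:
        sv_fixed = (v - FINAL_ADJUSTMENT) / FIXED_VALUE
    elif result.last_choice == result.fixed:
        sv_fixed = (v + FINAL_ADJUSTMENT) / FIXED_VALUE
    else:
        raise ValueError("last choice does not belong to the pairing")
    return {result.flexible: 1.0, result.fixed: sv_fixed}


def ordered_sv_fit(svs) -> tuple[float, float]:
    """OLS of the three SVs, sorted descending, on codes (-1, 0, 1).

    Closed form: intercept = mean(sv), slope = (lowest - highest) / 2.
    """
    vals = sorted(svs, reverse=True)
    if len(vals) != 3:
        raise ValueError("exactly three subjective values expected")
    intercept = sum(vals) / 3.0
    slope = (vals[2] - vals[0]) / 2.0
    return intercept, slope


def aggregate_svs(participant_id, pairing_results) -> SVProfile:
    """Average per-pairing SVs across the two pairings of each strategy."""
    per_strategy: dict[Strategy, list[float]] = {s: [] for s in CANONICAL_ORDER}
    for result in pairing_results:
        for s, v in pairing_sv(result).items():
            per_strategy[s].append(v)
    bad = [s.value for s, vals in per_strategy.items() if len(vals) != 2]
    if bad:
        raise ValueError(f"incomplete session: strategies {bad} not in exactly 2 pairings")
    sv = {s: (vals[0] + vals[1]) / 2.0 for s, vals in per_strategy.items()}
    # rank: highest SV -> -1, middle -> 0, lowest -> 1; ties broken canonically
    ranked = sorted(CANONICAL_ORDER, key=lambda s: (-sv[s], CANONICAL_ORDER.index(s)))
    rank_code = {s: code for s, code in zip(ranked, (-1, 0, 1))}
    intercept, slope = ordered_sv_fit(sv.values())
    return SVProfile(
        participant_id=str(participant_id),
        sv=sv,
        rank_code=rank_code,
        ordered_intercept=intercept,
        ordered_slope=slope,
        predicted_choice=ranked[0],
    )


def profile_from_session(session: SessionLog) -> SVProfile:
    """Aggregate a full session log into an :class:`SVProfile`."""
    return aggregate_svs(session.participant_id, session.pairing_results)


def _threshold_walk(m_star: float) -> float:
    """Brute-force bracket oracle: per-pairing SV of the fixed strategy for
    a deterministic chooser with indifference point ``m_star``.

    Walks the halving staircase directly with plain arithmetic (chooses
    flexible iff the displayed value >= m_star), independent of the
    session engine.
    """
    eps = 1e-9  # displayed values and m* are 0.01 grid points; absorb float jitter
    value, adjustment = 1.0, 0.5
    for _ in range(5):
        disp = math.floor(value * 100.0 + 0.5) / 100.0
        if disp >= m_star - eps:  # flexible chosen -> lower its offer
            value -= adjustment
        else:
            value += adjustment
        adjustment /= 2.0
    disp = math.floor(value * 100.0 + 0.5) / 100.0
    if disp >= m_star - eps:
        return (disp - FINAL_ADJUSTMENT) / FIXED_VALUE
    return (disp + FINAL_ADJUSTMENT) / FIXED_VALUE


def expected_sv(agent) -> dict:
    """Analytic oracle: aggregated SVs a transitive deterministic agent
    must obtain, without running the session engine.

    For each pairing the higher-utility strategy is flexible (canonical
    order breaks exact ties, as in the equal round) and the fixed
    strategy's SV follows from the threshold walk at
    ``m* = 2 + u_fixed - u_flexible``.
    """
    if not math.isinf(agent.inverse_temperature) or agent.lapse_rate:
        raise ValueError("expected SVs are defined for deterministic agents only")
    u = agent.utilities
    per_strategy: dict[Strategy, list[float]] = {s: [] for s in CANONICAL_ORDER}
    from .strategies import ALL_PAIRS

    for pair in ALL_PAIRS:
        a, b = canonical_sort(pair)
        flexible = a if u[a] >= u[b] else b  # canonical tie-break
        fixed = b if flexible is a else a
        m_star = FIXED_VALUE + u[fixed] - u[flexible]
        per_strategy[flexible].append(1.0)
        per_strategy[fixed].append(_threshold_walk(m_star))
    return {s: (v[0] + v[1]) / 2.0 for s, v in per_strategy.items()}
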