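"""Synthetic cohort generator with the study's full data structure.

Emulates a cohort of participants who each complete the five-block
paradigm (neutral viewing, negative viewing, and the three regulation
strategies), rate arousal/effort/utility on a 0-300 continuous slider
after each block, carry per-trial facial-EMG activity summaries, and run
through the discounting session.  Subjective values are always produced
by running simulated agents through the titration engine — there is no
shortcut path from generator weights to SVs.

Agent utilities are built from the participant's own (within-centred)
effort, utility and corrugator scores so that configured regression
weights hold in expectation, plus an idiosyncratic utility component
whose per-participant dispersion creates between-subject SV variance.
A purely additive per-subject shift of all three utilities would cancel
in pairwise discounting, so subject-level heterogeneity enters through
the dispersion scale instead of an additive intercept.

Also hosts the evolutionary stimulus-set partitioner that splits a pool
of rated pictures into sets with matched valence and arousal means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .strategies import (
    CANONICAL_ORDER,
    ALL_CONDITIONS,
    VIEW_NEUTRAL,
    VIEW_NEGATIVE,
)
from .agents import Agent
from .titration import run_session
from .valuation import profile_from_session

REGULATION = tuple(s.value for s in CANONICAL_ORDER)

#: Condition-level rating and EMG means/SDs the generator reproduces
#: (slider units for ratings, mV for EMG).
CONDITION_TABLE = {
    "arousal": {
        VIEW_NEUTRAL: (26.6, 39.1),
        VIEW_NEGATIVE: (187.8, 87.3),
        "distraction": (158.1, 92.5),
        "distancing": (164.0, 87.2),
        "suppression": (168.6, 95.8),
    },
    "effort": {
        VIEW_NEUTRAL: (18.1, 27.4),
        VIEW_NEGATIVE: (49.4, 62.3),
        "distraction": (208.5, 96.1),
        "distancing": (189.8, 92.3),
        "suppression": (158.3, 99.5),
    },
    "utility": {
        "distraction": (216.6, 93.2),
        "distancing": (214.8, 78.6),
        "suppression": (229.3, 95.0),
    },
    "corrugator": {
        VIEW_NEUTRAL: (0.04, 6.99),
        VIEW_NEGATIVE: (1.03, 7.21),
        "distraction": (0.0, 7.67),
        "distancing": (0.25, 1.92),
        "suppression": (0.07, 3.78),
    },
    "levator": {
        VIEW_NEUTRAL: (0.09, 1.84),
        VIEW_NEGATIVE: (0.58, 3.2),
        "distraction": (-0.05, 1.16),
        "distancing": (0.01, 1.0),
        "suppression": (-0.03, 0.92),
    },
}


@dataclass
class StudyConfig:
    """Generator parameters; defaults emulate the study conditions."""

    n_participants: int = 120
    trials_per_block: int = 20
    scale_max: float = 300.0  # slider range upper bound
    rating_icc: float = 0.3  # between-subject share of rating variance
    emg_icc: float = 0.3  # between-subject share of condition-mean EMG variance
    condition_table: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in CONDITION_TABLE.items()
    })
    # regression weights linking within-centred predictors to agent utility
    # (EUR per predictor unit on the subjective-value scale, see methods)
    w_effort: float = -6.85e-4
    w_utility: float = 1.42e-3
    w_corrugator: float = 7.45e-3
    # idiosyncratic utility component (EUR); together with the dispersion
    # scale this sets the between-subject share of SV variance (the
    # defaults put the null-model ICC at about 0.19)
    utility_sd: float = 0.30
    dispersion_log_sd: float = 0.45
    # decision noise of the simulated participants
    inverse_temperature: float = 10.0
    lapse_rate: float = 0.02
    # probability that the actual last-block choice equals the predicted one
    choice_agreement: float = 0.75
    # questionnaire links (0 = no association, the study's null findings)
    flexer_mean: float = 50.0
    flexer_sd: float = 10.0
    flexer_w_intercept: float = 0.0
    flexer_w_slope: float = 0.0
    granularity: str = "trial"  # "trial" or "condition"

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.trials_per_block < 1:
            raise ValueError("need at least 1 trial per block")
        for name in ("rating_icc", "emg_icc"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        for measure, conds in self.condition_table.items():
            for cond, (mu, sd) in conds.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {measure}/{cond}")
        if not 0.0 <= self.choice_agreement <= 1.0:
            raise ValueError("choice agreement must be a probability")
        if self.granularity not in ("trial", "condition"):
            raise ValueError("granularity must be 'trial' or 'condition'")


@dataclass
class StudyData:
    """Everything one synthetic study produces."""

    table: pd.DataFrame  # long-format analysis table (strategy rows)
    blocks: pd.DataFrame  # block-level ratings/EMG for all five conditions
    session_logs: list
    profiles: list
    truth: dict


def _truncated_normal(rng, mu, sd, low, high, max_tries=200):
    """Draw one value by resampling (not clipping) into [low, high]."""
    if sd == 0:
        return float(min(max(mu, low), high))
    for _ in range(max_tries):
        x = rng.normal(mu, sd)
        if low <= x <= high:
            return float(x)
    return float(min(max(mu, low), high))  # pathological config; keep going


def generate_study(config: StudyConfig | None = None, seed=0) -> StudyData:
    """Generate ratings, EMG summaries, discounting sessions and questionnaires.

    Deterministic given ``seed``.  Returns the long-format analysis
    table (trial- or condition-granularity), the five-condition block
    table, the raw session logs, the SV profiles computed from them by
    the valuation module, and a ground-truth record.
    """
    config = config or StudyConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    tbl = config.condition_table
    n_trials = config.trials_per_block

    block_rows, table_rows = [], []
    logs, profiles, truth_agents = [], [], {}
    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        # shared subject effects (standard-normal, scaled per condition SD)
        z_subj = {m: rng.normal() for m in ("arousal", "effort", "utility",
                                            "corrugator", "levator")}
        ratings, trial_emg = {}, {}
        for cond in ALL_CONDITIONS:
            row = {"participant_id": pid, "condition": cond}
            for measure in ("arousal", "effort", "utility"):
                if cond not in tbl[measure]:
                    row[measure] = np.nan
                    continue
                mu, sd = tbl[measure][cond]
                b = math.sqrt(config.rating_icc) * sd * z_subj[measure]
                resid = math.sqrt(1.0 - config.rating_icc) * sd
                row[measure] = _truncated_normal(
                    rng, mu + b, resid, 0.0, config.scale_max
                )
            for measure in ("corrugator", "levator"):
                mu, sd = tbl[measure][cond]
                b = math.sqrt(config.emg_icc) * sd * z_subj[measure]
                resid = math.sqrt(1.0 - config.emg_icc) * sd
                # per-trial noise aggregates back to the condition-mean SD
                trial_sd = resid * math.sqrt(n_trials)
                trials = mu + b + rng.normal(0.0, trial_sd, size=n_trials)
                trial_emg[(cond, measure)] = trials
                row[measure] = float(trials.mean())
            block_rows.append(row)
            ratings[cond] = row

        # agent utilities from within-centred predictors + idiosyncrasy
        eff = np.array([ratings[s]["effort"] for s in REGULATION])
        uti = np.array([ratings[s]["utility"] for s in REGULATION])
        cor = np.array([ratings[s]["corrugator"] for s in REGULATION])
        struct = (
            config.w_effort * (eff - eff.mean())
            + config.w_utility * (uti - uti.mean())
            + config.w_corrugator * (cor - cor.mean())
        )
        scale = math.exp(rng.normal(0.0, config.dispersion_log_sd))
        idio = scale * rng.normal(0.0, config.utility_sd, size=3)
        utilities = dict(zip(CANONICAL_ORDER, 2.0 * struct + idio))
        agent = Agent(
            utilities=utilities,
            inverse_temperature=config.inverse_temperature,
            lapse_rate=config.lapse_rate,
        )
        session = run_session(pid, agent, rng)
        profile = profile_from_session(session)
        logs.append(session)
        profiles.append(profile)
        truth_agents[pid] = {s.value: u for s, u in utilities.items()}

        # last-block choice: agrees with the SV prediction at the set rate
        if rng.random() < config.choice_agreement:
            actual = profile.predicted_choice
        else:
            others = [s for s in CANONICAL_ORDER if s != profile.predicted_choice]
            actual = others[int(rng.integers(2))]

        flexer = (
            config.flexer_mean
            + config.flexer_w_intercept * profile.ordered_intercept
            + config.flexer_w_slope * profile.ordered_slope
            + rng.normal(0.0, config.flexer_sd)
        )
        self_control = float(rng.normal())
        nfc = float(rng.normal())

        for s in CANONICAL_ORDER:
            base = {
                "participant_id": pid,
                "strategy": s.value,
                "sv": profile.sv[s],
                "rank_code": profile.rank_code[s],
                "effort": ratings[s.value]["effort"],
                "arousal": ratings[s.value]["arousal"],
                "utility": ratings[s.value]["utility"],
                "flexer": flexer,
                "self_control": self_control,
                "nfc": nfc,
                "predicted_choice": profile.predicted_choice.value,
                "actual_choice": actual.value,
            }
            if config.granularity == "trial":
                for t in range(n_trials):
                    table_rows.append(
                        base
                        | {
                            "trial": t + 1,
                            "corrugator": trial_emg[(s.value, "corrugator")][t],
                            "levator": trial_emg[(s.value, "levator")][t],
                        }
                    )
            else:
                table_rows.append(
                    base
                    | {
                        "corrugator": ratings[s.value]["corrugator"],
                        "levator": ratings[s.value]["levator"],
                    }
                )

    truth = {
        "seed": int(seed) if np.isscalar(seed) else None,
        "config": {
            k: v for k, v in asdict(config).items() if k != "condition_table"
        },
        "agent_utilities": truth_agents,
    }
    return StudyData(
        table=pd.DataFrame(table_rows),
        blocks=pd.DataFrame(block_rows),
        session_logs=logs,
        profiles=profiles,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Evolutionary stimulus-set partitioning


@dataclass(frozen=True)
class StimulusSet:
    """One picture set with its mean normative ratings."""

    member_ids: tuple
    mean_valence: float
    mean_arousal: float


@dataclass
class GAParams:
    population: int = 60
    generations: int = 250
    tournament: int = 3
    elite: int = 2
    swaps_per_mutation: int = 1


def _partition_objective(assignment, ratings, k):
    """Sum over rating dimensions of the variance of the k set means."""
    total = 0.0
    for dim in range(ratings.shape[1]):
        means = np.array([ratings[assignment == g, dim].mean() for g in range(k)])
        total += float(means.var())
    return total


def partition_stimuli(ratings, k=5, set_size=20, ga_params: GAParams | None = None, seed=0):
    """Split rated items into ``k`` equal sets with matched rating means.

    Genetic search over permutations (contiguous chunks of a permutation
    define the sets): tournament selection, cross-set swap mutation and
    elitism, minimizing the summed variance of set means over the rating
    dimensions.  With elitism the best objective is non-increasing
    across generations.  Deterministic given ``seed``.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be an (items x dimensions) array")
    n = ratings.shape[0]
    if n != k * set_size:
        raise ValueError(f"{n} items cannot be split into {k} sets of {set_size}")
    params = ga_params or GAParams()
    rng = np.random.default_rng(seed)

    def assignment_of(perm):
        a = np.empty(n, dtype=int)
        for g in range(k):
            a[perm[g * set_size : (g + 1) * set_size]] = g
        return a

    pop = [rng.permutation(n) for _ in range(params.population)]
    fitness = np.array([_partition_objective(assignment_of(p), ratings, k) for p in pop])
    for _ in range(params.generations):
        order = np.argsort(fitness)
        new_pop = [pop[j].copy() for j in order[: params.elite]]
        while len(new_pop) < params.population:
            contenders = rng.integers(0, params.population, size=params.tournament)
            winner = contenders[np.argmin(fitness[contenders])]
            child = pop[winner].copy()
            for _ in range(params.swaps_per_mutation):
                i1, i2 = rng.integers(0, n, size=2)
                child[i1], child[i2] = child[i2], child[i1]
            new_pop.append(child)
        pop = new_pop
        fitness = np.array(
            [_partition_objective(assignment_of(p), ratings, k) for p in pop]
        )
    best = pop[int(np.argmin(fitness))]
    assignment = assignment_of(best)
    sets = []
    for g in range(k):
        ids = tuple(int(x) for x in np.flatnonzero(assignment == g))
        sets.append(
            StimulusSet(
                member_ids=ids,
                mean_valence=float(ratings[list(ids), 0].mean()),
                mean_arousal=float(ratings[list(ids), 1].mean()),
            )
        )
    return sets
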