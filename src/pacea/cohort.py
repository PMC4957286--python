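"""Synthetic participant-level cohort with the structure the model assumes.

The aggregate model inputs (activity distributions, completion fraction,
dropout ledger, mean non-completer cost) summarise an underlying
participant-level process: short-form activity-questionnaire answers
scored into low/moderate/high categories, a completion/dropout pathway,
and per-stage sports costs.  This module simulates that process and
provides estimators that recover the aggregates, so the full pipeline is
testable end to end without any external data.

Questionnaire scoring follows the standard short-form categorical
protocol: weekly MET-minutes are ``8 * vigorous + 4 * moderate + 3.3 *
walking`` minutes (sessions under 10 min/day contribute nothing), and the
category rules are encoded in :func:`ipaq_category` with the thresholds
exposed as module constants so a different scoring dialect can be swapped
in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import DROPOUT_STAGES, LEVELS, ProgrammeParams

__all__ = [
    "ipaq_category",
    "generate_cohort",
    "estimate_inputs",
    "RecoveredInputs",
    "default_stage_cost_schedule",
    "DEFAULT_FOLLOWUP_RESPONSE",
]

MET_VIGOROUS = 8.0
MET_MODERATE = 4.0
MET_WALKING = 3.3
MIN_SESSION_MINUTES = 10.0
HIGH_VIG_DAYS = 3
HIGH_VIG_MET = 1500.0
HIGH_ANY_DAYS = 7
HIGH_ANY_MET = 3000.0
MOD_VIG_DAYS = 3
MOD_VIG_MINUTES = 20.0
MOD_WALKMOD_DAYS = 5
MOD_WALKMOD_MINUTES = 30.0
MOD_ANY_DAYS = 5
MOD_ANY_MET = 600.0

#: follow-up questionnaire response probability among completers (52 of 159)
DEFAULT_FOLLOWUP_RESPONSE = 52 / 159


def ipaq_category(vig_days: int, vig_min_per_day: float, mod_days: int,
                  mod_min_per_day: float, walk_days: int,
                  walk_min_per_day: float) -> str:
    """Score one week of activity answers into 'low'/'moderate'/'high'."""
    for days in (vig_days, mod_days, walk_days):
        if not (0 <= days <= 7):
            raise ValueError("days must be in [0, 7]")
    for minutes in (vig_min_per_day, mod_min_per_day, walk_min_per_day):
        if minutes < 0:
            raise ValueError("minutes must be >= 0")
    vig_min = vig_min_per_day if vig_min_per_day >= MIN_SESSION_MINUTES else 0.0
    mod_min = mod_min_per_day if mod_min_per_day >= MIN_SESSION_MINUTES else 0.0
    walk_min = walk_min_per_day if walk_min_per_day >= MIN_SESSION_MINUTES else 0.0
    met = (MET_VIGOROUS * vig_days * vig_min
           + MET_MODERATE * mod_days * mod_min
           + MET_WALKING * walk_days * walk_min)
    any_days = vig_days + mod_days + walk_days
    if (vig_days >= HIGH_VIG_DAYS and met >= HIGH_VIG_MET) or \
            (any_days >= HIGH_ANY_DAYS and met >= HIGH_ANY_MET):
        return "high"
    if (vig_days >= MOD_VIG_DAYS and vig_min >= MOD_VIG_MINUTES) or \
            (mod_days >= MOD_WALKMOD_DAYS and mod_min >= MOD_WALKMOD_MINUTES) or \
            (walk_days >= MOD_WALKMOD_DAYS and walk_min >= MOD_WALKMOD_MINUTES) or \
            (any_days >= MOD_ANY_DAYS and met >= MOD_ANY_MET):
        return "moderate"
    return "low"


def default_stage_cost_schedule(p: ProgrammeParams) -> tuple[float, ...]:
    """A plausible cost allocation per dropout stage for the synthetic ledger.

    Never-starters incur nothing; a month-1 dropout incurs the induction;
    later dropouts additionally incur the first paid membership month.
    This is an audit device — its count-weighted mean is deliberately NOT
    forced to equal the published average non-completer cost, whose exact
    allocation is unpublished.
    """
    c = p.stage_cost_components
    first_month = c.induction + c.membership_per_month
    return (0.0, c.induction, first_month, first_month, first_month)


def _answers_for_level(level: str, rng: np.random.Generator) -> tuple:
    """Propose questionnaire answers whose score maps back to ``level``."""
    for _ in range(100):
        if level == "low":
            row = (int(rng.integers(0, 2)), float(rng.integers(0, 15)),
                   int(rng.integers(0, 3)), float(rng.integers(0, 20)),
                   int(rng.integers(0, 3)), float(rng.integers(0, 25)))
        elif level == "moderate":
            row = (0, 0.0,
                   int(rng.integers(5, 7)), float(rng.integers(30, 50)),
                   int(rng.integers(0, 2)), float(rng.integers(10, 20)))
        else:
            row = (int(rng.integers(5, 8)), float(rng.integers(45, 61)),
                   int(rng.integers(0, 3)), float(rng.integers(10, 30)),
                   int(rng.integers(0, 3)), float(rng.integers(10, 30)))
        if ipaq_category(*row) == level:
            return row
    raise RuntimeError(f"could not propose answers scoring as {level!r}")


def generate_cohort(n: int, seed: int, p: ProgrammeParams,
                    followup_response: float = DEFAULT_FOLLOWUP_RESPONSE,
                    stage_cost_schedule: tuple[float, ...] | None = None
                    ) -> pd.DataFrame:
    """Simulate ``n`` participants of the recruitment-and-completion process.

    Baseline levels are multinomial with the programme's baseline
    fractions; completion is Bernoulli at the completion fraction;
    non-completers drop out at a stage drawn proportional to the dropout
    ledger; completers' follow-up level is multinomial with the follow-up
    fractions and is observed only for the fraction who answer the
    follow-up questionnaire.  Sports costs accrue per the stage schedule
    (completers incur the full per-completer cost).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if stage_cost_schedule is None:
        stage_cost_schedule = default_stage_cost_schedule(p)
    if len(stage_cost_schedule) != len(DROPOUT_STAGES):
        raise ValueError("stage cost schedule length mismatch")

    base_fracs = np.array(p.baseline_activity.fractions)
    follow_fracs = np.array(p.followup_activity.fractions)
    drop_counts = np.array(p.dropout_counts, dtype=float)
    drop_probs = drop_counts / drop_counts.sum()

    baseline_level = rng.choice(len(LEVELS), size=n, p=base_fracs)
    completer = rng.random(n) < p.completion.value
    stage = np.full(n, "completed", dtype=object)
    stage_idx = rng.choice(len(DROPOUT_STAGES), size=(~completer).sum(), p=drop_probs)
    stage[~completer] = [DROPOUT_STAGES[i] for i in stage_idx]

    followup_level = np.full(n, None, dtype=object)
    responded = np.zeros(n, dtype=bool)
    comp_idx = np.flatnonzero(completer)
    fl = rng.choice(len(LEVELS), size=len(comp_idx), p=follow_fracs)
    resp = rng.random(len(comp_idx)) < followup_response
    for k, i in enumerate(comp_idx):
        if resp[k]:
            followup_level[i] = LEVELS[fl[k]]
            responded[i] = True

    cost = np.empty(n)
    cost[completer] = p.sports_cost_per_completer.value
    cost[~completer] = [stage_cost_schedule[i] for i in stage_idx]

    answers = {k: np.empty(n) for k in ("vig_days", "vig_min", "mod_days",
                                        "mod_min", "walk_days", "walk_min")}
    fu_answers = {f"fu_{k}": np.full(n, np.nan) for k in answers}
    for i in range(n):
        row = _answers_for_level(LEVELS[baseline_level[i]], rng)
        for k, v in zip(answers, row):
            answers[k][i] = v
        if responded[i]:
            row = _answers_for_level(followup_level[i], rng)
            for k, v in zip(answers, row):
                fu_answers[f"fu_{k}"][i] = v

    df = pd.DataFrame({
        "id": np.arange(n),
        **answers,
        "baseline_level": [LEVELS[i] for i in baseline_level],
        "completer": completer,
        "dropout_stage": stage,
        **fu_answers,
        "followup_level": followup_level,
        "sports_cost": cost,
    })
    return df


@dataclass(frozen=True)
class RecoveredInputs:
    """Aggregates estimated back from a participant-level cohort."""

    n: int
    completion_fraction: float
    baseline_fractions: tuple[float, float, float]
    followup_fractions: tuple[float, float, float] | None
    n_followup_respondents: int
    dropout_counts: tuple[int, ...]
    mean_noncompleter_cost: float


def estimate_inputs(records: pd.DataFrame) -> RecoveredInputs:
    """Recover the aggregate model inputs from a participant cohort.

    The follow-up distribution is computed only over completers with
    follow-up answers (missing-at-random assumption); with zero completers
    it is flagged unavailable (``None``).
    """
    if len(records) == 0:
        raise ValueError("no participant records")
    n = len(records)
    completers = records[records["completer"]]
    base = tuple((records["baseline_level"] == lv).mean() for lv in LEVELS)
    respondents = completers[completers["followup_level"].notna()]
    follow = (tuple((respondents["followup_level"] == lv).mean() for lv in LEVELS)
              if len(respondents) else None)
    noncomp = records[~records["completer"]]
    drop = tuple(int((noncomp["dropout_stage"] == s).sum()) for s in DROPOUT_STAGES)
    return RecoveredInputs(
        n=n,
        completion_fraction=len(completers) / n,
        baseline_fractions=base,
        followup_fractions=follow,
        n_followup_respondents=len(respondents),
        dropout_counts=drop,
        mean_noncompleter_cost=float(noncomp["sports_cost"].mean()) if len(noncomp) else 0.0,
    )
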