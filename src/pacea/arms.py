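"""Arm and stratum construction, and programme cost accounting.

The intervention is modelled per *recruited* person.  Completers (fraction
``c``) hold their end-of-programme activity level for the duration of
effect ``D`` months and then revert to the overall baseline distribution;
everyone else stays at baseline throughout.  Because the joint
(before, after) distribution of completers is not observed, reversion uses
the assumption-minimal independence coupling: a completer at follow-up
level *i* reverts to baseline level *j* with probability ``f_i * b_j``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .params import LEVELS, ProgrammeParams

__all__ = [
    "Stratum",
    "ArmSpec",
    "programme_cost_per_recruit",
    "build_arms",
    "noncompleter_cost_from_ledger",
]


@dataclass(frozen=True)
class Stratum:
    """A fixed-weight activity pathway within an arm.

    ``activity_before`` applies for cycles ``0 .. D-1`` and
    ``activity_after`` from cycle ``D`` on, where ``D`` is the programme's
    duration of effect in months.  Strata that never switch simply have
    ``activity_after == activity_before``.
    """

    weight: float
    activity_before: str
    activity_after: str

    def __post_init__(self) -> None:
        if self.activity_before not in LEVELS or self.activity_after not in LEVELS:
            raise ValueError("unknown activity level")
        if self.weight < 0:
            raise ValueError("stratum weight must be >= 0")


@dataclass(frozen=True)
class ArmSpec:
    name: str
    strata: tuple[Stratum, ...]
    upfront_cost_per_person: float

    def __post_init__(self) -> None:
        total = sum(s.weight for s in self.strata)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stratum weights sum to {total}, not 1")
        if self.upfront_cost_per_person < 0:
            raise ValueError("upfront cost must be >= 0")


def programme_cost_per_recruit(p: ProgrammeParams) -> float:
    """Mean programme cost per recruited person.

    General costs accrue for everyone; sports-related costs accrue in full
    for completers and at the observed average for non-completers.
    """
    c = p.completion.value
    return (p.general_cost_per_recruit.value
            + c * p.sports_cost_per_completer.value
            + (1.0 - c) * p.sports_cost_per_noncompleter.value)


def build_arms(p: ProgrammeParams) -> tuple[ArmSpec, ArmSpec]:
    """Build the (intervention, control) arm specifications.

    Control: one stratum per baseline activity level, never switching, no
    upfront cost.  Intervention: non-completers mirror the control strata
    at weight ``(1-c) * b_j``; completers contribute nine product-coupled
    strata at weight ``c * f_i * b_j`` (follow-up level *i* before the
    duration of effect elapses, baseline level *j* after).
    """
    c = p.completion.value
    base = dict(zip(LEVELS, p.baseline_activity.fractions))
    follow = dict(zip(LEVELS, p.followup_activity.fractions))

    control = ArmSpec(
        name="control",
        strata=tuple(Stratum(base[j], j, j) for j in LEVELS),
        upfront_cost_per_person=0.0,
    )
    strata = [Stratum((1.0 - c) * base[j], j, j) for j in LEVELS]
    strata += [Stratum(c * follow[i] * base[j], i, j) for i in LEVELS for j in LEVELS]
    intervention = ArmSpec(
        name="intervention",
        strata=tuple(strata),
        upfront_cost_per_person=programme_cost_per_recruit(p),
    )
    return intervention, control


def noncompleter_cost_from_ledger(dropout_counts: Sequence[int],
                                  stage_cost_schedule: Sequence[float]) -> float:
    """Count-weighted mean sports cost over non-completers.

    ``dropout_counts[k]`` is the number of participants who left at stage
    ``k`` (stage 0 = never started) and ``stage_cost_schedule[k]`` the cost
    a participant leaving at that stage is allocated.  This is an audit /
    synthetic-pipeline device: the base-case analysis takes the published
    average non-completer cost as a primitive input, because the exact
    stage allocation behind it is not published.
    """
    if len(dropout_counts) == 0:
        raise ValueError("empty dropout ledger")
    if len(dropout_counts) != len(stage_cost_schedule):
        raise ValueError("schedule length must match the number of stages")
    if any(n < 0 for n in dropout_counts):
        raise ValueError("dropout counts must be >= 0")
    total = sum(dropout_counts)
    if total == 0:
        raise ValueError("dropout ledger has no participants")
    return sum(n * k for n, k in zip(dropout_counts, stage_cost_schedule)) / total
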