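"""Independent reference implementation of one stratum's cohort dynamics.

A deliberately slow, dictionary-based simulator built only from the scalar
per-state operations (transition rows, utilities, cycle costs).  It shares
no code with the vectorized engine's occupancy bookkeeping, so agreement
between the two is a real consistency check of the engine's tunnel shifts,
event-cost timing and discounting.
"""

import math
from collections import defaultdict

from pacea.markov import (HealthState, build_transition_row, cycle_cost,
                          state_utility)


def simulate_stratum(mp, lt, before, after, duration_months):
    """Run one stratum to the horizon; returns (cost, qaly, ly, ly_disc)."""
    start = int(round(mp.settings.starting_age.value))
    max_age = mp.settings.max_age
    rate = mp.settings.annual_discount_rate
    ceil_d = math.ceil(duration_months)
    horizon = (max_age - start) * 12

    occ = {("healthy",): 1.0}
    cost = qaly = ly = lyd = 0.0
    for t in range(horizon):
        age = start + t // 12
        level = before if t < ceil_d else after
        df = (1.0 + rate) ** (-t / 12.0)
        for state, mass in occ.items():
            if state[0] == "dead" or mass == 0.0:
                continue
            hs = HealthState(state[0], state[1] if len(state) > 1 else None)
            qaly += mass * state_utility(hs, age, level, mp) / 12.0 * df
            ly += mass / 12.0
            lyd += mass / 12.0 * df
            if state[0] != "healthy":
                cost += mass * cycle_cost(hs, False, mp) * df
        new = defaultdict(float)
        for state, mass in occ.items():
            if mass == 0.0:
                continue
            if state[0] == "dead":
                new[("dead",)] += mass
                continue
            hs = HealthState(state[0], state[1] if len(state) > 1 else None)
            if state[0] == "healthy":
                row, ex = build_transition_row(hs, age, level, mp, lt, detail=True)
                new[("healthy",)] += mass * row["healthy"]
                new[("chd", 0)] += mass * row["chd"]
                new[("stroke", 0)] += mass * row["stroke"]
                new[("diabetes",)] += mass * row["diabetes"]
                new[("dead",)] += mass * row["dead"]
                cost += mass * (row["chd"] + ex["dead_via_chd"]) * \
                    cycle_cost(HealthState("chd"), True, mp) * df
                cost += mass * (row["stroke"] + ex["dead_via_stroke"]) * \
                    cycle_cost(HealthState("stroke"), True, mp) * df
            elif state[0] == "diabetes":
                row = build_transition_row(hs, age, level, mp, lt)
                new[("diabetes",)] += mass * row["diabetes"]
                new[("dead",)] += mass * row["dead"]
            else:
                row = build_transition_row(hs, age, level, mp, lt)
                new[(state[0], min(state[1] + 1, 12))] += mass * row[state[0]]
                new[("dead",)] += mass * row["dead"]
        occ = dict(new)
    return cost, qaly, ly, lyd
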