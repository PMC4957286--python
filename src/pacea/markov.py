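"""Lifetime Markov cohort engine.

Health states are healthy, three chronic disease states (coronary heart
disease, stroke, type II diabetes) and dead; disease states carry a
12-month "first year after onset" tunnel that drives the first-event
utility weight.  Cycles are monthly; the cohort starts 100 % healthy at
the starting age and runs until everyone is dead (occupancy remaining at
the maximum age is forced into the dead state).

Two surfaces are provided over the same arithmetic:

* a scalar per-state API (:func:`build_transition_row`,
  :func:`state_utility`, :func:`cycle_cost`) used for inspection and
  testing, and
* a vectorized engine (:func:`run_cohort`, :func:`run_incremental_batch`)
  that evaluates all activity-pathway strata — and, for probabilistic
  sensitivity analysis, whole batches of parameter draws — in one pass.

Modelling conventions: annual rates convert to monthly probabilities by
constant-hazard ``1 - exp(-r/12)``; relative risks act multiplicatively on
incidence probabilities and on cause-specific mortality hazards; disease
utility weights multiply the age-specific healthy utility; the
mental-wellbeing gain is additive on the utility scale in every alive
state (total utility clamped to 1); no half-cycle correction is applied;
discounting is ``(1 + rate)^(-t)`` with ``t`` in years from model start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .arms import ArmSpec
from .lifetable import LifeTable, background_death_probs
from .params import DISEASES, LEVELS, ModelParameters

__all__ = [
    "HealthState",
    "CohortResult",
    "annual_rate_to_monthly_prob",
    "incidence_probability",
    "build_transition_row",
    "state_utility",
    "cycle_cost",
    "run_cohort",
    "run_incremental_batch",
    "TUNNEL_MONTHS",
]

TUNNEL_MONTHS = 12
STATE_NAMES = ("healthy", "chd", "stroke", "diabetes", "dead")
#: the nine (level before switch, level after switch) activity pathways
COMBOS = tuple((i, j) for i in range(3) for j in range(3))


@dataclass(frozen=True)
class HealthState:
    """A model state; disease states carry months since onset (0-based)."""

    name: str
    months_since_onset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.name not in STATE_NAMES:
            raise ValueError(f"unknown state {self.name!r}")
        if self.name in ("chd", "stroke", "diabetes") and self.months_since_onset is None:
            object.__setattr__(self, "months_since_onset", 0)


@dataclass(frozen=True)
class CohortResult:
    """Discounted totals per person for one arm, plus an optional trace."""

    discounted_cost: float
    discounted_qaly: float
    life_years: float            # undiscounted
    discounted_life_years: float
    trace: Optional[pd.DataFrame] = None


class ModelConsistencyError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# scalar operations

def annual_rate_to_monthly_prob(r: float) -> float:
    """Constant-hazard conversion of a yearly rate to a monthly probability."""
    if r < 0:
        raise ValueError("annual rate must be >= 0")
    return -math.expm1(-r / 12.0)


def incidence_probability(disease: str, age: int, level: str,
                          params: ModelParameters) -> float:
    """Monthly probability of an incident event for the given activity level."""
    base = annual_rate_to_monthly_prob(params.disease(disease).incidence.value(age))
    return base * params.relative_risks.for_disease(disease).factor(level)


def _healthy_row_components(age: int, level: str, params: ModelParameters,
                            lt: LifeTable) -> dict:
    p = {d: incidence_probability(d, age, level, params) for d in DISEASES}
    fatal = {d: (params.disease(d).fatal_fraction.value(age)
                 if params.disease(d).fatal_fraction is not None else 0.0)
             for d in DISEASES}
    p_cvd, p_non = background_death_probs(lt, age, 1.0, 1.0)
    p_bg = float(p_cvd + p_non)
    total = p["chd"] + p["stroke"] + p["diabetes"] + p_bg
    scale = 1.0 / total if total > 1.0 else 1.0
    return {
        "chd": p["chd"] * (1 - fatal["chd"]) * scale,
        "stroke": p["stroke"] * (1 - fatal["stroke"]) * scale,
        "diabetes": p["diabetes"] * scale,
        "dead_via_chd": p["chd"] * fatal["chd"] * scale,
        "dead_via_stroke": p["stroke"] * fatal["stroke"] * scale,
        "dead_background": p_bg * scale,
    }


def build_transition_row(state: HealthState, age: int, level: str,
                         params: ModelParameters, lt: LifeTable,
                         detail: bool = False):
    """One row of the transition matrix over (healthy, chd, stroke, diabetes, dead).

    Competing exits are summed and, in the (never attained at plausible
    inputs) case that they exceed 1, proportionally normalized.  Disease
    states exit only to dead, via cause-split background mortality under
    that disease's post-event relative risks; dead is absorbing.
    """
    row = dict.fromkeys(STATE_NAMES, 0.0)
    extras: dict = {}
    if state.name == "healthy":
        comp = _healthy_row_components(age, level, params, lt)
        row["chd"] = comp["chd"]
        row["stroke"] = comp["stroke"]
        row["diabetes"] = comp["diabetes"]
        row["dead"] = (comp["dead_via_chd"] + comp["dead_via_stroke"]
                       + comp["dead_background"])
        row["healthy"] = 1.0 - sum(v for k, v in row.items() if k != "healthy")
        extras = {k: comp[k] for k in ("dead_via_chd", "dead_via_stroke",
                                       "dead_background")}
    elif state.name == "dead":
        row["dead"] = 1.0
    else:
        rr = params.mortality_rrs.for_disease(state.name)
        p_cvd, p_non = background_death_probs(lt, age, rr.cvd.value, rr.non_cvd.value)
        dd = min(float(p_cvd + p_non), 1.0)
        row["dead"] = dd
        row[state.name] = 1.0 - dd
        extras = {"dead_cvd": float(p_cvd), "dead_noncvd": float(p_non)}
    return (row, extras) if detail else row


def state_utility(state: HealthState, age: int, level: str,
                  params: ModelParameters) -> float:
    """Annual utility weight: age utility x disease multiplier + mental-health gain."""
    if state.name == "dead":
        return 0.0
    u_age = params.utilities.age_bands.value(age)
    if state.name == "healthy":
        mult = 1.0
    elif state.name == "diabetes":
        mult = params.utilities.diabetes.value
    else:
        first = state.months_since_onset is not None and \
            state.months_since_onset < TUNNEL_MONTHS
        key = f"{state.name}_{'first' if first else 'post'}_event"
        mult = getattr(params.utilities, key).value
    u = u_age * mult + params.utilities.mh_gain(level)
    return min(max(u, 0.0), 1.0)


def cycle_cost(state: HealthState, entering_event: bool,
               params: ModelParameters) -> float:
    """GBP accrued in one monthly cycle for a person in ``state``.

    The one-off acute cost is charged in the incidence cycle (for CHD and
    stroke, whether or not the event proves immediately fatal); occupancy
    of a disease state thereafter accrues the annual state cost / 12.
    """
    if state.name in ("healthy", "dead"):
        return 0.0
    dp = params.disease(state.name)
    if entering_event:
        return dp.first_event_cost.value if dp.first_event_cost is not None else 0.0
    return dp.annual_state_cost.value / 12.0


# --------------------------------------------------------------------------
# vectorized engine

class _EngineInputs:
    """Per-draw parameter arrays shared by all strata (batch dimension B)."""

    def __init__(self, mps: Sequence[ModelParameters], lt: LifeTable):
        B = len(mps)
        mp0 = mps[0]
        self.B = B
        self.max_age = mp0.settings.max_age
        self.rate = mp0.settings.annual_discount_rate
        A = self.max_age  # ages indexed 0..max_age
        ages = np.arange(A + 1)

        self.start = np.array(
            [int(round(mp.settings.starting_age.value)) for mp in mps])
        if np.any(self.start >= self.max_age):
            raise ValueError("starting age must be below the maximum age")
        self.ceil_D = np.array(
            [int(math.ceil(mp.programme.duration_of_effect_months.value)) for mp in mps])

        self.q_by_age = np.asarray(lt.q_at(ages), dtype=float)
        self.cvd_by_age = np.asarray(lt.cvd_at(ages), dtype=float)

        def band_arrays(tables):
            # all draws share the band structure; only values differ
            bands0 = tables[0].bands
            los = np.array([b.age_lo for b in bands0])
            idx = np.clip(np.searchsorted(los, ages, side="right") - 1, 0,
                          len(bands0) - 1)
            vals = np.array([[b.param.value for b in t.bands] for t in tables])
            return vals[:, idx]  # (B, A+1)

        self.inc_by_age = {d: band_arrays([mp.disease(d).incidence for mp in mps])
                           for d in DISEASES}
        self.fatal_by_age = {d: band_arrays([mp.disease(d).fatal_fraction for mp in mps])
                             for d in ("chd", "stroke")}
        self.u_age_by_age = band_arrays([mp.utilities.age_bands for mp in mps])

        self.rr_inc = np.ones((B, 3, 3))  # (draw, disease, level)
        for bi, mp in enumerate(mps):
            for di, d in enumerate(DISEASES):
                rr = mp.relative_risks.for_disease(d)
                self.rr_inc[bi, di, 1] = rr.moderate.value
                self.rr_inc[bi, di, 2] = rr.high.value
        self.mort_rr = np.empty((B, 3, 2))  # (draw, disease, cause cvd/noncvd)
        for bi, mp in enumerate(mps):
            for di, d in enumerate(DISEASES):
                rr = mp.mortality_rrs.for_disease(d)
                self.mort_rr[bi, di, 0] = rr.cvd.value
                self.mort_rr[bi, di, 1] = rr.non_cvd.value

        self.u_first = np.array([[mp.utilities.chd_first_event.value,
                                  mp.utilities.stroke_first_event.value] for mp in mps])
        self.u_post = np.array([[mp.utilities.chd_post_event.value,
                                 mp.utilities.stroke_post_event.value] for mp in mps])
        self.u_dia = np.array([mp.utilities.diabetes.value for mp in mps])
        self.mh = np.array([[0.0, mp.utilities.mh_gain_moderate.value,
                             mp.utilities.mh_gain_high.value] for mp in mps])
        self.c_first = np.array([[mp.chd.first_event_cost.value,
                                  mp.stroke.first_event_cost.value] for mp in mps])
        self.c_annual = np.array([[mp.chd.annual_state_cost.value,
                                   mp.stroke.annual_state_cost.value,
                                   mp.diabetes.annual_state_cost.value] for mp in mps])


class _ComboResults:
    def __init__(self, cost, qaly, ly_d, ly_u, trace=None):
        self.cost = cost          # (B, 9)
        self.qaly = qaly
        self.ly_disc = ly_d
        self.ly_undisc = ly_u
        self.trace = trace


def _run_combos(ei: _EngineInputs, collect_trace: bool = False) -> _ComboResults:
    B, S = ei.B, len(COMBOS)
    before = np.array([c[0] for c in COMBOS])
    after = np.array([c[1] for c in COMBOS])
    T = int((ei.max_age - ei.start.min()) * 12)
    rows = np.arange(B)[:, None]

    # per-cycle, per-draw precomputations (level-independent)
    tt = np.arange(T)
    age_bt = np.minimum(ei.start[:, None] + tt[None, :] // 12, ei.max_age)  # (B,T)
    q = ei.q_by_age[age_bt]
    cvd = ei.cvd_by_age[age_bt]
    h_all = -np.log1p(-np.minimum(q, 1 - 1e-15))
    p_bg = -np.expm1(-h_all * cvd) - np.expm1(-h_all * (1 - cvd))
    dd = np.empty((B, T, 3))
    for di in range(3):
        p_c = -np.expm1(-h_all * cvd * ei.mort_rr[:, di, 0][:, None])
        p_n = -np.expm1(-h_all * (1 - cvd) * ei.mort_rr[:, di, 1][:, None])
        dd[:, :, di] = np.minimum(p_c + p_n, 1.0)
    inc_m = np.stack(
        [-np.expm1(-np.take_along_axis(ei.inc_by_age[d], age_bt, axis=1) / 12.0)
         for d in DISEASES], axis=-1)                      # (B,T,3)
    fatal = np.stack(
        [np.take_along_axis(ei.fatal_by_age[d], age_bt, axis=1)
         for d in ("chd", "stroke")], axis=-1)             # (B,T,2)
    u_age = np.take_along_axis(ei.u_age_by_age, age_bt, axis=1)  # (B,T)
    disc = (1.0 + ei.rate) ** (-(tt / 12.0))
    active = (age_bt < ei.max_age).astype(float)           # (B,T)

    # occupancy
    healthy = np.ones((B, S))
    chd_tun = np.zeros((B, S, TUNNEL_MONTHS))
    str_tun = np.zeros((B, S, TUNNEL_MONTHS))
    chd_post = np.zeros((B, S))
    str_post = np.zeros((B, S))
    dia = np.zeros((B, S))
    dead = np.zeros((B, S))

    cost = np.zeros((B, S))
    qaly = np.zeros((B, S))
    ly_d = np.zeros((B, S))
    ly_u = np.zeros((B, S))

    trace_frames = [] if collect_trace else None

    for t in range(T):
        act = active[:, t][:, None]
        if not np.any(act):
            break
        # cohort members past the maximum age are forced into the dead state
        expired = act == 0.0
        if np.any(expired):
            lost = (healthy + chd_tun.sum(-1) + chd_post + str_tun.sum(-1)
                    + str_post + dia) * expired
            dead += lost
            for arr in (healthy, chd_post, str_post, dia):
                arr *= act
            chd_tun *= act[:, :, None]
            str_tun *= act[:, :, None]

        lvl = np.where(t < ei.ceil_D[:, None], before[None, :], after[None, :])
        mh_t = ei.mh[rows, lvl]                              # (B,S)
        p_inc = inc_m[:, t, :][:, None, :] * \
            np.stack([ei.rr_inc[:, di, :][rows, lvl] for di in range(3)], axis=-1)
        exits = p_inc.sum(-1) + p_bg[:, t][:, None]
        over = exits > 1.0
        if np.any(over):
            scale = np.where(over, 1.0 / np.maximum(exits, 1e-300), 1.0)
            p_inc = p_inc * scale[:, :, None]
            p_bg_s = p_bg[:, t][:, None] * scale
            exits = np.minimum(exits, 1.0)
        else:
            p_bg_s = np.broadcast_to(p_bg[:, t][:, None], (B, S))

        # accrual on the occupancy holding during this cycle
        mc = chd_tun.sum(-1)
        ms = str_tun.sum(-1)
        alive = healthy + mc + chd_post + ms + str_post + dia
        ua = u_age[:, t][:, None]
        util = (healthy * np.minimum(ua + mh_t, 1.0)
                + mc * np.minimum(ua * ei.u_first[:, 0][:, None] + mh_t, 1.0)
                + chd_post * np.minimum(ua * ei.u_post[:, 0][:, None] + mh_t, 1.0)
                + ms * np.minimum(ua * ei.u_first[:, 1][:, None] + mh_t, 1.0)
                + str_post * np.minimum(ua * ei.u_post[:, 1][:, None] + mh_t, 1.0)
                + dia * np.minimum(ua * ei.u_dia[:, None] + mh_t, 1.0))
        df = disc[t]
        qaly += util * (df / 12.0) * act
        ly_d += alive * (df / 12.0) * act
        ly_u += alive * (1.0 / 12.0) * act

        ev = healthy[:, :, None] * p_inc                     # (B,S,3) event masses
        state_cost = ((mc + chd_post) * ei.c_annual[:, 0][:, None]
                      + (ms + str_post) * ei.c_annual[:, 1][:, None]
                      + dia * ei.c_annual[:, 2][:, None]) / 12.0
        event_cost = (ev[:, :, 0] * ei.c_first[:, 0][:, None]
                      + ev[:, :, 1] * ei.c_first[:, 1][:, None])
        cost += (state_cost + event_cost) * df * act

        if collect_trace:
            trace_frames.append(np.stack(
                [healthy, mc, chd_post, ms, str_post, dia, dead], axis=-1))

        # transitions
        f_c = fatal[:, t, 0][:, None]
        f_s = fatal[:, t, 1][:, None]
        s_c = (1.0 - dd[:, t, 0])[:, None]
        s_s = (1.0 - dd[:, t, 1])[:, None]
        s_d = (1.0 - dd[:, t, 2])[:, None]
        dead += (ev[:, :, 0] * f_c + ev[:, :, 1] * f_s + healthy * p_bg_s
                 + (mc + chd_post) * (1.0 - s_c) + (ms + str_post) * (1.0 - s_s)
                 + dia * (1.0 - s_d))
        healthy = healthy * (1.0 - exits)
        chd_post = (chd_post + chd_tun[:, :, -1]) * s_c
        str_post = (str_post + str_tun[:, :, -1]) * s_s
        new_chd = np.empty_like(chd_tun)
        new_chd[:, :, 1:] = chd_tun[:, :, :-1] * s_c[:, :, None]
        new_chd[:, :, 0] = ev[:, :, 0] * (1.0 - f_c[:, 0][:, None])
        chd_tun = new_chd
        new_str = np.empty_like(str_tun)
        new_str[:, :, 1:] = str_tun[:, :, :-1] * s_s[:, :, None]
        new_str[:, :, 0] = ev[:, :, 1] * (1.0 - f_s[:, 0][:, None])
        str_tun = new_str
        dia = dia * s_d + ev[:, :, 2]

    # close out: force any remaining occupancy into dead, check conservation
    residual = (healthy + chd_tun.sum(-1) + chd_post + str_tun.sum(-1)
                + str_post + dia)
    dead += residual
    drift = np.abs(dead - 1.0).max()
    if drift > 1e-9 or np.any((dead < -1e-12)):
        raise ModelConsistencyError(f"occupancy mass drifted by {drift:.2e}")

    trace = None
    if collect_trace:
        occ = np.stack(trace_frames, axis=0)  # (T', B, S, 7)
        trace = occ
    return _ComboResults(cost, qaly, ly_d, ly_u, trace)


def _combo_index(stratum) -> int:
    return 3 * LEVELS.index(stratum.activity_before) + LEVELS.index(stratum.activity_after)


def run_cohort(arm: ArmSpec, params: ModelParameters, lt: LifeTable,
               trace: bool = False) -> CohortResult:
    """Run one arm to extinction and return discounted per-person totals.

    Each stratum starts fully healthy at the starting age; stratum totals
    are combined by weight and the arm's upfront programme cost is added
    undiscounted at time zero.
    """
    ei = _EngineInputs([params], lt)
    res = _run_combos(ei, collect_trace=trace)
    w = np.zeros(len(COMBOS))
    for s in arm.strata:
        w[_combo_index(s)] += s.weight
    out = CohortResult(
        discounted_cost=float(res.cost[0] @ w) + arm.upfront_cost_per_person,
        discounted_qaly=float(res.qaly[0] @ w),
        life_years=float(res.ly_undisc[0] @ w),
        discounted_life_years=float(res.ly_disc[0] @ w),
        trace=_build_trace(res.trace, arm, params) if trace else None,
    )
    return out


_TRACE_STATES = ("healthy", "chd_first_year", "chd_post", "stroke_first_year",
                 "stroke_post", "diabetes", "dead")


def _build_trace(occ: np.ndarray, arm: ArmSpec, params: ModelParameters) -> pd.DataFrame:
    """Long-format per-cycle occupancy trace (one row per cycle/stratum/state)."""
    T = occ.shape[0]
    start = int(round(params.settings.starting_age.value))
    frames = []
    for si, s in enumerate(arm.strata):
        combo = _combo_index(s)
        sub = occ[:, 0, combo, :]  # (T, 7)
        df = pd.DataFrame(sub, columns=_TRACE_STATES)
        df.insert(0, "cycle", np.arange(T))
        df.insert(1, "age", start + np.arange(T) // 12)
        df.insert(2, "stratum",
                  f"s{si}:{s.activity_before}->{s.activity_after}")
        df.insert(3, "weight", s.weight)
        frames.append(df.melt(id_vars=["cycle", "age", "stratum", "weight"],
                              var_name="state", value_name="occupancy"))
    return pd.concat(frames, ignore_index=True)


def run_incremental_batch(mps: Sequence[ModelParameters], lt: LifeTable
                          ) -> pd.DataFrame:
    """Evaluate intervention-vs-control increments for a batch of parameter sets.

    The nine activity-pathway combinations are simulated once per draw and
    the two arms are formed by reweighting them, so a probabilistic
    sensitivity analysis costs one engine pass per draw rather than two.
    Returns a DataFrame with delta_cost, delta_qaly, delta_ly columns.
    """
    from .arms import programme_cost_per_recruit  # local to avoid cycle at import

    ei = _EngineInputs(mps, lt)
    res = _run_combos(ei)
    B = len(mps)
    w_ctrl = np.zeros((B, 9))
    w_int = np.zeros((B, 9))
    upfront = np.empty(B)
    for bi, mp in enumerate(mps):
        pr = mp.programme
        c = pr.completion.value
        b = np.array(pr.baseline_activity.fractions)
        f = np.array(pr.followup_activity.fractions)
        for j in range(3):
            w_ctrl[bi, 3 * j + j] = b[j]
            w_int[bi, 3 * j + j] += (1 - c) * b[j]
            for i in range(3):
                w_int[bi, 3 * i + j] += c * f[i] * b[j]
        upfront[bi] = programme_cost_per_recruit(pr)
    dw = w_int - w_ctrl
    return pd.DataFrame({
        "delta_cost": (res.cost * dw).sum(1) + upfront,
        "delta_qaly": (res.qaly * dw).sum(1),
        "delta_ly": (res.ly_disc * dw).sum(1),
        "control_cost": (res.cost * w_ctrl).sum(1),
        "control_qaly": (res.qaly * w_ctrl).sum(1),
        "control_ly": (res.ly_disc * w_ctrl).sum(1),
    })
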