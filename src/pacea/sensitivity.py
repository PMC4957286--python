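"""One-way / threshold sensitivity analysis and probabilistic SA with CEAC.

Distribution parameterization for the probabilistic sensitivity analysis
treats each printed lower/upper pair as a 95 % interval, so the implied
standard deviation is ``(upper - lower) / 3.92``.  Beta and gamma
distributions are fitted by method of moments around the base value;
log-normals take the base as the median with log-scale SD
``(ln upper - ln lower) / 3.92``; activity compositions are drawn jointly
from a Dirichlet centred on the base fractions; the duration of effect is
uniform on its range; the starting age is normal, rounded to whole years
and clamped to its limits.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import params as P
from .arms import build_arms
from .cea import CEAResult, from_deltas, incremental
from .lifetable import LifeTable
from .markov import run_cohort, run_incremental_batch
from .params import ModelParameters

__all__ = [
    "PSASample",
    "CEACCurve",
    "evaluate_cea",
    "one_way_sweep",
    "threshold_search",
    "sample_parameter_set",
    "run_psa",
    "ceac",
    "DIRICHLET_CONCENTRATION",
]

log = logging.getLogger(__name__)

#: concentration of the Dirichlet draws for activity compositions
DIRICHLET_CONCENTRATION = 100.0


@dataclass(frozen=True)
class PSASample:
    """One probabilistic draw: the sampled scalars and its incremental outputs."""

    draw: int
    values: dict
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]

    def nmb(self, wtp: float) -> float:
        return wtp * self.delta_qaly - self.delta_cost


@dataclass(frozen=True)
class CEACCurve:
    wtp: np.ndarray
    probability: np.ndarray


def evaluate_cea(mp: ModelParameters, lt: LifeTable) -> CEAResult:
    """Base-case style paired run of both arms under one parameter set."""
    intervention, control = build_arms(mp.programme)
    return incremental(run_cohort(intervention, mp, lt),
                       run_cohort(control, mp, lt))


# --------------------------------------------------------------------------
# one-way sensitivity

def one_way_sweep(param_id: str, grid: Sequence[float], base: ModelParameters,
                  lt: LifeTable) -> list[tuple[float, CEAResult]]:
    """Evaluate the incremental result at each grid value of one parameter."""
    param = P.get_param(base, param_id)
    out = []
    for v in grid:
        if param.lower is not None and param.upper is not None and \
                not (param.lower - 1e-12 <= v <= param.upper + 1e-12):
            raise ValueError(f"grid value {v} outside [{param.lower}, {param.upper}]")
        out.append((v, evaluate_cea(P.set_value(base, param_id, v), lt)))
    return out


def _nmb_at(param_id: str, value: float, wtp: float, base: ModelParameters,
            lt: LifeTable) -> float:
    return evaluate_cea(P.set_value(base, param_id, value), lt).nmb(wtp)


def threshold_search(param_id: str, wtp: float, base: ModelParameters,
                     lt: LifeTable, tol: float = 1e-3,
                     max_iter: int = 60) -> Optional[float]:
    """Find the parameter value at which the ICER equals ``wtp``.

    Bisection on the net monetary benefit at ``wtp`` (zero NMB is exactly
    an ICER of ``wtp`` whenever QALYs are gained).  The endpoints must
    bracket a sign change; if the NMB has the same sign at both endpoints
    of the sensitivity range, there is no threshold in range and ``None``
    is returned.  A non-monotone profile (endpoint NMBs bracketing but the
    base value outside the bracket direction) raises, advising a grid
    inspection via :func:`one_way_sweep`.
    """
    param = P.get_param(base, param_id)
    if not param.has_range:
        raise ValueError(f"{param_id} has no sensitivity range")
    lo, hi = param.lower, param.upper
    f_lo = _nmb_at(param_id, lo, wtp, base, lt)
    f_hi = _nmb_at(param_id, hi, wtp, base, lt)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        return None
    lo_sign = f_lo > 0
    for _ in range(max_iter):
        if hi - lo < tol:
            break
        mid = 0.5 * (lo + hi)
        f_mid = _nmb_at(param_id, mid, wtp, base, lt)
        if f_mid == 0.0:
            return mid
        if (f_mid > 0) == lo_sign:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


#: parameters the model consumes at whole-number resolution (months / years)
INTEGER_PARAMS = ("programme.duration_of_effect_months", "settings.starting_age")


def integer_threshold_search(param_id: str, wtp: float, base: ModelParameters,
                             lt: LifeTable) -> Optional[int]:
    """Threshold search over whole-number parameter values.

    For parameters the model consumes at integer resolution (duration of
    effect in months, starting age in years) the ICER is a step function,
    so the threshold is the first integer on the cost-effective side of
    the sign change.  Returns ``None`` when no crossing lies in range.
    """
    param = P.get_param(base, param_id)
    grid = range(math.ceil(param.lower), math.floor(param.upper) + 1)
    values = [(v, _nmb_at(param_id, float(v), wtp, base, lt)) for v in grid]
    signs = [f > 0 for _, f in values]
    if all(signs) or not any(signs):
        return None
    for (v0, f0), (v1, f1) in zip(values, values[1:]):
        if (f0 > 0) != (f1 > 0):
            return v1 if f1 > 0 else v0
    return None


def one_way_table(base: ModelParameters, lt: LifeTable, wtp: float,
                  param_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """One-way sensitivity summary: endpoint ICERs and threshold per parameter.

    Thresholds use the integer search for integer-resolution parameters
    and bisection otherwise; parameters whose range never crosses ``wtp``
    report no threshold.
    """
    if param_ids is None:
        param_ids = [path for path, p in P.iter_scalar_params(base)
                     if p.lower is not None and p.upper is not None]
    rows = []
    for pid in param_ids:
        param = P.get_param(base, pid)
        cea_lo = evaluate_cea(P.set_value(base, pid, param.lower), lt)
        cea_hi = evaluate_cea(P.set_value(base, pid, param.upper), lt)
        if pid in INTEGER_PARAMS:
            th = integer_threshold_search(pid, wtp, base, lt)
        else:
            th = threshold_search(pid, wtp, base, lt)
        rows.append({
            "parameter": pid,
            "base_value": param.value,
            "lower": param.lower,
            "upper": param.upper,
            "icer_at_lower": cea_lo.icer if cea_lo.icer is not None else np.nan,
            "icer_at_upper": cea_hi.icer if cea_hi.icer is not None else np.nan,
            "threshold": th if th is not None else np.nan,
            "note": "" if th is not None else "no threshold in range",
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis

def _beta_mean_sd(mean: float, sd: float, rng: np.random.Generator,
                  lo: float, hi: float, name: str) -> float:
    var = sd * sd
    limit = mean * (1.0 - mean)
    if mean <= 0.0 or mean >= 1.0 or var >= limit:
        log.warning("beta moments infeasible for %s; falling back to uniform", name)
        return float(rng.uniform(lo, hi))
    k = limit / var - 1.0
    return float(rng.beta(mean * k, (1.0 - mean) * k))


def _gamma_mean_sd(mean: float, sd: float, rng: np.random.Generator,
                   lo: float, hi: float, name: str) -> float:
    if mean <= 0.0 or sd <= 0.0:
        log.warning("gamma moments infeasible for %s; falling back to uniform", name)
        return float(rng.uniform(lo, hi))
    shape = (mean / sd) ** 2
    return float(rng.gamma(shape, sd * sd / mean))


def _draw_scalar(param: P.Param, rng: np.random.Generator, name: str) -> float:
    lo, hi = param.lower, param.upper
    sd = (hi - lo) / 3.92
    if param.dist == "beta":
        return _beta_mean_sd(param.value, sd, rng, lo, hi, name)
    if param.dist == "gamma":
        return _gamma_mean_sd(param.value, sd, rng, lo, hi, name)
    if param.dist == "lognormal":
        log_sd = (math.log(hi) - math.log(lo)) / 3.92
        return float(np.exp(rng.normal(math.log(param.value), log_sd)))
    if param.dist == "uniform":
        return float(rng.uniform(lo, hi))
    if param.dist == "normal":
        return float(rng.normal(param.value, sd))
    raise ValueError(f"no sampler for distribution {param.dist!r} ({name})")


def _draw_activity(dist: P.ActivityDistribution, rng: np.random.Generator
                   ) -> tuple[float, float, float]:
    alpha = np.array(dist.fractions) * DIRICHLET_CONCENTRATION
    draw = rng.dirichlet(alpha)
    return float(draw[0]), float(draw[1]), float(draw[2])


def sample_parameter_set(base: ModelParameters, rng: np.random.Generator
                         ) -> ModelParameters:
    """Draw one full parameter set from the assigned PSA distributions.

    Activity compositions are drawn jointly (Dirichlet); the starting age
    is rounded to whole years and clamped to its printed limits; every
    other ranged scalar is drawn from its own family.  Draws that would
    leave a distribution's support fall back to uniform over the range
    with a logged warning.
    """
    mp = base
    for path, param in P.iter_scalar_params(base):
        if not param.has_range or param.dist == "dirichlet":
            continue
        value = _draw_scalar(param, rng, path)
        if path == "settings.starting_age":
            value = float(np.clip(round(value), param.lower, param.upper))
        mp = P.set_value(mp, path, value)
    pr = mp.programme
    baseline = pr.baseline_activity.with_fractions(
        *_draw_activity(base.programme.baseline_activity, rng))
    followup = pr.followup_activity.with_fractions(
        *_draw_activity(base.programme.followup_activity, rng))
    import dataclasses
    return dataclasses.replace(
        mp, programme=dataclasses.replace(pr, baseline_activity=baseline,
                                          followup_activity=followup))


def run_psa(n_draws: int, seed: int, base: ModelParameters, lt: LifeTable,
            chunk_size: int = 250, keep_values: bool = False
            ) -> list[PSASample]:
    """Probabilistic sensitivity analysis: ``n_draws`` paired model runs.

    One master seed spawns an independent substream per draw, so results
    do not depend on evaluation order or chunking.  Set ``keep_values`` to
    retain each draw's sampled scalars (for support checks / diagnostics).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_draws)
    samples: list[PSASample] = []
    for lo in range(0, n_draws, chunk_size):
        hi = min(lo + chunk_size, n_draws)
        mps = [sample_parameter_set(base, np.random.default_rng(streams[i]))
               for i in range(lo, hi)]
        inc = run_incremental_batch(mps, lt)
        for k, mp in enumerate(mps):
            dq = float(inc["delta_qaly"].iloc[k])
            dc = float(inc["delta_cost"].iloc[k])
            values = (dict(
                (path, param.value) for path, param in P.iter_scalar_params(mp))
                if keep_values else {})
            samples.append(PSASample(
                draw=lo + k, values=values, delta_cost=dc, delta_qaly=dq,
                icer=(dc / dq) if dq != 0.0 else None))
    return samples


def psa_table(samples: Sequence[PSASample]) -> pd.DataFrame:
    return pd.DataFrame({
        "draw": [s.draw for s in samples],
        "delta_cost": [s.delta_cost for s in samples],
        "delta_qaly": [s.delta_qaly for s in samples],
        "icer": [s.icer if s.icer is not None else np.nan for s in samples],
    })


def ceac(samples: Sequence[PSASample], wtp_grid: Sequence[float]) -> CEACCurve:
    """Probability of positive net monetary benefit over a willingness grid.

    A draw counts as cost-effective at ``wtp`` iff its net monetary benefit
    ``wtp * delta_qaly - delta_cost`` is positive — the coherent reading in
    all four cost/QALY quadrants (a draw losing QALYs only counts where its
    savings outweigh the loss).
    """
    if len(samples) == 0:
        raise ValueError("no PSA samples supplied")
    dq = np.array([s.delta_qaly for s in samples])
    dc = np.array([s.delta_cost for s in samples])
    grid = np.asarray(list(wtp_grid), dtype=float)
    prob = np.array([(lam * dq - dc > 0).mean() for lam in grid])
    return CEACCurve(wtp=grid, probability=prob)


def probability_cost_effective(samples: Sequence[PSASample], wtp: float) -> float:
    return float(ceac(samples, [wtp]).probability[0])
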