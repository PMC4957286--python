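"""Cause-split background mortality by age.

The model needs, for every integer age, the monthly all-cause death
probability and the share of those deaths attributable to cardiovascular
causes (so that post-event relative risks can be applied per cause).
National statistics offices publish such tables; here a Gompertz-hazard
generator provides a self-contained synthetic stand-in, and a reader
accepts any real table supplied as delimited text.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LifeTable",
    "generate_life_table",
    "default_life_table",
    "read_life_table",
    "write_life_table",
    "background_death_probs",
    "LifeTableError",
]


class LifeTableError(ValueError):
    pass


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed monthly all-cause death probability and CVD death share."""

    ages: np.ndarray        # contiguous integer ages
    q_month: np.ndarray     # monthly all-cause death probability
    cvd_share: np.ndarray   # fraction of deaths from cardiovascular causes

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        if ages.ndim != 1 or len(ages) == 0:
            raise LifeTableError("life table must have at least one row")
        if np.any(np.diff(ages) != 1):
            raise LifeTableError("ages must be contiguous integers")
        if np.any((self.q_month < 0) | (self.q_month > 1)):
            raise LifeTableError("q_month outside [0, 1]")
        if np.any((self.cvd_share < 0) | (self.cvd_share > 1)):
            raise LifeTableError("cvd_share outside [0, 1]")

    def _idx(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=int)
        return np.clip(age - int(self.ages[0]), 0, len(self.ages) - 1)

    def q_at(self, age):
        """Monthly all-cause death probability, clamped outside the table."""
        return self.q_month[self._idx(age)]

    def cvd_at(self, age):
        return self.cvd_share[self._idx(age)]


def generate_life_table(
    gompertz_alpha: float = -10.3,
    gompertz_beta: float = 0.094,
    cvd_share_params: tuple[float, float, float, float] = (0.05, 0.003, 0.05, 0.35),
    min_age: int = 25,
    max_age: int = 110,
) -> LifeTable:
    """Synthetic life table from a Gompertz hazard and a clamped linear CVD share.

    The annual all-cause hazard is ``mu(a) = exp(alpha + beta * a)``; the
    monthly death probability is ``1 - exp(-mu(a)/12)``.  The share of
    deaths attributed to cardiovascular causes rises linearly with age
    between a floor and a ceiling:
    ``clamp(intercept + slope * (a - 30), floor, ceiling)``.

    The defaults approximate contemporary UK all-cause mortality levels at
    mid and old age; they stand in for unpublished national tables and are
    fully replaceable via :func:`read_life_table`.
    """
    if gompertz_beta <= 0:
        raise LifeTableError("gompertz_beta must be positive")
    intercept, slope, floor, ceiling = cvd_share_params
    if not (0.0 <= floor <= ceiling <= 1.0):
        raise LifeTableError("cvd share floor/ceiling must satisfy 0 <= floor <= ceiling <= 1")
    ages = np.arange(min_age, max_age + 1)
    mu = np.exp(gompertz_alpha + gompertz_beta * ages)
    q_month = -np.expm1(-mu / 12.0)
    share = np.clip(intercept + slope * (ages - 30), floor, ceiling)
    return LifeTable(ages=ages, q_month=q_month, cvd_share=share)


def default_life_table() -> LifeTable:
    """The bundled synthetic table used by the base-case analysis."""
    return generate_life_table()


def read_life_table(table_text: str) -> LifeTable:
    """Parse a 3-column delimited table ``age,q_month,cvd_share`` (header required)."""
    lines = [ln.strip() for ln in io.StringIO(table_text) if ln.strip()]
    if len(lines) < 2:
        raise LifeTableError("life-table text needs a header and at least one row")
    header = [h.strip().lower() for h in lines[0].split(",")]
    if header != ["age", "q_month", "cvd_share"]:
        raise LifeTableError("expected header 'age,q_month,cvd_share'")
    ages, qs, shares = [], [], []
    for rowno, line in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in line.split(",")]
        if len(fields) != 3:
            raise LifeTableError(f"row {rowno}: expected 3 fields")
        try:
            age, q, share = int(fields[0]), float(fields[1]), float(fields[2])
        except ValueError:
            raise LifeTableError(f"row {rowno}: unparsable value") from None
        if not (0.0 <= q <= 1.0):
            raise LifeTableError(f"row {rowno}: q_month {q} outside [0, 1]")
        if not (0.0 <= share <= 1.0):
            raise LifeTableError(f"row {rowno}: cvd_share {share} outside [0, 1]")
        if ages and age != ages[-1] + 1:
            raise LifeTableError(f"row {rowno}: gap in ages ({ages[-1]} -> {age})")
        ages.append(age)
        qs.append(q)
        shares.append(share)
    return LifeTable(ages=np.array(ages), q_month=np.array(qs), cvd_share=np.array(shares))


def write_life_table(lt: LifeTable) -> str:
    rows = ["age,q_month,cvd_share"]
    for a, q, s in zip(lt.ages, lt.q_month, lt.cvd_share):
        rows.append(f"{int(a)},{float(q)!r},{float(s)!r}")
    return "\n".join(rows) + "\n"


def background_death_probs(lt: LifeTable, age, rr_cvd: float = 1.0,
                           rr_noncvd: float = 1.0):
    """Monthly (CVD, non-CVD) death probabilities at ``age`` under cause RRs.

    The all-cause monthly probability is decomposed into cause-specific
    hazards (``h_cvd = -ln(1-q) * cvd_share`` and its complement); relative
    risks scale the hazards, keeping each returned probability valid for
    arbitrarily large multipliers.  At ``rr = 1`` the two probabilities
    combine as competing risks to reproduce ``q_month`` exactly in hazard
    space: ``(1-p_cvd)(1-p_noncvd) = 1-q``.
    """
    if rr_cvd < 0 or rr_noncvd < 0:
        raise LifeTableError("relative risks must be >= 0")
    q = lt.q_at(age)
    share = lt.cvd_at(age)
    h = -np.log1p(-np.minimum(q, 1 - 1e-15))
    p_cvd = -np.expm1(-h * share * rr_cvd)
    p_noncvd = -np.expm1(-h * (1.0 - share) * rr_noncvd)
    # cap the total so the pair remains a valid sub-probability split
    total = p_cvd + p_noncvd
    over = total > 1.0
    if np.any(over):
        scale = np.where(over, 1.0 / np.where(total > 0, total, 1.0), 1.0)
        p_cvd = p_cvd * scale
        p_noncvd = p_noncvd * scale
    return p_cvd, p_noncvd
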