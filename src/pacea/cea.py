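"""Incremental cost-effectiveness outputs from paired arm results."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .markov import CohortResult

__all__ = ["CEAResult", "incremental", "qaly_to_days_full_health", "results_table"]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class CEAResult:
    """Increments (intervention minus control) and the derived ratio.

    ``icer`` is ``delta_cost / delta_qaly`` from unrounded deltas; it is
    ``None`` when no QALYs are gained or lost.  ``label`` flags dominance:
    'dominant' (cheaper and more effective), 'dominated' (dearer and less
    effective), or 'tradeoff'.
    """

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: Optional[float]
    label: str

    def nmb(self, wtp: float) -> float:
        """Net monetary benefit at willingness to pay ``wtp`` per QALY."""
        return wtp * self.delta_qaly - self.delta_cost


def incremental(intervention: CohortResult, control: CohortResult) -> CEAResult:
    """Incremental cost, QALYs, life-years and ICER between two arm runs."""
    dc = intervention.discounted_cost - control.discounted_cost
    dq = intervention.discounted_qaly - control.discounted_qaly
    dl = intervention.discounted_life_years - control.discounted_life_years
    return from_deltas(dc, dq, dl)


def from_deltas(delta_cost: float, delta_qaly: float, delta_ly: float = math.nan
                ) -> CEAResult:
    if delta_qaly == 0.0:
        icer = None
        label = "undefined" if delta_cost != 0.0 else "indifferent"
    else:
        icer = delta_cost / delta_qaly
        if delta_qaly > 0 and delta_cost <= 0:
            label = "dominant"
        elif delta_qaly < 0 and delta_cost >= 0:
            label = "dominated"
        else:
            label = "tradeoff"
    return CEAResult(delta_cost=delta_cost, delta_qaly=delta_qaly,
                     delta_ly=delta_ly, icer=icer, label=label)


def qaly_to_days_full_health(dq: float) -> float:
    """Express a QALY increment as equivalent days in full health."""
    return dq * DAYS_PER_YEAR


def results_table(intervention: CohortResult, control: CohortResult) -> pd.DataFrame:
    """Base-case summary mirroring the usual cost/life-year/QALY layout."""
    cea = incremental(intervention, control)
    return pd.DataFrame(
        {
            "total_cost": [control.discounted_cost, intervention.discounted_cost,
                           cea.delta_cost],
            "total_life_years": [control.discounted_life_years,
                                 intervention.discounted_life_years, cea.delta_ly],
            "total_qalys": [control.discounted_qaly, intervention.discounted_qaly,
                            cea.delta_qaly],
            "icer": [float("nan"), float("nan"),
                     cea.icer if cea.icer is not None else float("nan")],
        },
        index=["control", "intervention", "increment"],
    )
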