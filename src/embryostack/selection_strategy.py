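"""Twin-rate-constrained embryo selection.

Given a patient's available embryos and a trained hierarchy, every candidate
transfer plan — each single embryo and each unordered pair — is scored for
predicted pregnancy probability and predicted twin risk.  The recommendation
maximizes predicted pregnancy among plans whose twin risk does not exceed the
clinic's acceptable twin-rate threshold τ; single-embryo plans carry twin risk
0 by definition (monozygotic twinning is out of scope), so a feasible plan
always exists.  If a transfer fails, the procedure is re-run on the remaining
embryos until none are left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .cohort_io import EmbryoRecord, PatientRecord
from .hierarchical_model import HierarchicalModel, predict_det, predict_single

__all__ = [
    "SelectionPlan",
    "enumerate_plans",
    "recommend",
    "sequential_plan",
    "feasibility_frontier",
    "strategy_report",
]


@dataclass(frozen=True)
class SelectionPlan:
    """A candidate transfer: one embryo or an unordered pair, with predictions."""

    embryo_ids: tuple[str, ...]
    pregnancy: float
    twin: float

    def feasible(self, tau: float) -> bool:
        return self.twin <= tau

    @property
    def n_embryos(self) -> int:
        return len(self.embryo_ids)


def enumerate_plans(
    model: HierarchicalModel, patient: PatientRecord, embryos: Sequence[EmbryoRecord]
) -> list[SelectionPlan]:
    """All k single-embryo plans plus all k(k-1)/2 pair plans, scored.

    Pair plans use unordered embryo-id pairs (sorted), and their scores are
    invariant to the order the embryos are supplied in.
    """
    if len(embryos) == 0:
        raise ValueError("no embryos to plan with")
    plans: list[SelectionPlan] = []
    for embryo in embryos:
        p = predict_single(model, patient, embryo, model.schema)
        plans.append(SelectionPlan(embryo_ids=(embryo.embryo_id,), pregnancy=p, twin=0.0))
    for ea, eb in combinations(embryos, 2):
        preg, twin = predict_det(model, patient, ea, eb)
        ids = tuple(sorted((ea.embryo_id, eb.embryo_id)))
        plans.append(SelectionPlan(embryo_ids=ids, pregnancy=preg, twin=twin))
    return plans


def _plan_order_key(plan: SelectionPlan):
    # maximize pregnancy; ties → lower twin risk, then fewer embryos, then ids
    return (-plan.pregnancy, plan.twin, plan.n_embryos, plan.embryo_ids)


def recommend(
    model: HierarchicalModel,
    patient: PatientRecord,
    embryos: Sequence[EmbryoRecord],
    tau: float,
) -> SelectionPlan:
    """Feasible plan (twin ≤ τ) with maximal predicted pregnancy.

    Ties are broken by lower twin risk, then fewer embryos, then lexicographic
    embryo ids.  Because single-embryo plans have twin risk 0, a feasible plan
    always exists for any τ ≥ 0.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0,1]")
    feasible = [p for p in enumerate_plans(model, patient, embryos) if p.feasible(tau)]
    return min(feasible, key=_plan_order_key)


def sequential_plan(
    model: HierarchicalModel,
    patient: PatientRecord,
    embryos: Sequence[EmbryoRecord],
    tau: float,
) -> list[SelectionPlan]:
    """Re-planning sequence: recommend, remove the transferred embryos, repeat.

    Models the protocol where a failed fresh transfer triggers a new plan with
    the remaining embryos until all have been transferred.  The returned plans
    partition the embryo set.
    """
    remaining = list(embryos)
    sequence: list[SelectionPlan] = []
    while remaining:
        plan = recommend(model, patient, remaining, tau)
        sequence.append(plan)
        remaining = [e for e in remaining if e.embryo_id not in plan.embryo_ids]
    return sequence


def feasibility_frontier(plans: Sequence[SelectionPlan]) -> list[tuple[float, float]]:
    """Best achievable predicted pregnancy as a step function of τ.

    Returns (τ, pregnancy) breakpoints at the sorted distinct twin-risk values
    of the plans; the frontier is non-decreasing in τ since the feasible set
    only grows.
    """
    thresholds = sorted({p.twin for p in plans})
    frontier = []
    for tau in thresholds:
        best = max(p.pregnancy for p in plans if p.twin <= tau)
        frontier.append((tau, best))
    return frontier


def strategy_report(
    model: HierarchicalModel,
    patient: PatientRecord,
    embryos: Sequence[EmbryoRecord],
    tau: float,
) -> dict:
    """Structured report: all scored plans, the recommendation at τ, and the
    feasibility frontier, as a JSON-serializable mapping."""
    plans = enumerate_plans(model, patient, embryos)
    feasible = [p for p in plans if p.feasible(tau)]
    chosen = min(feasible, key=_plan_order_key)
    return {
        "tau": tau,
        "plans": [
            {
                "embryo_ids": list(p.embryo_ids),
                "pregnancy": p.pregnancy,
                "twin": p.twin,
                "feasible": p.feasible(tau),
            }
            for p in sorted(plans, key=_plan_order_key)
        ],
        "recommendation": {
            "embryo_ids": list(chosen.embryo_ids),
            "pregnancy": chosen.pregnancy,
            "twin": chosen.twin,
        },
        "frontier": [{"tau": t, "pregnancy": p} for t, p in feasibility_frontier(plans)],
    }


def report_to_text(report: dict) -> str:
    """Stable text serialization of a strategy report."""
    return json.dumps(report, indent=2, sort_keys=True)
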