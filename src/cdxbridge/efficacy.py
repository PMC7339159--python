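"""Objective response rate (ORR) estimation and the primary-objective rule.

ORR is the proportion of *all treated* patients whose best response is
complete (CR) or partial (PR); stable disease, progression and
non-evaluable outcomes all count in the denominator but not the numerator.
The trial's primary objective is met when the lower bound of the two-sided
95% CI for ORR in CDx-positive patients strictly exceeds a margin
(25% here, anchored to historical response rates in the indication).

Outcome tables are pandas DataFrames with one row per patient:

    patient_id, treated, response, alteration, chemo_refractory,
    cta_call, cdx_call
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from .concordance import ProportionEstimate, proportion_estimate
from .panel import FUSIONS, PANEL_TARGETS, POINT_MUTATIONS

__all__ = [
    "RESPONSE_CATEGORIES",
    "RESPONDER_CATEGORIES",
    "ORREstimate",
    "orr",
    "orr_by_alteration",
    "primary_objective",
]

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")
RESPONDER_CATEGORIES = frozenset({"CR", "PR"})

Predicate = Callable[[pd.DataFrame], pd.Series]


@dataclass(frozen=True)
class ORREstimate:
    """Responder count, denominator and CI for one (sub)group.

    ``estimate`` is None for an empty subgroup, rendered as an em-dash in
    reports rather than 0.0.
    """

    subgroup: str
    responders: int
    n: int
    estimate: ProportionEstimate | None

    def __post_init__(self) -> None:
        if self.responders > self.n:
            raise ValueError("responders cannot exceed n")


def _estimate(subgroup: str, responders: int, n: int, ci_method: str) -> ORREstimate:
    est = proportion_estimate(responders, n, ci_method) if n > 0 else None
    return ORREstimate(subgroup, responders, n, est)


def orr(
    outcomes: pd.DataFrame,
    subset: Predicate | pd.Series | None = None,
    ci_method: str = "wilson",
    subgroup: str = "Overall",
) -> ORREstimate:
    """ORR among treated patients, optionally restricted to a subset.

    ``subset`` may be a boolean mask aligned with ``outcomes`` or a callable
    producing one; it is applied after restricting to treated patients.
    Raises if the subset is empty, naming the subgroup.
    """
    treated = outcomes[outcomes["treated"].astype(bool)]
    if subset is not None:
        mask = subset(treated) if callable(subset) else subset.loc[treated.index]
        treated = treated[mask.astype(bool)]
    if len(treated) == 0:
        raise ValueError(f"no treated patients in subset {subgroup!r}")
    responders = int(treated["response"].isin(RESPONDER_CATEGORIES).sum())
    return _estimate(subgroup, responders, len(treated), ci_method)


def orr_by_alteration(
    outcomes: pd.DataFrame,
    ci_method: str = "wilson",
    targets: Sequence[str] = PANEL_TARGETS,
) -> list[ORREstimate]:
    """Per-alteration ORR plus point-mutation/fusion aggregates and overall.

    Operates on the treated patients of ``outcomes`` (callers restrict to
    the double-positive population first when reproducing a bridging
    table).  Subgroup rows are disjoint — each patient carries one primary
    alteration — so per-target counts sum to the class aggregates and the
    aggregates to the overall row.  Targets never observed are still
    reported, with n = 0 and no estimate.
    """
    treated = outcomes[outcomes["treated"].astype(bool)]
    rows: list[ORREstimate] = []
    is_resp = treated["response"].isin(RESPONDER_CATEGORIES)

    def count(mask: pd.Series) -> tuple[int, int]:
        return int((is_resp & mask).sum()), int(mask.sum())

    all_mask = treated["alteration"].isin(targets)
    rows.append(_estimate("Overall", *count(all_mask), ci_method))
    for label, members in (("Point mutations", POINT_MUTATIONS), ("Fusions", FUSIONS)):
        class_targets = [t for t in members if t in targets]
        rows.append(_estimate(label, *count(treated["alteration"].isin(class_targets)), ci_method))
        for t in class_targets:
            rows.append(_estimate(t, *count(treated["alteration"] == t), ci_method))
    return rows


@dataclass(frozen=True)
class ObjectiveDecision:
    met: bool
    ci_low: float
    margin: float


def primary_objective(est: ORREstimate, margin: float = 25.0) -> ObjectiveDecision:
    """Primary-objective rule: met iff the ORR CI lower bound strictly
    exceeds the margin."""
    if est.estimate is None:
        raise ValueError(f"subgroup {est.subgroup!r} has no estimate (n = 0)")
    return ObjectiveDecision(
        met=est.estimate.ci_low > margin, ci_low=est.estimate.ci_low, margin=margin
    )
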