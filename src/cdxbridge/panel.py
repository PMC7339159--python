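"""Qualitative RT-PCR call engine for a nine-target FGFR2/3 alteration panel.

A multiplex real-time RT-PCR companion diagnostic reports, per sample, a
qualitative FGFR alteration status derived from per-target cycle-threshold
(Ct) values: a target is *positive* when its Ct is less than or equal to the
assay-specific cut-off (boundary inclusive), and a sample is FGFR-positive
when at least one target is positive. Before any target call is made the
sample must clear two quality gates, in order:

1. *insufficient* — the extracted RNA concentration is below the minimum
   input requirement (18 ng/uL by default);
2. *invalid* — the PCR run failed its template controls, or the sample's
   internal amplification control fell outside its acceptance Ct window.

The three accounting categories (valid result / insufficient / invalid) are
disjoint, with the pre-analytical gate assessed first.

Actual commercial Ct cut-offs are proprietary; every threshold here
(per-target cut-off 33.0 cycles, internal-control window [20, 35], NTC
contamination floor 35) is a synthetic configuration default used by the
simulator and tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "UNDETERMINED",
    "POINT_MUTATIONS",
    "FUSIONS",
    "PANEL_TARGETS",
    "DEFAULT_CT_CUTOFF",
    "DEFAULT_IC_RANGE",
    "DEFAULT_MIN_RNA_CONC",
    "DEFAULT_NTC_FLOOR",
    "TargetAssay",
    "CtProfile",
    "ControlAcceptance",
    "RunControls",
    "SampleCall",
    "ValidityTally",
    "default_panel",
    "check_rna_sufficiency",
    "validate_run",
    "call_target",
    "call_sample",
    "tally_validity",
]

#: Sentinel used in input/output files for a reaction with no amplification.
UNDETERMINED = "undetermined"

POINT_MUTATIONS: tuple[str, ...] = ("R248C", "S249C", "G370C", "Y373C")
FUSIONS: tuple[str, ...] = ("TACC3_V1", "TACC3_V3", "BAIAP2L1", "CASP7", "BICC1")
PANEL_TARGETS: tuple[str, ...] = POINT_MUTATIONS + FUSIONS

# Synthetic defaults -- real kit constants are proprietary.
DEFAULT_CT_CUTOFF = 33.0
DEFAULT_IC_RANGE = (20.0, 35.0)
DEFAULT_MIN_RNA_CONC = 18.0
DEFAULT_NTC_FLOOR = 35.0

VALID_STATUSES = ("fgfr_positive", "fgfr_negative", "invalid", "insufficient")


@dataclass(frozen=True)
class TargetAssay:
    """One target of the panel: name, class, Ct cut-off and PCR mix.

    ``reaction_mix`` identifies which of the four multiplex PCR mixes
    carries the target (1-2 mutations, 3-4 fusions by convention).
    """

    name: str
    alteration_class: str  # "point_mutation" | "fusion"
    ct_cutoff: float = DEFAULT_CT_CUTOFF
    reaction_mix: int = 1

    def __post_init__(self) -> None:
        if self.alteration_class not in ("point_mutation", "fusion"):
            raise ValueError(f"unknown alteration class {self.alteration_class!r}")
        if not self.ct_cutoff > 0:
            raise ValueError("ct_cutoff must be positive")
        if self.reaction_mix not in (1, 2, 3, 4):
            raise ValueError("reaction_mix must be 1..4")


def default_panel(ct_cutoff: float = DEFAULT_CT_CUTOFF) -> list[TargetAssay]:
    """The full nine-target panel (4 point mutations + 5 fusions).

    All targets share one synthetic Ct cut-off; a real assay would carry a
    validated per-target constant.
    """
    mix_of = {
        "R248C": 1, "S249C": 1, "G370C": 2, "Y373C": 2,
        "TACC3_V1": 3, "TACC3_V3": 3, "BAIAP2L1": 4, "CASP7": 4, "BICC1": 4,
    }
    return [
        TargetAssay(t, "point_mutation", ct_cutoff, mix_of[t]) for t in POINT_MUTATIONS
    ] + [TargetAssay(t, "fusion", ct_cutoff, mix_of[t]) for t in FUSIONS]


@dataclass
class CtProfile:
    """Per-sample Ct measurements: one entry per panel target plus the
    internal amplification control.  ``None`` encodes "undetermined"
    (no amplification within the run)."""

    sample_id: str
    run_id: str
    target_ct: dict[str, float | None]
    internal_control_ct: float | None
    rna_conc: float | None = None  # ng/uL, optional


@dataclass(frozen=True)
class ControlAcceptance:
    """Acceptance window for one target's run controls.

    The positive template control (PTC) must amplify inside
    ``ptc_range``; the no-template control (NTC) must either not amplify
    at all or amplify only above ``ntc_floor`` (late, negligible signal --
    anything earlier indicates contamination).
    """

    ptc_range: tuple[float, float] = (20.0, 30.0)
    ntc_floor: float = DEFAULT_NTC_FLOOR

    def __post_init__(self) -> None:
        lo, hi = self.ptc_range
        if not lo < hi:
            raise ValueError("ptc_range must be a non-empty interval")


@dataclass
class RunControls:
    """Template-control Ct values for one PCR run, per target."""

    run_id: str
    ptc_ct: dict[str, float]
    ntc_ct: dict[str, float | None]
    acceptance: dict[str, ControlAcceptance] = field(default_factory=dict)

    def acceptance_for(self, target: str) -> ControlAcceptance:
        return self.acceptance.get(target, ControlAcceptance())


@dataclass(frozen=True)
class SampleCall:
    """Qualitative FGFR status for one sample.

    ``positive_targets`` is non-empty iff status is ``fgfr_positive``;
    invalid/insufficient samples carry no target results.
    """

    sample_id: str
    status: str
    positive_targets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.status == "fgfr_positive") != bool(self.positive_targets):
            raise ValueError("positive_targets must be non-empty iff fgfr_positive")


def check_rna_sufficiency(rna_conc: float, min_conc: float = DEFAULT_MIN_RNA_CONC) -> str:
    """Pre-analytical gate: ``"sufficient"`` iff the RNA concentration meets
    the minimum input requirement (boundary inclusive)."""
    if rna_conc < 0:
        raise ValueError(f"negative RNA concentration: {rna_conc}")
    if not min_conc > 0:
        raise ValueError("min_conc must be positive")
    return "sufficient" if rna_conc >= min_conc else "insufficient"


def validate_run(
    controls: RunControls, targets: Sequence[str] = PANEL_TARGETS
) -> tuple[str, list[str]]:
    """Assess a run's template controls against their acceptance criteria.

    Returns ``("valid", [])`` when every PTC Ct lies inside its window and
    every NTC is undetermined or above its contamination floor; otherwise
    ``("invalid", reasons)`` with one reason per failing control.
    """
    reasons: list[str] = []
    for target in targets:
        if target not in controls.ptc_ct or target not in controls.ntc_ct:
            raise ValueError(f"run {controls.run_id}: no control for target {target!r}")
        acc = controls.acceptance_for(target)
        ptc = controls.ptc_ct[target]
        lo, hi = acc.ptc_range
        if not (lo <= ptc <= hi):
            reasons.append(f"PTC {target}: Ct {ptc:g} outside [{lo:g}, {hi:g}]")
        ntc = controls.ntc_ct[target]
        if ntc is not None and ntc < acc.ntc_floor:
            reasons.append(f"NTC {target}: Ct {ntc:g} below floor {acc.ntc_floor:g} (contamination)")
    return ("valid" if not reasons else "invalid", reasons)


def call_target(ct: float | None, cutoff: float) -> str:
    """One target call: positive iff Ct amplified at or below the cut-off."""
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    return "positive" if ct is not None and ct <= cutoff else "negative"


def call_sample(
    profile: CtProfile,
    panel: Sequence[TargetAssay],
    run_status: str = "valid",
    min_conc: float = DEFAULT_MIN_RNA_CONC,
    ic_range: tuple[float, float] = DEFAULT_IC_RANGE,
) -> SampleCall:
    """Sample-level qualitative FGFR status.

    Precedence: *insufficient* (RNA below minimum, when quantified) is
    assessed before *invalid* (failed run controls or internal control out
    of its acceptance window), which is assessed before any target call.
    A valid sample is fgfr_positive iff at least one target's Ct is at or
    below its cut-off, with every positive target listed in panel order.
    """
    panel_names = [a.name for a in panel]
    unknown = set(profile.target_ct) - set(panel_names)
    if unknown:
        raise ValueError(
            f"sample {profile.sample_id}: unknown target(s) {sorted(unknown)}"
        )
    missing = set(panel_names) - set(profile.target_ct)
    if missing:
        raise ValueError(
            f"sample {profile.sample_id}: missing target(s) {sorted(missing)}"
        )

    if profile.rna_conc is not None:
        if check_rna_sufficiency(profile.rna_conc, min_conc) == "insufficient":
            return SampleCall(profile.sample_id, "insufficient")

    ic = profile.internal_control_ct
    ic_ok = ic is not None and ic_range[0] <= ic <= ic_range[1]
    if run_status != "valid" or not ic_ok:
        return SampleCall(profile.sample_id, "invalid")

    positives = tuple(
        a.name for a in panel
        if call_target(profile.target_ct[a.name], a.ct_cutoff) == "positive"
    )
    if positives:
        return SampleCall(profile.sample_id, "fgfr_positive", positives)
    return SampleCall(profile.sample_id, "fgfr_negative")


@dataclass(frozen=True)
class ValidityTally:
    """Per-status counts/percentages over a batch of sample calls.

    ``valid_percent`` pools the two callable statuses (positive + negative),
    matching how a testing report accounts for samples that yielded a
    result.  Percentages are rounded to one decimal for reporting; counts
    are exact.
    """

    n: int
    counts: dict[str, int]
    percents: dict[str, float]
    valid_n: int
    valid_percent: float


def tally_validity(calls: Sequence[SampleCall]) -> ValidityTally:
    """Count samples per status and report percentages of the full batch."""
    if not calls:
        raise ValueError("tally_validity requires a non-empty list of calls")
    n = len(calls)
    counts = Counter(c.status for c in calls)
    full = {s: counts.get(s, 0) for s in VALID_STATUSES}
    percents = {s: round(100.0 * c / n, 1) for s, c in full.items()}
    valid_n = full["fgfr_positive"] + full["fgfr_negative"]
    return ValidityTally(
        n=n,
        counts=full,
        percents=percents,
        valid_n=valid_n,
        valid_percent=round(100.0 * valid_n / n, 1),
    )
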