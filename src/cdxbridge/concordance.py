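"""Agreement statistics for paired qualitative assay calls.

A bridging study compares an index test (the companion diagnostic, CDx)
against a reference (the clinical trial assay, CTA, or an orthogonal ddPCR
assay) on paired binary calls, summarised in an oriented 2x2 table:

================  =========  =========
                  ref +      ref -
index +           a          b
index -           c          d
================  =========  =========

with positive, negative and overall percent agreement

    PPA = a / (a + c),   NPA = d / (b + d),   OPA = (a + d) / N.

Each proportion carries a two-sided binomial confidence interval, either the
Wilson score interval or the exact Clopper-Pearson interval; both are
first-class because study reports mix them (score intervals for agreement
and response-rate tables, exact intervals where a protocol requires "exact"
bounds, e.g. an accuracy study's acceptance rule on CI lower limits).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "AgreementTable",
    "ProportionEstimate",
    "AccuracyDecision",
    "build_2x2",
    "wilson_ci",
    "clopper_pearson_ci",
    "proportion_estimate",
    "percent_agreement",
    "accuracy_decision",
]

CI_METHODS = ("wilson", "clopper_pearson")
_STATSMODELS_METHOD = {"wilson": "wilson", "clopper_pearson": "beta"}


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion x/n on the percent scale with its CI.

    Internal values are never rounded; rounding happens only at report
    serialisation.
    """

    numerator: int
    denominator: int
    point: float
    ci_low: float
    ci_high: float
    method: str
    conf_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("need 0 <= numerator <= denominator")
        if not (0.0 <= self.ci_low <= self.point + 1e-9
                and self.point - 1e-9 <= self.ci_high <= 100.0):
            raise ValueError("CI must bracket the point estimate within [0, 100]")

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        """(point, low, high) rounded for table output."""
        return (
            round(self.point, ndigits),
            round(self.ci_low, ndigits),
            round(self.ci_high, ndigits),
        )


def _binomial_ci(x: int, n: int, conf_level: float, method: str) -> tuple[float, float]:
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not 0 < conf_level < 1:
        raise ValueError("conf_level must be in (0, 1)")
    lo, hi = proportion_confint(x, n, alpha=1 - conf_level,
                                method=_STATSMODELS_METHOD[method])
    # guard against one-ulp overshoot of the [0, 1] range
    return max(0.0, 100.0 * float(lo)), min(100.0, 100.0 * float(hi))


def wilson_ci(x: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, in percent.

    Symmetric in complement: the interval for (n - x, n) is the reflection
    (100 - high, 100 - low).
    """
    return _binomial_ci(x, n, conf_level, "wilson")


def clopper_pearson_ci(x: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Exact (beta-quantile) Clopper-Pearson interval, in percent.

    x = 0 pins the lower bound at 0; x = n pins the upper bound at 100.
    """
    return _binomial_ci(x, n, conf_level, "clopper_pearson")


def proportion_estimate(
    x: int, n: int, method: str = "wilson", conf_level: float = 0.95
) -> ProportionEstimate:
    """Point estimate plus CI for x successes of n, as a ProportionEstimate."""
    if method not in CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}; expected one of {CI_METHODS}")
    lo, hi = _binomial_ci(x, n, conf_level, method)
    return ProportionEstimate(x, n, 100.0 * x / n, lo, hi, method, conf_level)


@dataclass(frozen=True)
class AgreementTable:
    """Oriented 2x2 counts: index test on rows, reference on columns."""

    a: int  # index+ & ref+
    b: int  # index+ & ref-
    c: int  # index- & ref+
    d: int  # index- & ref-
    index_name: str = "CDx"
    ref_name: str = "CTA"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n == 0:
            raise ValueError("agreement table must contain at least one pair")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def build_2x2(
    paired_calls: Iterable[tuple[str, str]] | Iterable[tuple[str, str, str]],
    positive_label: str = "positive",
    negative_label: str = "negative",
    index_name: str = "CDx",
    ref_name: str = "CTA",
) -> AgreementTable:
    """Tabulate paired (index, ref) calls into an oriented 2x2 table.

    Pairs may carry a leading sample id for error reporting.  Every call
    must be the positive or negative label: samples with an invalid,
    insufficient, or missing result must be excluded upstream (they belong
    in the validity tally, not the agreement table).
    """
    a = b = c = d = 0
    n_seen = 0
    for i, pair in enumerate(paired_calls):
        if len(pair) == 3:
            sample, index_call, ref_call = pair
        else:
            index_call, ref_call = pair
            sample = f"pair #{i}"
        for name, call in ((index_name, index_call), (ref_name, ref_call)):
            if call not in (positive_label, negative_label):
                raise ValueError(
                    f"{sample}: non-binary {name} call {call!r}; exclude "
                    "invalid/insufficient pairs before building the 2x2 table"
                )
        n_seen += 1
        if index_call == positive_label:
            if ref_call == positive_label:
                a += 1
            else:
                b += 1
        else:
            if ref_call == positive_label:
                c += 1
            else:
                d += 1
    if n_seen == 0:
        raise ValueError("no paired calls supplied")
    return AgreementTable(a, b, c, d, index_name=index_name, ref_name=ref_name)


def percent_agreement(
    table: AgreementTable, method: str = "wilson", conf_level: float = 0.95
) -> dict[str, ProportionEstimate]:
    """PPA, NPA and OPA with CIs for an oriented 2x2 table.

    PPA conditions on reference-positive pairs, NPA on reference-negative
    pairs, OPA on all pairs; raises if a conditioning margin is empty.
    """
    if table.a + table.c == 0:
        raise ValueError("PPA undefined: no reference-positive pairs")
    if table.b + table.d == 0:
        raise ValueError("NPA undefined: no reference-negative pairs")
    return {
        "ppa": proportion_estimate(table.a, table.a + table.c, method, conf_level),
        "npa": proportion_estimate(table.d, table.b + table.d, method, conf_level),
        "opa": proportion_estimate(table.a + table.d, table.n, method, conf_level),
    }


@dataclass(frozen=True)
class AccuracyDecision:
    """Outcome of the accuracy acceptance rule on CI lower limits."""

    passed: bool
    ppa_ci_low: float
    npa_ci_low: float
    ppa_floor: float
    npa_floor: float
    ppa_ok: bool
    npa_ok: bool


def accuracy_decision(
    ppa: ProportionEstimate,
    npa: ProportionEstimate,
    ppa_floor: float = 85.0,
    npa_floor: float = 90.0,
) -> AccuracyDecision:
    """Accuracy acceptance: pass iff the CI lower limit for PPA is >= its
    floor AND the CI lower limit for NPA is >= its floor (both inclusive)."""
    ppa_ok = ppa.ci_low >= ppa_floor
    npa_ok = npa.ci_low >= npa_floor
    return AccuracyDecision(
        passed=ppa_ok and npa_ok,
        ppa_ci_low=ppa.ci_low,
        npa_ci_low=npa.ci_low,
        ppa_floor=ppa_floor,
        npa_floor=npa_floor,
        ppa_ok=ppa_ok,
        npa_ok=npa_ok,
    )
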