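"""Weighted-ORR imputation sensitivity analysis.

In a bridging study, patients positive on the new companion diagnostic but
negative on the enrolling trial assay (CDx+/CTA-, the *positive discordant*
stratum) were never treated, so their response rate is unobservable.  The
sensitivity analysis imputes it as a stated fraction f of the observed ORR
in the *positive concordant* (CDx+/CTA+) stratum and reports the weighted
overall ORR

    ORR_w(f) = w * ORR_cc + (1 - w) * f * ORR_cc = ORR_cc * (w + (1 - w) f),

where w is the probability weight of the concordant stratum among CDx+
patients.  The weight is not printed in study reports; two constructions
are provided:

* ``calibrate_weight`` — anchor the f = 0 scenario to a reference ORR
  (e.g. the ORR of all trial-assay-positive treated patients), giving
  w = ORR_ref / ORR_cc.  This is the default.
* ``prevalence_weight`` — the expected concordant share of CDx+ patients in
  a screened population with prevalence p and agreement rates PPA / NPA:
  w = p*PPA / (p*PPA + (1-p)*(1-NPA)).  Offered as an interpretation, not
  ground truth.

Uncertainty comes from a seeded percentile bootstrap over the concordant
patients only: the imputed stratum is a deterministic multiple of ORR_cc,
so each resample recomputes ORR_cc and applies the affine map above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "WeightScheme",
    "WeightedScenario",
    "DEFAULT_FRACTIONS",
    "calibrate_weight",
    "prevalence_weight",
    "weighted_orr_point",
    "bootstrap_weighted_ci",
    "scenario_table",
]

DEFAULT_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)
DEFAULT_N_BOOT = 2000


@dataclass(frozen=True)
class WeightScheme:
    """Probability weight of the concordant-positive stratum among CDx+."""

    w_concordant: float
    source: str = "explicit"  # calibrated | prevalence_model | explicit

    def __post_init__(self) -> None:
        if not 0.0 < self.w_concordant <= 1.0:
            raise ValueError("w_concordant must lie in (0, 1]")


@dataclass(frozen=True)
class WeightedScenario:
    """One imputation scenario: fraction f, hypothetical discordant ORR
    (= f * ORR_cc), and the weighted overall ORR with its bootstrap CI."""

    fraction: float
    hypothetical_orr: float
    weighted_orr: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def _weight(w: WeightScheme | float) -> float:
    return w.w_concordant if isinstance(w, WeightScheme) else float(w)


def calibrate_weight(orr_concordant: float, orr_reference: float) -> WeightScheme:
    """Weight anchored so the f = 0 scenario equals ``orr_reference``.

    Both arguments are on the percent scale.  Requires
    0 <= orr_reference <= orr_concordant (otherwise the weight would leave
    (0, 1]).
    """
    if not 0.0 < orr_concordant <= 100.0:
        raise ValueError("orr_concordant must lie in (0, 100]")
    if orr_reference < 0.0 or orr_reference > orr_concordant:
        raise ValueError(
            "calibration requires 0 <= orr_reference <= orr_concordant "
            f"(got {orr_reference} vs {orr_concordant}); weight would exceed 1"
        )
    return WeightScheme(orr_reference / orr_concordant, source="calibrated")


def prevalence_weight(prevalence: float, ppa: float, one_minus_npa: float) -> WeightScheme:
    """Expected concordant share of CDx+ patients in a screened population.

    With alteration prevalence p and paired-assay agreement rates, a CDx+
    patient is CTA+ (concordant) with probability
    p*PPA / (p*PPA + (1-p)*(1-NPA)).  All arguments are probabilities in
    (0, 1).
    """
    for name, v in (("prevalence", prevalence), ("ppa", ppa),
                    ("one_minus_npa", one_minus_npa)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {v}")
    denom = prevalence * ppa + (1.0 - prevalence) * one_minus_npa
    if denom <= 0.0:
        raise ValueError("degenerate denominator: no CDx+ mass")
    return WeightScheme(prevalence * ppa / denom, source="prevalence_model")


def weighted_orr_point(orr_cc: float, f: float, w: WeightScheme | float) -> float:
    """Weighted overall ORR (percent) at imputation fraction f."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction f must lie in [0, 1]")
    wc = _weight(w)
    return orr_cc * (wc + (1.0 - wc) * f)


def _responses_array(responses: Sequence[int] | np.ndarray) -> np.ndarray:
    arr = np.asarray(responses, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("responses must be a non-empty 1-d indicator array")
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("responses must be 0/1 responder indicators")
    return arr


def bootstrap_weighted_ci(
    responses: Sequence[int] | np.ndarray,
    w: WeightScheme | float,
    f: float,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    conf_level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the weighted ORR at fraction f.

    Resamples the concordant-positive responder indicators with
    replacement, recomputes ORR_cc per resample and applies the weighted
    point map; the weight itself is held fixed.  Bit-reproducible given
    ``seed``.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200 for a percentile interval")
    if seed is None:
        raise ValueError("a seed is required for a reproducible bootstrap")
    arr = _responses_array(responses)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, arr.size, size=(n_boot, arr.size))
    orr_boot = 100.0 * arr[draws].mean(axis=1)
    wc = _weight(w)
    stat = orr_boot * (wc + (1.0 - wc) * f)
    alpha = 1.0 - conf_level
    lo, hi = np.percentile(stat, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def scenario_table(
    responses: Sequence[int] | np.ndarray,
    w: WeightScheme | float,
    f_list: Sequence[float] = DEFAULT_FRACTIONS,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    conf_level: float = 0.95,
) -> list[WeightedScenario]:
    """One WeightedScenario per imputation fraction.

    All scenarios share one bootstrap resampling of ORR_cc (same seed), so
    their intervals are comparable row to row.
    """
    arr = _responses_array(responses)
    orr_cc = 100.0 * arr.mean()
    rows = []
    for f in f_list:
        lo, hi = bootstrap_weighted_ci(arr, w, f, n_boot=n_boot, seed=seed,
                                       conf_level=conf_level)
        rows.append(WeightedScenario(
            fraction=float(f),
            hypothetical_orr=f * orr_cc,
            weighted_orr=weighted_orr_point(orr_cc, f, w),
            ci_low=lo,
            ci_high=hi,
            n_boot=n_boot,
            seed=seed,
        ))
    return rows
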