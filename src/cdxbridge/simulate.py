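"""Synthetic screened-cohort generator for bridging-study analyses.

Emulates the data-generating process the analysis pipeline assumes: a
screened population of urothelial-carcinoma patients (~2,000 by default) in
which ~18% carry one of nine FGFR2/3 alterations, screened by an imperfect
trial assay (CTA); CTA-positive patients are treated and contribute a best
response drawn per alteration; every eligible sample is retested by the
companion diagnostic (CDx), whose call is concordant with the CTA at
configurable rates, and a small fraction of samples fails pre-analytical
(insufficient RNA) or analytical (run/internal-control) quality gates.

Two generation paths exist:

* the *statistical* path (``generate``) assigns CTA/CDx/ddPCR calls
  directly from the configured rates — fast, used for parameter-recovery
  tests;
* the *mechanistic* path (``generate_ct_profiles``) additionally renders
  each sample as per-target Ct values plus run controls, so the calls are
  reproduced by the qualitative call engine from raw-style inputs — used
  for end-to-end tests, since the engine's Ct cut-offs are themselves
  synthetic.

Default parameters are frozen study conditions: per-alteration frequencies
proportional to the treated double-positive subgroup sizes, CDx|CTA
concordance 0.872 / 0.030, invalid/insufficient sample rates 1.7% / 1.0%,
and per-alteration response probabilities equal to the observed subgroup
ORRs (rare fusion targets at the fusion-class aggregate 1/3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import DEFAULT_CT_CUTOFF, DEFAULT_IC_RANGE, PANEL_TARGETS, UNDETERMINED

__all__ = [
    "CtModel",
    "DemographicsModel",
    "CohortConfig",
    "SyntheticCohort",
    "generate",
    "generate_ct_profiles",
]


class ConfigError(ValueError):
    """Raised for invalid cohort-generation parameters."""


# Subgroup sizes of the treated double-positive population, used as
# prevalence weights; never-observed targets get a floor of 1 so that they
# can occur at all.
_ALTERATION_WEIGHTS = {
    "R248C": 13, "S249C": 42, "G370C": 3, "Y373C": 11,
    "TACC3_V1": 14, "TACC3_V3": 5, "BAIAP2L1": 1, "CASP7": 1, "BICC1": 1,
}

_RESPONSE_PROBS = {
    "R248C": 7 / 13, "S249C": 19 / 42, "G370C": 1 / 3, "Y373C": 7 / 11,
    "TACC3_V1": 5 / 14, "TACC3_V3": 1 / 5,
    # rare fusions: fusion-class aggregate
    "BAIAP2L1": 1 / 3, "CASP7": 1 / 3, "BICC1": 1 / 3,
}


@dataclass(frozen=True)
class CtModel:
    """Gaussian Ct emission model for the mechanistic path.

    Positive targets amplify well below the cut-off (mean 5 cycles below
    the 33-cycle synthetic default), negatives usually fail to amplify and
    otherwise land above the cut-off; the internal control sits mid-window.
    """

    positive_mean: float = 28.0
    positive_sd: float = 1.5
    negative_detect_prob: float = 0.05
    negative_mean: float = 36.5
    negative_sd: float = 0.8
    internal_control_mean: float = 27.0
    internal_control_sd: float = 2.0


@dataclass(frozen=True)
class DemographicsModel:
    """Baseline-variable distributions shared by tested and not-tested
    patients (the representative, null configuration).

    Continuous variables are normal (optionally clipped to a range);
    categorical variables are sampled from fixed frequencies.
    """

    continuous: Mapping[str, tuple[float, float, float | None, float | None]] = field(
        default_factory=lambda: {
            "age": (66.6, 9.87, 18.0, None),
            "tumor_area": (61.9, 30.37, 0.0, 100.0),
            "viable_cells": (64.9, 25.18, 0.0, 100.0),
        }
    )
    categorical: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "sex": {"Male": 0.762, "Female": 0.238},
            "race": {"White": 0.657, "Black": 0.010, "Asian": 0.141, "Other": 0.192},
            "ethnicity": {"Hispanic/Latino": 0.016, "Not Hispanic/Latino": 0.771,
                          "Unknown": 0.213},
            "region": {"North America": 0.158, "Asia": 0.156, "Europe": 0.686},
            "site": {"Primary": 0.845, "Metastatic": 0.154, "Unknown": 0.001},
        }
    )
    tested_fraction: float = 0.28


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the generator; ``seed`` is mandatory.

    ``total_prevalence`` is split across targets proportionally to
    ``alteration_weights``; the remainder of the population carries no
    alteration.  ``cdx_pos_given_cta_pos``/``_neg`` directly control the
    expected PPA and 1 - NPA of the paired assays.
    """

    seed: int
    n_screened: int = 2000
    total_prevalence: float = 0.18
    alteration_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_ALTERATION_WEIGHTS)
    )
    cta_sensitivity: float = 0.95
    cta_specificity: float = 0.99
    cdx_pos_given_cta_pos: float = 0.872
    cdx_pos_given_cta_neg: float = 0.030
    ddpcr_sensitivity: float = 0.99
    ddpcr_specificity: float = 0.995
    response_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(_RESPONSE_PROBS)
    )
    response_prob_no_alteration: float = 0.20
    treated_prob_given_cta_pos: float = 0.99
    chemo_refractory_prob: float = 0.879
    insufficient_rate: float = 0.010
    invalid_rate: float = 0.017
    demographics: DemographicsModel = field(default_factory=DemographicsModel)
    ct_model: CtModel = field(default_factory=CtModel)
    ct_cutoff: float = DEFAULT_CT_CUTOFF
    run_size: int = 72

    def __post_init__(self) -> None:
        probs = {
            "total_prevalence": self.total_prevalence,
            "cta_sensitivity": self.cta_sensitivity,
            "cta_specificity": self.cta_specificity,
            "cdx_pos_given_cta_pos": self.cdx_pos_given_cta_pos,
            "cdx_pos_given_cta_neg": self.cdx_pos_given_cta_neg,
            "ddpcr_sensitivity": self.ddpcr_sensitivity,
            "ddpcr_specificity": self.ddpcr_specificity,
            "response_prob_no_alteration": self.response_prob_no_alteration,
            "treated_prob_given_cta_pos": self.treated_prob_given_cta_pos,
            "chemo_refractory_prob": self.chemo_refractory_prob,
            "insufficient_rate": self.insufficient_rate,
            "invalid_rate": self.invalid_rate,
            **{f"response_prob[{t}]": p for t, p in self.response_prob.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {p}")
        if self.insufficient_rate + self.invalid_rate > 1.0:
            raise ConfigError("insufficient_rate + invalid_rate exceeds 1")
        if self.n_screened < 1:
            raise ConfigError("n_screened must be positive")
        if set(self.alteration_weights) - set(PANEL_TARGETS):
            raise ConfigError("alteration_weights contains unknown targets")
        if any(w < 0 for w in self.alteration_weights.values()):
            raise ConfigError("alteration_weights must be nonnegative")

    @property
    def prevalence(self) -> dict[str, float]:
        """Per-target prevalence map (sums to ``total_prevalence``)."""
        total_w = sum(self.alteration_weights.values())
        return {
            t: self.total_prevalence * w / total_w
            for t, w in self.alteration_weights.items()
        }


@dataclass
class SyntheticCohort:
    """Generated cohort: one patients table + one demographics table.

    ``patients`` has one row per screened patient with the underlying
    truth (``true_alteration``), both assay calls, the CDx sample QC
    status, and treatment/response fields; the ``*_table`` methods project
    it onto the delimited-text schemas the pipeline reads.
    """

    config: CohortConfig
    patients: pd.DataFrame
    demographics: pd.DataFrame

    def outcomes_table(self) -> pd.DataFrame:
        cols = ["patient_id", "treated", "response", "alteration",
                "chemo_refractory", "cta_call", "cdx_call"]
        out = self.patients.rename(columns={"true_alteration": "alteration"})
        out = out.copy()
        # CDx call reported as its QC status when no valid result exists
        bad = out["sample_status"] != "valid"
        out.loc[bad, "cdx_call"] = out.loc[bad, "sample_status"]
        return out[cols]

    def paired_calls_table(self, include_ddpcr: bool = True) -> pd.DataFrame:
        out = self.patients.copy()
        bad = out["sample_status"] != "valid"
        out.loc[bad, "cdx_call"] = out.loc[bad, "sample_status"]
        out = out.rename(columns={"patient_id": "sample_id",
                                  "cdx_call": "index_call", "cta_call": "ref_call"})
        cols = ["sample_id", "index_call", "ref_call"]
        if include_ddpcr:
            cols.append("ddpcr_call")
        return out[cols]

    def demographics_table(self) -> pd.DataFrame:
        return self.demographics.copy()


def _draw_categorical(rng: np.random.Generator, freqs: Mapping[str, float],
                      n: int) -> np.ndarray:
    cats = list(freqs)
    p = np.array([freqs[c] for c in cats], dtype=float)
    p = p / p.sum()
    return rng.choice(cats, size=n, p=p)


def generate(config: CohortConfig) -> SyntheticCohort:
    """Generate a screened cohort through the statistical (direct-call)
    path; reproducible given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_screened

    prev = config.prevalence
    labels = list(prev) + ["none"]
    p = np.array([prev[t] for t in prev] + [1.0 - sum(prev.values())])
    true_alt = rng.choice(labels, size=n, p=p)
    altered = true_alt != "none"

    u = rng.random(n)
    cta_pos = np.where(altered, u < config.cta_sensitivity,
                       u < 1.0 - config.cta_specificity)

    u = rng.random(n)
    cdx_pos = np.where(cta_pos, u < config.cdx_pos_given_cta_pos,
                       u < config.cdx_pos_given_cta_neg)

    u = rng.random(n)
    ddpcr_pos = np.where(altered, u < config.ddpcr_sensitivity,
                         u < 1.0 - config.ddpcr_specificity)

    u = rng.random(n)
    status = np.where(
        u < config.insufficient_rate, "insufficient",
        np.where(u < config.insufficient_rate + config.invalid_rate,
                 "invalid", "valid"),
    )

    treated = cta_pos & (rng.random(n) < config.treated_prob_given_cta_pos)
    chemo_ref = treated & (rng.random(n) < config.chemo_refractory_prob)

    p_resp = np.array([
        config.response_prob.get(t, config.response_prob_no_alteration)
        if t != "none" else config.response_prob_no_alteration
        for t in true_alt
    ])
    responder = treated & (rng.random(n) < p_resp)
    # best-response categories: responders mostly PR, non-responders SD/PD/NE
    resp_cat = np.full(n, "", dtype=object)
    u = rng.random(n)
    resp_cat[responder] = np.where(u[responder] < 0.15, "CR", "PR")
    nonresp = treated & ~responder
    resp_cat[nonresp] = np.select(
        [u[nonresp] < 0.35, u[nonresp] < 0.90], ["SD", "PD"], default="NE"
    )

    ids = np.array([f"P{i:05d}" for i in range(n)])
    patients = pd.DataFrame({
        "patient_id": ids,
        "true_alteration": np.where(altered, true_alt, "none"),
        "cta_call": np.where(cta_pos, "positive", "negative"),
        "cdx_call": np.where(cdx_pos, "positive", "negative"),
        "ddpcr_call": np.where(ddpcr_pos, "positive", "negative"),
        "sample_status": status,
        "treated": treated,
        "chemo_refractory": chemo_ref,
        "response": resp_cat,
    })

    demo = config.demographics
    demo_cols: dict[str, np.ndarray] = {
        "patient_id": ids,
        "tested": rng.random(n) < demo.tested_fraction,
    }
    for var, (mean, sd, lo, hi) in demo.continuous.items():
        x = rng.normal(mean, sd, size=n)
        if lo is not None or hi is not None:
            x = np.clip(x, lo if lo is not None else -np.inf,
                        hi if hi is not None else np.inf)
        demo_cols[var] = np.round(x, 1)
    for var, freqs in demo.categorical.items():
        demo_cols[var] = _draw_categorical(rng, freqs, n)
    demographics = pd.DataFrame(demo_cols)[
        ["patient_id", "tested", "age", "sex", "race", "ethnicity", "region",
         "tumor_area", "viable_cells", "site"]
    ]

    return SyntheticCohort(config=config, patients=patients,
                           demographics=demographics)


def generate_ct_profiles(
    cohort: SyntheticCohort, config: CohortConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render the cohort mechanistically as Ct + run-control tables.

    The call engine, run on these tables, reproduces the cohort's CDx
    calls: samples intended positive amplify their alteration target well
    below the cut-off (a random target for false positives), intended
    negatives amplify nothing or only above it; invalid samples get a
    failed internal control and insufficient ones an RNA concentration
    below the input minimum.  Run controls always pass (run-level failures
    are modelled through the per-sample invalid rate).
    """
    config = config or cohort.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    ct = config.ct_model
    pts = cohort.patients
    n = len(pts)
    cutoff = config.ct_cutoff
    ic_lo, ic_hi = DEFAULT_IC_RANGE

    rows = []
    for i in range(n):
        sample_id = pts["patient_id"].iat[i]
        run_id = f"R{i // config.run_size:03d}"
        status = pts["sample_status"].iat[i]
        is_pos = pts["cdx_call"].iat[i] == "positive"
        alt = pts["true_alteration"].iat[i]
        pos_target = None
        if is_pos:
            pos_target = alt if alt in PANEL_TARGETS else rng.choice(PANEL_TARGETS)
        row: dict[str, object] = {"sample_id": sample_id, "run_id": run_id}
        for t in PANEL_TARGETS:
            if t == pos_target:
                row[t] = round(min(rng.normal(ct.positive_mean, ct.positive_sd),
                                   cutoff), 2)
            elif rng.random() < ct.negative_detect_prob:
                row[t] = round(max(rng.normal(ct.negative_mean, ct.negative_sd),
                                   cutoff + 0.5), 2)
            else:
                row[t] = UNDETERMINED
        if status == "invalid":
            row["internal_control_ct"] = UNDETERMINED
        else:
            ic = np.clip(rng.normal(ct.internal_control_mean,
                                    ct.internal_control_sd),
                         ic_lo + 0.5, ic_hi - 0.5)
            row["internal_control_ct"] = round(float(ic), 2)
        if status == "insufficient":
            row["rna_conc"] = round(float(rng.uniform(2.0, 17.0)), 1)
        else:
            row["rna_conc"] = round(float(rng.uniform(25.0, 80.0)), 1)
        rows.append(row)
    ct_table = pd.DataFrame(rows)

    control_rows = []
    for run in ct_table["run_id"].unique():
        for target in PANEL_TARGETS:
            control_rows.append({
                "run_id": run, "control_type": "ptc", "target": target,
                "ct": round(float(rng.uniform(23.0, 27.0)), 2),
            })
            control_rows.append({
                "run_id": run, "control_type": "ntc", "target": target,
                "ct": UNDETERMINED,
            })
    controls = pd.DataFrame(control_rows)
    return ct_table, controls
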