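"""End-to-end bridging-study pipeline: files in, report out.

Orchestrates the stage modules into one deterministic run mirroring a
bridging-study report: sample-validity accounting, cohort
representativeness, index-vs-reference concordance, accuracy against an
orthogonal reference with its acceptance rule, ORR tables with the
primary-objective rule, and the weighted-ORR imputation scenarios.
Sections whose inputs are absent are skipped with a logged notice.  Report
values are kept at full precision internally; rounding (1 decimal for
agreement/efficacy tables, 2 for the accuracy table) happens only when
tables are serialised.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import concordance as conc
from . import efficacy as eff
from . import io as bio
from . import panel
from . import represent as rep
from . import weighted as wgt

__all__ = ["PipelineConfig", "BridgingReport", "run_pipeline"]

log = logging.getLogger("cdxbridge.pipeline")

BINARY = ("positive", "negative")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and sampling parameters for one pipeline run."""

    seed: int
    ct_table: str | None = None
    run_controls: str | None = None
    paired_calls: str | None = None
    outcomes: str | None = None
    demographics: str | None = None
    ppa_floor: float = 85.0
    npa_floor: float = 90.0
    orr_margin: float = 25.0
    alpha: float = 0.05
    fractions: tuple[float, ...] = wgt.DEFAULT_FRACTIONS
    n_boot: int = wgt.DEFAULT_N_BOOT
    weight_mode: str = "calibrated"  # calibrated | prevalence
    ct_cutoff: float = panel.DEFAULT_CT_CUTOFF
    min_rna_conc: float = panel.DEFAULT_MIN_RNA_CONC

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = bio.load_config(path)
        if "seed" not in cfg:
            raise ValueError(f"{path}: a 'seed' field is required")
        inputs = cfg.get("inputs", {})
        thresholds = cfg.get("thresholds", {})
        weighted_cfg = cfg.get("weighted", {})
        panel_cfg = cfg.get("panel", {})
        base = Path(path).parent

        def resolve(p: str | None) -> str | None:
            return str(base / p) if p else None

        return cls(
            seed=int(cfg["seed"]),
            ct_table=resolve(inputs.get("ct_table")),
            run_controls=resolve(inputs.get("run_controls")),
            paired_calls=resolve(inputs.get("paired_calls")),
            outcomes=resolve(inputs.get("outcomes")),
            demographics=resolve(inputs.get("demographics")),
            ppa_floor=float(thresholds.get("ppa_floor", 85.0)),
            npa_floor=float(thresholds.get("npa_floor", 90.0)),
            orr_margin=float(thresholds.get("orr_margin", 25.0)),
            alpha=float(thresholds.get("alpha", 0.05)),
            fractions=tuple(weighted_cfg.get("fractions", wgt.DEFAULT_FRACTIONS)),
            n_boot=int(weighted_cfg.get("n_boot", wgt.DEFAULT_N_BOOT)),
            weight_mode=str(weighted_cfg.get("mode", "calibrated")),
            ct_cutoff=float(panel_cfg.get("ct_cutoff", panel.DEFAULT_CT_CUTOFF)),
            min_rna_conc=float(panel_cfg.get("min_rna_conc",
                                             panel.DEFAULT_MIN_RNA_CONC)),
        )


def _est_dict(e: conc.ProportionEstimate) -> dict[str, Any]:
    return {"numerator": e.numerator, "denominator": e.denominator,
            "point": e.point, "ci_low": e.ci_low, "ci_high": e.ci_high,
            "method": e.method, "conf_level": e.conf_level}


def _orr_dict(e: eff.ORREstimate) -> dict[str, Any]:
    return {"subgroup": e.subgroup, "responders": e.responders, "n": e.n,
            "estimate": _est_dict(e.estimate) if e.estimate else None}


@dataclass
class BridgingReport:
    """All sections of one pipeline run, with serialisation helpers.

    The machine-readable summary (``to_dict``) contains exactly the numbers
    rendered in the tables, at full precision — there is no second
    computation path.
    """

    calls: list[panel.SampleCall] | None = None
    validity: panel.ValidityTally | None = None
    representativeness: pd.DataFrame | None = None
    concordance_table: conc.AgreementTable | None = None
    concordance: dict[str, conc.ProportionEstimate] | None = None
    accuracy_table: conc.AgreementTable | None = None
    accuracy: dict[str, conc.ProportionEstimate] | None = None
    accuracy_result: conc.AccuracyDecision | None = None
    efficacy_overall: eff.ORREstimate | None = None
    efficacy_by_alteration: list[eff.ORREstimate] | None = None
    efficacy_chemo_refractory: eff.ORREstimate | None = None
    objective: eff.ObjectiveDecision | None = None
    excluded_no_valid_cdx: int | None = None
    weight: wgt.WeightScheme | None = None
    scenarios: list[wgt.WeightedScenario] | None = None

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        if self.validity:
            out["validity"] = {
                "n": self.validity.n, "counts": self.validity.counts,
                "percents": self.validity.percents,
                "valid_n": self.validity.valid_n,
                "valid_percent": self.validity.valid_percent,
            }
        if self.representativeness is not None:
            out["representativeness"] = self.representativeness.to_dict("records")
        if self.concordance:
            t = self.concordance_table
            out["concordance"] = {
                "table": {"a": t.a, "b": t.b, "c": t.c, "d": t.d, "n": t.n},
                "estimates": {k: _est_dict(v) for k, v in self.concordance.items()},
            }
        if self.accuracy:
            t = self.accuracy_table
            out["accuracy"] = {
                "table": {"a": t.a, "b": t.b, "c": t.c, "d": t.d, "n": t.n},
                "estimates": {k: _est_dict(v) for k, v in self.accuracy.items()},
                "decision": {
                    "passed": self.accuracy_result.passed,
                    "ppa_ci_low": self.accuracy_result.ppa_ci_low,
                    "npa_ci_low": self.accuracy_result.npa_ci_low,
                    "ppa_floor": self.accuracy_result.ppa_floor,
                    "npa_floor": self.accuracy_result.npa_floor,
                },
            }
        if self.efficacy_overall:
            out["efficacy"] = {
                "overall": _orr_dict(self.efficacy_overall),
                "by_alteration": [_orr_dict(e) for e in
                                  (self.efficacy_by_alteration or [])],
                "chemo_refractory": (_orr_dict(self.efficacy_chemo_refractory)
                                     if self.efficacy_chemo_refractory else None),
                "excluded_no_valid_cdx": self.excluded_no_valid_cdx,
                "primary_objective": {
                    "met": self.objective.met, "ci_low": self.objective.ci_low,
                    "margin": self.objective.margin,
                },
            }
        if self.scenarios:
            out["weighted_orr"] = {
                "weight": {"w_concordant": self.weight.w_concordant,
                           "source": self.weight.source},
                "scenarios": [{
                    "fraction": s.fraction,
                    "hypothetical_orr": s.hypothetical_orr,
                    "weighted_orr": s.weighted_orr,
                    "ci_low": s.ci_low, "ci_high": s.ci_high,
                    "n_boot": s.n_boot,
                } for s in self.scenarios],
            }
        return out

    # -- table serialisation -------------------------------------------------

    @staticmethod
    def _agreement_frame(estimates: dict[str, conc.ProportionEstimate],
                         ndigits: int) -> pd.DataFrame:
        rows = []
        for stat, e in estimates.items():
            pt, lo, hi = e.rounded(ndigits)
            rows.append({"statistic": stat, "numerator": e.numerator,
                         "denominator": e.denominator, "point": pt,
                         "ci_low": lo, "ci_high": hi, "method": e.method})
        return pd.DataFrame(rows)

    def efficacy_frame(self, ndigits: int = 1) -> pd.DataFrame:
        rows = []
        for e in self.efficacy_by_alteration or []:
            if e.estimate is None:
                rows.append({"subgroup": e.subgroup, "n": e.n,
                             "responders": e.responders, "orr": "—",
                             "ci_low": "—", "ci_high": "—"})
            else:
                pt, lo, hi = e.estimate.rounded(ndigits)
                rows.append({"subgroup": e.subgroup, "n": e.n,
                             "responders": e.responders, "orr": pt,
                             "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)

    def scenario_frame(self, ndigits: int = 1) -> pd.DataFrame:
        return pd.DataFrame([{
            "fraction": s.fraction,
            "hypothetical_orr": round(s.hypothetical_orr, ndigits),
            "weighted_orr": round(s.weighted_orr, ndigits),
            "ci_low": round(s.ci_low, ndigits),
            "ci_high": round(s.ci_high, ndigits),
        } for s in self.scenarios or []])

    def write(self, outdir: str | Path) -> None:
        """Write every populated section as CSV plus a full-precision
        JSON summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.calls:
            bio.write_calls(self.calls, outdir / "calls.csv")
        if self.validity:
            pd.DataFrame([
                {"status": s, "count": self.validity.counts[s],
                 "percent": self.validity.percents[s]}
                for s in panel.VALID_STATUSES
            ]).to_csv(outdir / "validity.csv", index=False)
        if self.representativeness is not None:
            self.representativeness.to_csv(outdir / "representativeness.csv",
                                           index=False)
        if self.concordance:
            self._agreement_frame(self.concordance, 1).to_csv(
                outdir / "concordance.csv", index=False)
        if self.accuracy:
            self._agreement_frame(self.accuracy, 2).to_csv(
                outdir / "accuracy.csv", index=False)
        if self.efficacy_by_alteration:
            self.efficacy_frame().to_csv(outdir / "efficacy_by_alteration.csv",
                                         index=False)
        if self.scenarios:
            self.scenario_frame().to_csv(outdir / "weighted_orr.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _stage_calls(cfg: PipelineConfig, report: BridgingReport) -> None:
    profiles = bio.read_ct_table(cfg.ct_table)
    runs = bio.read_run_controls(cfg.run_controls)
    run_status = {rid: panel.validate_run(rc)[0] for rid, rc in runs.items()}
    assay_panel = panel.default_panel(cfg.ct_cutoff)
    calls = []
    for p in profiles:
        if p.run_id not in run_status:
            raise ValueError(f"sample {p.sample_id}: no controls for run {p.run_id}")
        calls.append(panel.call_sample(p, assay_panel, run_status[p.run_id],
                                       min_conc=cfg.min_rna_conc))
    report.calls = calls
    report.validity = panel.tally_validity(calls)
    log.info("call stage: %d samples, %.1f%% valid", len(calls),
             report.validity.valid_percent)


def _stage_concordance(cfg: PipelineConfig, report: BridgingReport) -> None:
    pairs = bio.read_paired_calls(cfg.paired_calls)
    ok = pairs["index_call"].isin(BINARY) & pairs["ref_call"].isin(BINARY)
    excluded = int((~ok).sum())
    binary = pairs[ok]
    log.info("concordance: %d pairs (%d excluded as invalid/insufficient)",
             len(binary), excluded)
    if report.validity is None:
        # no Ct-level inputs: account validity from the paired-call statuses
        calls = [
            panel.SampleCall(
                str(r.sample_id),
                {"positive": "fgfr_positive", "negative": "fgfr_negative"}.get(
                    r.index_call, r.index_call),
                ("unspecified",) if r.index_call == "positive" else (),
            )
            for r in pairs.itertuples()
        ]
        report.validity = panel.tally_validity(calls)
    table = conc.build_2x2(
        list(zip(binary["sample_id"], binary["index_call"], binary["ref_call"]))
    )
    report.concordance_table = table
    report.concordance = conc.percent_agreement(table, method="wilson")
    if "ddpcr_call" in pairs.columns:
        acc_ok = ok & pairs["ddpcr_call"].isin(BINARY)
        acc = pairs[acc_ok]
        acc_table = conc.build_2x2(
            list(zip(acc["sample_id"], acc["index_call"], acc["ddpcr_call"])),
            index_name="CDx", ref_name="ddPCR",
        )
        report.accuracy_table = acc_table
        report.accuracy = conc.percent_agreement(acc_table,
                                                 method="clopper_pearson")
        report.accuracy_result = conc.accuracy_decision(
            report.accuracy["ppa"], report.accuracy["npa"],
            cfg.ppa_floor, cfg.npa_floor)
    else:
        log.info("no ddPCR column: accuracy section skipped")


def _stage_efficacy(cfg: PipelineConfig, report: BridgingReport) -> None:
    outcomes = bio.read_outcomes(cfg.outcomes)
    treated = outcomes[outcomes["treated"]]
    double_pos = (outcomes["cta_call"] == "positive") & \
                 (outcomes["cdx_call"] == "positive")
    cta_pos_treated = treated[treated["cta_call"] == "positive"]
    report.excluded_no_valid_cdx = int(
        (cta_pos_treated["cdx_call"] != "positive").sum())

    dp = outcomes[double_pos]
    report.efficacy_overall = eff.orr(dp, subgroup="Overall")
    report.efficacy_by_alteration = eff.orr_by_alteration(dp)
    if dp[dp["treated"] & dp["chemo_refractory"]].shape[0] > 0:
        report.efficacy_chemo_refractory = eff.orr(
            dp, subset=lambda d: d["chemo_refractory"],
            subgroup="Chemo relapsed/refractory")
    report.objective = eff.primary_objective(report.efficacy_overall,
                                             cfg.orr_margin)
    log.info("efficacy: ORR %d/%d, primary objective %s",
             report.efficacy_overall.responders, report.efficacy_overall.n,
             "met" if report.objective.met else "not met")

    # weighted-ORR sensitivity analysis on the concordant-positive stratum
    responses = dp[dp["treated"]]["response"].isin(
        eff.RESPONDER_CATEGORIES).astype(int).to_numpy()
    orr_cc = report.efficacy_overall.estimate.point
    orr_ref = eff.orr(outcomes, subset=lambda d: d["cta_call"] == "positive",
                      subgroup="CTA+").estimate.point
    if cfg.weight_mode == "prevalence":
        pa = report.concordance
        if pa is None:
            raise ValueError("prevalence weight mode requires a concordance stage")
        report.weight = wgt.prevalence_weight(
            0.18, pa["ppa"].point / 100.0, 1.0 - pa["npa"].point / 100.0)
    elif orr_ref > orr_cc:
        # no attenuation between strata observable: degenerate calibration
        log.warning("reference ORR %.1f exceeds concordant ORR %.1f; "
                    "using weight 1", orr_ref, orr_cc)
        report.weight = wgt.WeightScheme(1.0, source="calibrated")
    else:
        report.weight = wgt.calibrate_weight(orr_cc, orr_ref)
    report.scenarios = wgt.scenario_table(
        responses, report.weight, f_list=cfg.fractions,
        n_boot=cfg.n_boot, seed=cfg.seed)


def _stage_representativeness(cfg: PipelineConfig, report: BridgingReport) -> None:
    demo = bio.read_demographics(cfg.demographics)
    report.representativeness = rep.representativeness_report(demo,
                                                              alpha=cfg.alpha)
    flagged = report.representativeness.query("significant")["variable"].tolist()
    log.info("representativeness: %d variables, flagged: %s",
             len(report.representativeness), flagged or "none")


def run_pipeline(cfg: PipelineConfig) -> BridgingReport:
    """Run every stage whose inputs are configured; deterministic given the
    input files and ``cfg.seed``."""
    report = BridgingReport()
    if cfg.ct_table and cfg.run_controls:
        _stage_calls(cfg, report)
    else:
        log.info("no Ct/run-control inputs: call stage skipped")
    if cfg.demographics:
        _stage_representativeness(cfg, report)
    if cfg.paired_calls:
        _stage_concordance(cfg, report)
    if cfg.outcomes:
        _stage_efficacy(cfg, report)
    return report
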