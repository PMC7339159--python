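"""Readers and writers for the pipeline's delimited-text tables.

All inputs are plain CSV.  A reaction that never crossed the fluorescence
threshold is encoded as the literal string ``undetermined`` (never a
numeric placeholder) and surfaces in memory as ``None``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .panel import (
    PANEL_TARGETS,
    UNDETERMINED,
    ControlAcceptance,
    CtProfile,
    RunControls,
    SampleCall,
)

__all__ = [
    "read_ct_table",
    "read_run_controls",
    "read_paired_calls",
    "read_outcomes",
    "read_demographics",
    "write_calls",
    "load_config",
]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def _parse_ct(value: object) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("", UNDETERMINED):
            return None
        value = float(v)
    ct = float(value)
    if ct <= 0:
        raise ValueError(f"Ct values must be positive, got {ct}")
    return ct


def _coerce_bool(series: pd.Series, column: str) -> pd.Series:
    def one(v: object) -> bool:
        if isinstance(v, (bool,)):
            return v
        key = str(v).strip().lower()
        if key not in _BOOL_MAP:
            raise ValueError(f"column {column!r}: cannot parse {v!r} as a flag")
        return _BOOL_MAP[key]

    return series.map(one)


def read_ct_table(path: str | Path,
                  targets: Sequence[str] = PANEL_TARGETS) -> list[CtProfile]:
    """Read a per-sample Ct table.

    Expected header: ``sample_id,run_id,<one column per target>,
    internal_control_ct[,rna_conc]``.
    """
    df = pd.read_csv(path, dtype=str)
    missing = ({"sample_id", "run_id", "internal_control_ct"} | set(targets)) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    profiles = []
    for _, row in df.iterrows():
        profiles.append(CtProfile(
            sample_id=str(row["sample_id"]),
            run_id=str(row["run_id"]),
            target_ct={t: _parse_ct(row[t]) for t in targets},
            internal_control_ct=_parse_ct(row["internal_control_ct"]),
            rna_conc=(float(row["rna_conc"])
                      if "rna_conc" in df.columns and pd.notna(row["rna_conc"])
                      and str(row["rna_conc"]).strip() != "" else None),
        ))
    return profiles


def read_run_controls(
    path: str | Path,
    acceptance: dict[str, ControlAcceptance] | None = None,
) -> dict[str, RunControls]:
    """Read a long-format run-control table
    (``run_id,control_type,target,ct``) into per-run RunControls."""
    df = pd.read_csv(path, dtype=str)
    missing = {"run_id", "control_type", "target", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    runs: dict[str, RunControls] = {}
    for run_id, grp in df.groupby("run_id", sort=False):
        ptc: dict[str, float] = {}
        ntc: dict[str, float | None] = {}
        for _, row in grp.iterrows():
            kind = row["control_type"].strip().lower()
            ct = _parse_ct(row["ct"])
            if kind == "ptc":
                if ct is None:
                    raise ValueError(
                        f"{path}: PTC for {row['target']} in run {run_id} "
                        "must have a numeric Ct")
                ptc[row["target"]] = ct
            elif kind == "ntc":
                ntc[row["target"]] = ct
            else:
                raise ValueError(f"{path}: unknown control_type {kind!r}")
        runs[str(run_id)] = RunControls(str(run_id), ptc, ntc, acceptance or {})
    return runs


def read_paired_calls(path: str | Path) -> pd.DataFrame:
    """Paired-call table: ``sample_id,index_call,ref_call[,ddpcr_call]``."""
    df = pd.read_csv(path, dtype=str)
    missing = {"sample_id", "index_call", "ref_call"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_outcomes(path: str | Path) -> pd.DataFrame:
    """Patient outcome table with treated/chemo_refractory parsed as flags."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"patient_id", "treated", "response", "alteration",
                "chemo_refractory", "cta_call", "cdx_call"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df["treated"] = _coerce_bool(df["treated"], "treated")
    df["chemo_refractory"] = _coerce_bool(df["chemo_refractory"], "chemo_refractory")
    return df


def read_demographics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "tested" not in df.columns:
        raise ValueError(f"{path}: missing column 'tested'")
    df["tested"] = _coerce_bool(df["tested"].astype(str), "tested")
    return df


def write_calls(calls: Sequence[SampleCall], path: str | Path) -> None:
    """Write sample calls as ``sample_id,status,positive_targets``
    (semicolon-joined target list)."""
    pd.DataFrame({
        "sample_id": [c.sample_id for c in calls],
        "status": [c.status for c in calls],
        "positive_targets": [";".join(c.positive_targets) for c in calls],
    }).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a structured YAML configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
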