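"""Shared fixtures: study tables reconstructed from printed counts.

The bridging cohort is rebuilt programmatically from the published
per-subgroup counts: 99 treated CTA+ patients (40 responders), of whom 81
are concordant-positive on the CDx (37 responders, per-alteration split
below) and 18 discordant (CDx-negative, 3 responders, all
chemotherapy-refractory); 69 of the 81 concordant patients are
chemotherapy-refractory with 32 responders.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

# Per-alteration (n, responders) for the treated double-positive patients.
# The published per-target rows overlap (their n sum past the overall 81
# because some patients carry two alterations); this cohort carries one
# primary alteration per patient, so the allocation below is the disjoint
# one consistent with the overall 81/37, the point-mutation aggregate
# 68/34 and the published rows it can preserve.
TABLE4_SUBGROUPS: dict[str, tuple[int, int]] = {
    "R248C": (13, 7),
    "S249C": (41, 19),
    "G370C": (3, 1),
    "Y373C": (11, 7),
    "TACC3_V1": (9, 2),
    "TACC3_V3": (3, 1),
    "BAIAP2L1": (1, 0),
    "CASP7": (0, 0),
    "BICC1": (0, 0),
}

CONCORDANCE_COUNTS = (82, 6, 12, 192)  # CDx vs CTA (reference), N = 292
ACCURACY_COUNTS = (103, 5, 1, 197)  # CDx vs ddPCR (reference), N = 306


def _interleave_flags(n: int, n_true: int) -> np.ndarray:
    """Deterministic 0/1 vector with n_true ones, spread across positions."""
    flags = np.zeros(n, dtype=bool)
    if n_true:
        flags[np.linspace(0, n - 1, n_true).round().astype(int)] = True
    return flags


@pytest.fixture(scope="session")
def bridging_outcomes() -> pd.DataFrame:
    """The 99 treated CTA-positive patients of the bridging cohort."""
    rows = []
    pid = 0
    # concordant-positive stratum: 81 patients, responders per alteration;
    # 12 of them (5 responders) are not chemotherapy-refractory
    chemo_naive_resp, chemo_naive_nonresp = 5, 7
    for alt, (n, resp) in TABLE4_SUBGROUPS.items():
        responders = _interleave_flags(n, resp)
        for r in responders:
            naive = False
            if r and chemo_naive_resp > 0:
                chemo_naive_resp -= 1
                naive = True
            elif not r and chemo_naive_nonresp > 0:
                chemo_naive_nonresp -= 1
                naive = True
            rows.append({
                "patient_id": f"B{pid:03d}", "treated": True,
                "response": "PR" if r else "PD", "alteration": alt,
                "chemo_refractory": not naive,
                "cta_call": "positive", "cdx_call": "positive",
            })
            pid += 1
    # discordant stratum: 18 CTA+/CDx- treated patients, 3 responders,
    # all chemotherapy-refractory
    for i in range(18):
        rows.append({
            "patient_id": f"B{pid:03d}", "treated": True,
            "response": "PR" if i < 3 else "SD", "alteration": "S249C",
            "chemo_refractory": True,
            "cta_call": "positive", "cdx_call": "negative",
        })
        pid += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def double_positive(bridging_outcomes: pd.DataFrame) -> pd.DataFrame:
    return bridging_outcomes[
        (bridging_outcomes["cta_call"] == "positive")
        & (bridging_outcomes["cdx_call"] == "positive")
    ]


@pytest.fixture(scope="session")
def concordant_responses() -> np.ndarray:
    """Responder indicators of the 81 concordant-positive treated patients."""
    return np.array([1] * 37 + [0] * 44)


def pairs_from_counts(a: int, b: int, c: int, d: int) -> list[tuple[str, str, str]]:
    """(sample, index_call, ref_call) triples realising a 2x2 table."""
    cells = [("positive", "positive")] * a + [("positive", "negative")] * b + \
            [("negative", "positive")] * c + [("negative", "negative")] * d
    return [(f"S{i:03d}", idx, ref) for i, (idx, ref) in enumerate(cells)]
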