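"""Call-engine tests: thresholding, QC precedence, validity accounting."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdxbridge.panel import (
    DEFAULT_CT_CUTOFF,
    DEFAULT_IC_RANGE,
    PANEL_TARGETS,
    ControlAcceptance,
    CtProfile,
    RunControls,
    SampleCall,
    call_sample,
    call_target,
    check_rna_sufficiency,
    default_panel,
    tally_validity,
    validate_run,
)

PANEL = default_panel()


def profile(ct_map=None, ic=27.0, rna=None, sample="S1"):
    cts = {t: None for t in PANEL_TARGETS}
    cts.update(ct_map or {})
    return CtProfile(sample, "R1", cts, ic, rna)


class TestRnaSufficiency:
    @pytest.mark.parametrize("conc,expected", [
        (18.0, "sufficient"),   # boundary meets the minimum requirement
        (0.0, "insufficient"),
        (17.9, "insufficient"),
        (100.0, "sufficient"),
    ])
    def test_threshold(self, conc, expected):
        assert check_rna_sufficiency(conc, 18.0) == expected

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            check_rna_sufficiency(-1.0)


class TestCallTarget:
    @pytest.mark.parametrize("ct,expected", [
        (DEFAULT_CT_CUTOFF, "positive"),          # boundary inclusive
        (DEFAULT_CT_CUTOFF + 0.01, "negative"),
        (None, "negative"),                       # no amplification
        (5.0, "positive"),
    ])
    def test_cutoff_rule(self, ct, expected):
        assert call_target(ct, DEFAULT_CT_CUTOFF) == expected

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            call_target(20.0, 0.0)


def make_controls(ptc=25.0, ntc=None, bad_target=None, bad_ptc=None):
    ptc_map = {t: ptc for t in PANEL_TARGETS}
    ntc_map = {t: ntc for t in PANEL_TARGETS}
    if bad_target is not None and bad_ptc is not None:
        ptc_map[bad_target] = bad_ptc
    return RunControls("R1", ptc_map, ntc_map)


class TestValidateRun:
    def test_fully_passing_plate(self):
        status, reasons = validate_run(make_controls())
        assert status == "valid" and reasons == []

    def test_ptc_out_of_range_names_target(self):
        status, reasons = validate_run(make_controls(bad_target="S249C", bad_ptc=32.0))
        assert status == "invalid"
        assert len(reasons) == 1 and "S249C" in reasons[0]

    def test_ntc_contamination(self):
        # NTC amplifying inside the amplifiable range (below the floor)
        status, reasons = validate_run(make_controls(ntc=30.0))
        assert status == "invalid"
        assert all("contamination" in r for r in reasons)

    def test_ntc_late_amplification_accepted(self):
        status, _ = validate_run(make_controls(ntc=38.0))
        assert status == "valid"

    def test_missing_target_rejected(self):
        controls = make_controls()
        del controls.ptc_ct["BICC1"]
        with pytest.raises(ValueError, match="BICC1"):
            validate_run(controls)


class TestCallSample:
    def test_single_positive_target(self):
        call = call_sample(profile({"Y373C": 30.0}), PANEL)
        assert call.status == "fgfr_positive"
        assert call.positive_targets == ("Y373C",)

    def test_all_undetermined_is_negative(self):
        call = call_sample(profile(), PANEL)
        assert call.status == "fgfr_negative" and call.positive_targets == ()

    def test_internal_control_failure_dominates_targets(self):
        call = call_sample(profile({"Y373C": 25.0}, ic=None), PANEL)
        assert call.status == "invalid"

    def test_insufficient_assessed_before_invalid(self):
        call = call_sample(profile({"Y373C": 25.0}, ic=None, rna=5.0), PANEL)
        assert call.status == "insufficient"

    def test_invalid_run_dominates(self):
        call = call_sample(profile({"Y373C": 25.0}), PANEL, run_status="invalid")
        assert call.status == "invalid"

    def test_unknown_target_rejected(self):
        p = profile()
        p.target_ct["NOT_A_TARGET"] = 20.0
        with pytest.raises(ValueError, match="NOT_A_TARGET"):
            call_sample(p, PANEL)

    def test_positive_targets_listed_in_panel_order(self):
        call = call_sample(profile({"BICC1": 30.0, "R248C": 29.0}), PANEL)
        assert call.positive_targets == ("R248C", "BICC1")


def brute_force_status(run_valid, rna, ic, n_pos):
    """Independent decision table for the sample-status logic."""
    if rna is not None and rna < 18.0:
        return "insufficient"
    if not run_valid:
        return "invalid"
    if ic is None or not (DEFAULT_IC_RANGE[0] <= ic <= DEFAULT_IC_RANGE[1]):
        return "invalid"
    return "fgfr_positive" if n_pos > 0 else "fgfr_negative"


def test_decision_table_exhaustive():
    """Every QC-state x positive-count combination maps to exactly the
    status the independent brute-force rule gives."""
    for run_valid, rna, ic, n_pos in itertools.product(
        (True, False), (None, 10.0, 30.0), (None, 27.0, 39.0), range(10)
    ):
        pos = {t: 28.0 for t in PANEL_TARGETS[:n_pos]}
        call = call_sample(profile(pos, ic=ic, rna=rna), PANEL,
                           run_status="valid" if run_valid else "invalid")
        assert call.status == brute_force_status(run_valid, rna, ic, n_pos), (
            run_valid, rna, ic, n_pos)


@settings(max_examples=60, derandomize=True)
@given(
    target=st.sampled_from(PANEL_TARGETS),
    ct=st.floats(1.0, 45.0),
    delta=st.floats(0.0, 20.0),
    others=st.lists(st.sampled_from(PANEL_TARGETS), max_size=4),
)
def test_lowering_ct_never_flips_positive_to_negative(target, ct, delta, others):
    base = profile({t: 30.0 for t in others} | {target: ct})
    lower = profile({t: 30.0 for t in others} | {target: max(ct - delta, 0.5)})
    before = call_sample(base, PANEL).status
    after = call_sample(lower, PANEL).status
    assert not (before == "fgfr_positive" and after == "fgfr_negative")


class TestTallyValidity:
    @staticmethod
    def calls(n_pos, n_neg, n_insuf, n_inv):
        out = [SampleCall(f"p{i}", "fgfr_positive", ("S249C",)) for i in range(n_pos)]
        out += [SampleCall(f"n{i}", "fgfr_negative") for i in range(n_neg)]
        out += [SampleCall(f"i{i}", "insufficient") for i in range(n_insuf)]
        out += [SampleCall(f"v{i}", "invalid") for i in range(n_inv)]
        return out

    def test_study_accounting(self):
        """292 valid of 300 samples gives 97.3% valid, 1.0% insufficient,
        1.7% invalid."""
        tally = tally_validity(self.calls(88, 204, 3, 5))
        assert tally.n == 300 and tally.valid_n == 292
        assert tally.valid_percent == 97.3
        assert tally.percents["insufficient"] == 1.0
        assert tally.percents["invalid"] == 1.7

    def test_all_negative_is_fully_valid(self):
        assert tally_validity(self.calls(0, 10, 0, 0)).valid_percent == 100.0

    def test_symmetric_split(self):
        assert tally_validity(self.calls(4, 0, 0, 4)).valid_percent == 50.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tally_validity([])

    @pytest.mark.parametrize("counts", [(88, 204, 3, 5), (1, 1, 1, 0), (7, 3, 2, 1)])
    def test_percentages_sum_to_100_within_rounding(self, counts):
        tally = tally_validity(self.calls(*counts))
        assert sum(tally.percents.values()) == pytest.approx(100.0, abs=0.4)
        assert sum(tally.counts.values()) == tally.n
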