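"""Synthetic-cohort generator: determinism, parameter recovery, and the
mechanistic Ct path round-tripping through the call engine."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy import stats

from cdxbridge import io as bio
from cdxbridge import panel
from cdxbridge.concordance import build_2x2, percent_agreement
from cdxbridge.simulate import (
    CohortConfig,
    ConfigError,
    CtModel,
    generate,
    generate_ct_profiles,
)


def cfg(**kw) -> CohortConfig:
    kw.setdefault("seed", 123)
    return CohortConfig(**kw)


class TestConfig:
    def test_probabilities_validated(self):
        with pytest.raises(ConfigError, match="cta_sensitivity"):
            cfg(cta_sensitivity=1.5)
        with pytest.raises(ConfigError, match="response_prob"):
            cfg(response_prob={"S249C": -0.1})

    def test_unknown_target_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            cfg(alteration_weights={"V600E": 1.0})

    def test_prevalence_map_sums_to_total(self):
        c = cfg(total_prevalence=0.18)
        assert sum(c.prevalence.values()) == pytest.approx(0.18)


class TestDeterminism:
    def test_same_seed_same_bytes(self):
        a, b = generate(cfg(n_screened=300)), generate(cfg(n_screened=300))
        assert a.patients.to_csv(index=False) == b.patients.to_csv(index=False)
        assert a.demographics.to_csv(index=False) == b.demographics.to_csv(index=False)
        ct_a, rc_a = generate_ct_profiles(a)
        ct_b, rc_b = generate_ct_profiles(b)
        assert ct_a.to_csv(index=False) == ct_b.to_csv(index=False)
        assert rc_a.to_csv(index=False) == rc_b.to_csv(index=False)

    def test_different_seed_differs(self):
        a = generate(cfg(seed=1, n_screened=300))
        b = generate(cfg(seed=2, n_screened=300))
        assert not a.patients.equals(b.patients)


class TestStatisticalPath:
    def test_perfect_assay_limit(self):
        c = cfg(cta_sensitivity=1.0, cta_specificity=1.0,
                cdx_pos_given_cta_pos=1.0, cdx_pos_given_cta_neg=0.0,
                insufficient_rate=0.0, invalid_rate=0.0, n_screened=800)
        cohort = generate(c)
        pairs = cohort.paired_calls_table(include_ddpcr=False)
        table = build_2x2(list(zip(pairs["sample_id"], pairs["index_call"],
                                   pairs["ref_call"])))
        est = percent_agreement(table)
        assert all(est[k].point == 100.0 for k in ("ppa", "npa", "opa"))

    def test_parameter_recovery_large_cohort(self):
        """On a 20,000-patient cohort the empirical PPA/NPA/ORR recover the
        configured rates within 2 binomial SEs."""
        c = cfg(seed=777, n_screened=20_000)
        cohort = generate(c)
        pts = cohort.patients
        valid = pts["sample_status"] == "valid"
        cta_pos = pts["cta_call"] == "positive"
        cdx_pos = pts["cdx_call"] == "positive"

        n_pos = int((valid & cta_pos).sum())
        ppa_hat = (valid & cta_pos & cdx_pos).sum() / n_pos
        se = np.sqrt(0.872 * 0.128 / n_pos)
        assert abs(ppa_hat - c.cdx_pos_given_cta_pos) < 2 * se

        n_neg = int((valid & ~cta_pos).sum())
        npa_hat = (valid & ~cta_pos & ~cdx_pos).sum() / n_neg
        se = np.sqrt(0.97 * 0.03 / n_neg)
        assert abs(npa_hat - (1 - c.cdx_pos_given_cta_neg)) < 2 * se

        treated = pts[pts["treated"]]
        # expected ORR: prevalence-weighted mix of per-alteration rates
        prev = c.prevalence
        p_alt = {t: c.cta_sensitivity * p for t, p in prev.items()}
        p_none = (1 - sum(prev.values())) * (1 - c.cta_specificity)
        total = sum(p_alt.values()) + p_none
        expected_orr = (sum(c.response_prob[t] * p for t, p in p_alt.items())
                        + c.response_prob_no_alteration * p_none) / total
        orr_hat = treated["response"].isin(("CR", "PR")).mean()
        se = np.sqrt(expected_orr * (1 - expected_orr) / len(treated))
        assert abs(orr_hat - expected_orr) < 2 * se

    def test_constant_response_prob_recovers_overall_orr(self):
        c = cfg(seed=9, n_screened=20_000,
                response_prob={t: 0.457 for t in cfg().response_prob},
                response_prob_no_alteration=0.457)
        treated = generate(c).patients.query("treated")
        orr_hat = treated["response"].isin(("CR", "PR")).mean()
        assert orr_hat == pytest.approx(0.457, abs=2 * np.sqrt(0.457 * 0.543 / len(treated)))

    def test_degenerate_prevalence_zero(self):
        cohort = generate(cfg(total_prevalence=0.0, n_screened=200,
                              cta_specificity=1.0))
        assert (cohort.patients["true_alteration"] == "none").all()
        assert not cohort.patients["treated"].any()

    def test_cta_negative_patients_never_treated(self):
        pts = generate(cfg(n_screened=2000)).patients
        assert not pts[pts["cta_call"] == "negative"]["treated"].any()


@pytest.fixture(scope="module")
def roundtrip(tmp_path_factory):
    """Cohort rendered as Ct/run-control files and re-called by the engine."""
    c = cfg(seed=42, n_screened=400)
    cohort = generate(c)
    ct_df, rc_df = generate_ct_profiles(cohort)
    d = tmp_path_factory.mktemp("mech")
    ct_df.to_csv(d / "ct.csv", index=False)
    rc_df.to_csv(d / "rc.csv", index=False)
    profiles = bio.read_ct_table(d / "ct.csv")
    runs = bio.read_run_controls(d / "rc.csv")
    status = {rid: panel.validate_run(rc)[0] for rid, rc in runs.items()}
    assay = panel.default_panel(c.ct_cutoff)
    calls = [panel.call_sample(p, assay, status[p.run_id]) for p in profiles]
    return cohort, calls


class TestMechanisticPath:
    def test_statuses_reproduced_by_engine(self, roundtrip):
        cohort, calls = roundtrip
        want = cohort.patients["sample_status"].to_numpy()
        got = np.array([c.status for c in calls])
        assert ((got == "insufficient") == (want == "insufficient")).all()
        assert ((got == "invalid") == (want == "invalid")).all()

    def test_calls_reproduced_for_valid_samples(self, roundtrip):
        cohort, calls = roundtrip
        valid = cohort.patients["sample_status"] == "valid"
        want = (cohort.patients["cdx_call"] == "positive").to_numpy()[valid]
        got = np.array([c.status == "fgfr_positive" for c in calls])[valid]
        # positives sit ~5 cycles below the cut-off; >99% must round-trip
        assert (got == want).mean() > 0.99

    def test_positive_tail_mass_matches_normal_oracle(self):
        """With the positive Ct distribution centred 5 cycles below the
        cut-off (sd 1), the normal tail gives >99% positive calls."""
        model = CtModel(positive_mean=28.0, positive_sd=1.0)
        p_call = stats.norm.cdf(33.0, loc=model.positive_mean,
                                scale=model.positive_sd)
        assert p_call > 0.99

    def test_zero_failure_rates_give_full_validity(self):
        c = cfg(seed=5, n_screened=300, insufficient_rate=0.0, invalid_rate=0.0)
        cohort = generate(c)
        ct_df, rc_df = generate_ct_profiles(cohort)
        assert (cohort.patients["sample_status"] == "valid").all()
        assert (ct_df["internal_control_ct"] != "undetermined").all()

    def test_default_rates_reproduce_validity_percent(self):
        """Across seeds at n=300, mean validity sits near the configured
        100*(1 - 0.010 - 0.017) = 97.3%."""
        rates = [
            (generate(cfg(seed=s, n_screened=300)).patients["sample_status"]
             == "valid").mean()
            for s in range(20)
        ]
        # SE of the mean over 20 cohorts of 300: ~0.2 points
        assert 100 * np.mean(rates) == pytest.approx(97.3, abs=0.8)
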