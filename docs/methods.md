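# Methods

## Setting and statistical model

A bridging study asks whether a companion diagnostic (CDx) selects the
same benefiting population as the clinical trial assay (CTA) that
enrolled the pivotal trial. Its evidence has four legs, each a module
here:

1. **Analytical concordance.** Paired qualitative calls on the same
   samples form an oriented 2×2 table (index assay on rows, reference on
   columns). Positive, negative and overall percent agreement are
   conditional binomial proportions: PPA = a/(a+c) conditions on
   reference-positive samples, NPA = d/(b+d) on reference-negative ones,
   OPA = (a+d)/N on all pairs. The identity OPA·N = PPA·(a+c) + NPA·(b+d)
   holds exactly and is enforced in tests. An *accuracy study* repeats
   the comparison against an orthogonal reference (droplet digital PCR)
   and applies an acceptance rule on CI lower limits: pass iff
   lower(PPA) ≥ 85% and lower(NPA) ≥ 90%, both inclusive.
2. **Clinical efficacy.** ORR is the fraction of *all treated* patients
   with complete or partial response; non-evaluable patients stay in the
   denominator. The primary objective is met iff the two-sided 95% CI
   lower bound of ORR in CDx-positive patients strictly exceeds 25%.
3. **Imputation sensitivity (weighted ORR).** CDx+/CTA− patients were
   never treated, so their ORR is imputed as f·ORR_cc for stated
   fractions f ∈ {0, 0.25, 0.5, 0.75, 1} of the observed
   concordant-positive ORR, giving
   ORR_w(f) = w·ORR_cc + (1−w)·f·ORR_cc — affine in f with slope
   (1−w)·ORR_cc, hence monotone in both f and ORR_cc.
4. **Representativeness.** Tested vs not-tested patients are compared per
   baseline variable: two-group t-test for continuous variables,
   Pearson chi-square for categorical ones, flagging p < α (0.05).

## Confidence-interval methods

Both the Wilson score interval and the exact Clopper–Pearson interval are
first-class (computed via `statsmodels.stats.proportion.proportion_confint`;
tests cross-check Clopper–Pearson against an independent bisection of the
binomial tail sums to 1e-4 of a percent). The default mapping —
**Wilson** for concordance and efficacy tables, **Clopper–Pearson** for
the accuracy study — was fixed by verifying numerically which method
reproduces each published interval exactly (82/94 → 79.0–92.5 and
37/81 → 35.3–56.5 are Wilson; 103/104 → 94.76–99.98 is Clopper–Pearson).
Study protocols often say "exact CI" while reports print score intervals;
both stay available everywhere. One published reference interval
(40.4%, CI 30.7–50.1 for 40/99) matches neither and appears to be a
Wald interval; it is not reproduced by this package's two methods and is
not used as a check. Report rounding is 1 decimal for agreement/efficacy
tables and 2 decimals for the accuracy table; internal values are never
rounded.

## Call engine

A target call is positive iff its Ct is **less than or equal to** the
assay cut-off (the boundary is inclusive); "undetermined" (no
amplification) is negative. Sample status is decided with strict
precedence — pre-analytical before analytical before reportable:

1. *insufficient* if the RNA concentration is quantified and below the
   18 ng/µL input minimum;
2. *invalid* if the run's template controls fail (PTC outside its
   acceptance window, or NTC amplifying below its contamination floor) or
   the sample's internal control is undetermined/out of window;
3. otherwise *fgfr_positive* (≥ 1 positive target, all listed in panel
   order) or *fgfr_negative*.

The three non-reportable/reportable accounting categories are disjoint,
and the full decision table is verified by exhaustive enumeration against
an independent brute-force rule. Commercial Ct cut-offs are proprietary,
so every threshold here is an explicitly synthetic configuration default:
cut-off 33.0 cycles for all nine targets, internal-control window
[20, 35], NTC floor 35. Multiple positive targets are all reported;
aggregation to a single "primary" alteration happens downstream in the
outcome table, which carries one alteration per patient.

## Weighted-ORR weight and bootstrap

The concordant-stratum weight w is not something a report prints. The
default construction **calibrates** it so the f = 0 scenario reproduces a
stated reference ORR (here the ORR of all CTA-positive treated patients,
40/99): w = ORR_ref / ORR_cc ≈ 0.8845. An alternative
**prevalence-model** weight w = p·PPA / (p·PPA + (1−p)·(1−NPA)) — the
expected concordant share of CDx-positive patients in a screened
population — gives ≈ 0.884 at p = 0.21 with the observed agreement rates,
which supports but does not prove the calibration interpretation; it is
documented as an interpretation, not ground truth.

Uncertainty: percentile bootstrap, B = 2,000 by default (B ≥ 200
enforced), seed mandatory. Each resample redraws the concordant
responder indicators with replacement, recomputes ORR_cc, and applies the
affine map; the weight is held fixed and the imputed stratum contributes
no sampling noise (it is a deterministic multiple of ORR_cc), matching
the "hypothetical ORR values" framing. Consequences checked in tests:
same seed → bit-identical intervals; at f = 1 the interval approximates
the Wilson interval of ORR_cc within ~2 percentage points; width shrinks
roughly as 1/√n when the cohort is replicated fourfold. BCa or
weight-resampling variants are deliberately out of scope.

## Representativeness test choices

The pooled-variance t-test is the default because it reproduces the
published p-values from rounded group summaries (age p ≈ 0.66, viable
cells p ≈ 0.007 → printed 0.01); Welch is available by flag. Chi-square
uses no continuity correction (verified: region p ≈ 0.16, race p ≈ 0.11
from the printed counts alone), df = k−1 for a k×2 table. Categories
observed in only one group are retained; categories empty in both are
dropped; an expected count of exactly zero raises. Published summaries
are accepted directly (`report_from_summaries`) since raw per-patient
data are rarely released.

## Synthetic cohort generator

The generator emulates the screened population the analysis assumes, with
defaults frozen as study conditions:

| parameter | default | basis |
|---|---|---|
| n_screened | 2,000 | screened-population scale |
| total alteration prevalence | 0.18 | ~15% of metastatic urothelial carcinoma, upper-weighted for a screening-enriched population |
| per-target weights | 13:42:3:11:14:5:1:1:1 | treated double-positive subgroup sizes; floor 1 for never-observed fusions |
| CTA sensitivity / specificity | 0.95 / 0.99 | plausible trial-assay operating point (not printed anywhere) |
| P(CDx+ \| CTA+), P(CDx+ \| CTA−) | 0.872 / 0.030 | observed agreement rates |
| insufficient / invalid rate | 0.010 / 0.017 | observed sample accounting |
| response probability per target | observed subgroup ORRs (rare fusions at the class aggregate 1/3) | efficacy table |
| response probability, no alteration | 0.20 | assumed attenuated response in false-positive patients |
| treated \| CTA+ | 0.99 | nearly all CTA+ patients were treated |
| chemo-refractory \| treated | 0.879 | 87 of 99 |
| demographics | screened-column means/SDs and frequencies | baseline table |

CTA-negative patients are never treated — exactly the missingness that
forces the weighted-ORR imputation. The Ct emission model places positive
targets at N(28, 1.5²), five cycles below the cut-off (normal tail: > 99%
call positive), negatives at "undetermined" with 5% late amplification at
N(36.5, 0.8²), and the internal control at N(27, 2²) truncated inside its
window; invalid samples get an undetermined internal control and
insufficient ones an RNA concentration below 18 ng/µL. Run controls are
emitted passing — run-level failures are folded into the per-sample
invalid rate rather than modelled as whole-plate events.

What the generator does *not* emulate: tumor heterogeneity, RNA
degradation, batch/plate effects, correlated demographics, or any
dependence of assay error on Ct proximity to the cut-off. The CDx call is
conditioned on the CTA call (so configured PPA/NPA are recovered
directly), while ddPCR is conditioned on the true alteration; synthetic
CDx-vs-ddPCR agreement is therefore lower than a real accuracy study
would show, and at default settings the synthetic accuracy decision can
fail its floors — a structural property of this conditional-independence
choice, not of the pipeline. Passing end-to-end tests demonstrate correct
propagation of configured rates, not realism of any single sample.

## Pipeline and numerical conventions

Stages run in a fixed order (calls → representativeness → concordance →
accuracy → efficacy → weighted ORR), each skipped with a logged notice
when its inputs are absent; row counts are logged at stage boundaries.
The JSON summary carries full-precision values and the CSV tables their
rounded renderings — the same numbers, no second computation path.
Re-running on identical inputs is byte-identical. Degenerate situations:
zero-denominator subgroups render as "—"; an empty conditioning margin
(no reference-positives) raises rather than reporting NaN; if the
reference ORR exceeds the concordant ORR (possible in synthetic cohorts
where the strata respond identically), the calibrated weight is clamped
to 1 with a logged warning, making all scenarios equal ORR_cc.

Problem sizes used in the test suite — cohorts of 300–500 for end-to-end
checks, 20,000 for parameter recovery, 2,000 bootstrap/coverage
replicates — keep every statistical tolerance at ≥ 2 standard errors
while the full suite runs in seconds.

## Known limitations

- The two CI methods cannot reproduce Wald-style intervals some reports
  print for secondary quantities.
- The weighted-ORR bootstrap ignores uncertainty in the weight itself;
  whether the original analysis resampled it is unstated, so this package
  fixes it and says so.
- Per-patient outcome rows carry a single primary alteration; published
  subgroup rows that overlap (patients with two alterations) cannot be
  reproduced simultaneously with their overall row from disjoint data.
- The representativeness module tests marginal balance only; it is not a
  propensity or standardized-difference diagnostic.
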