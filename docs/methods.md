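# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices, and the places where the design was genuinely open.

## Study design being modelled

A nested case-control design over a population cohort of adults aged 35–70:
cases (HLDL) are hypercholesterolemic by LDL-C > 4.9 mmol/L **and**
TC > 7.5 mmol/L; controls (LLDL) satisfy TC < 5.2 mmol/L with LDL-C in
[2.6, 3.4] mmol/L. Discovery sequences 25 extreme participants per arm;
validation genotypes a 45-variant panel (27 risk-increasing, 18
risk-reducing) in 338 cases vs 339 controls. The HLDL rule conjoins both
cut-offs (the two criteria are stated jointly); because the primary text is
ambiguous on this point the cut-offs and the conjunction live in
`SelectionCriteria` rather than being hard-coded. Ranking for extreme
selection is by LDL-C with TC as tie-break and participant id as the final
deterministic tie-break; the source describes ranking "LDL-C/TC" without an
ordering, so this is this package's explicit convention.

## Prioritization cascade

Filters, in order: exonic-only; drop synonymous SNVs; drop variants
predicted tolerable. The deleteriousness rule is operationalized as
*SIFT = tolerated AND PolyPhen-2 = benign* — the source names both tools and
says tolerable variants were removed without giving a combination rule, and
the AND form is the conservative reading (a variant called damaging by
either tool survives). Frameshift / stop-gain / stop-loss variants bypass
the predictor filter because the predictors are undefined for them, and a
missing prediction never causes removal. The three filters key on disjoint
predicates and therefore commute; this is property-tested by permutation.

Direction is pure carrier exclusivity (carrier = any non-reference genotype
call; dosage is not modelled in discovery). Ranking is a stable sort on
(gene tier, functional-class priority 1 = frameshift/stop, 2 =
non-synonymous SNV, 3 = non-frameshift indel/substitution, carrier count
descending, locus). Tier-3 risk-increasing candidates must additionally
have **strictly more than 10** case carriers and **at least 40%** of the
case arm with zero control carriers. MutationTaster, FATHMM and ClinVar are
carried into the reports as impact-assessment columns, not used as filters.
How exactly 27 + 18 of the larger candidate lists were chosen for
genotyping is not stated in the source; `select_validation_panel` takes the
top-k of the documented ranking and is this package's convention.

Tier gene panels default to the genes named in the published tier tables
(tier 1: LDLR, APOB, PCSK9, LDLRAP1; tier 2: NYNRIN, CELSR2, PARP10, MAF1,
OSBPL7, DCPS, GPAA1, LPA, OPLAH, SPATC1; tier 3: the 13 high-frequency
genes). The full tier-2/3 universes are cited to external references
without enumeration, so anything beyond the defaults requires explicit
`TierConfig` (including the `"complement"` sentinel with a user-supplied
gene universe). A depth filter is assumed to have been applied upstream of
the call set (germline calls at 50× in the source); the reader treats its
input as depth-qualified.

## Association statistics

Crude OR is the cross-product ratio with Woolf standard error; the reported
χ² is the **Wald** statistic (ln OR / se)², not Pearson's — recomputation of
the published univariable rows shows the printed values match the Wald form
(tobacco: 7.98 Wald vs 8.05 Pearson). CIs use 1.96 exactly, which matches
the printed intervals at two decimals. Zero cells raise by default; an
optional Haldane–Anscombe 0.5 correction is available. Report rounding is
2 dp for OR/CI/χ² and 3 dp for p; full precision is kept internally.

Two printed CI bounds in the published univariable table fail the
log-symmetry self-check √(low·high) = OR and are treated as typesetting
slips: the family-history-of-hyperlipidemia interval prints (1.20, 5.40)
where the printed counts give (1.10, 5.40), and the obesity-with-medication
lower bound prints 0.42 where the counts give 0.41. One printed p-value
(family history of stroke: χ² 1.87 with p 0.704) is internally inconsistent
(χ²₁ = 1.87 ⇒ p ≈ 0.17); the computed value is reported. The fasting-glucose
unit is printed inconsistently across the source tables ("mg/L" in one,
mmol/L elsewhere); the values (≈ 6.5–7.2) are only physiological as mmol/L,
which is what the schema uses throughout.

Genotype odds ratios compare each non-reference genotype against the
reference genotype as its own 2×2 (the "CT vs C" layout); additive 0/1/2
coding is available but indicator-vs-reference is the default, matching the
published tables. Bonferroni correction is α/m over the genotyped panel.

## Risk models

Logistic fits are maximum likelihood via statsmodels (Newton iterations,
standard errors from the observed information); rank-deficient designs
raise naming the collinear columns, and perfect separation is flagged on
the fit with CIs suppressed rather than raised. Nagelkerke's R² is the
Cox–Snell R² rescaled by its maximum, 1 − exp(2ℓ₀/n). AUROC is the
Mann–Whitney statistic with ties counted ½; its CI is the DeLong
placement-variance normal interval truncated to [0, 1] (the source does not
name a CI method; DeLong is the field standard). Continuous predictors
enter untransformed per unit; multi-unit odds ratios (e.g. per 5 years) are
derived reporting (ORᵏ), not refits.

Backward elimination removes the highest-p candidate with p ≥ 0.20 unless
its removal changes any remaining coefficient by more than 15% (relative) —
the change-in-estimate heuristic standard in epidemiologic modelling; the
source states the p-threshold but quantifies "no substantive changes" no
further, so 15% is exposed as configuration. Under the null a candidate's
Wald p is approximately uniform, so a single pure-noise predictor is
removed in about 80% of replicates — an inherent property of the p ≥ 0.20
rule, verified by simulation in the test suite.

ΔR² between nested models is only defined on identical rows;
`delta_r2` raises on differing row sets and `fit_nested` aligns the common
complete cases first (whether the published models shared one complete-case
subset is unstated; enforcing alignment is the safe choice). Interaction
tests fit main effects plus a product term and report the product term's
Wald p; inestimable products (empty cells, separation) raise.

## Synthetic data

The generators encode the validation study's marginal structure as
defaults: group sizes 338/339, binary covariates at the published 2×2
counts (exact mode reproduces every cell bit-for-bit, including the missing
cells implied by the varying printed denominators; stochastic mode converts
the same counts to per-group Bernoulli rates), continuous covariates as
per-group Normals at the published means/SDs truncated by rejection (age to
the 35–70 inclusion window), and lipid panels drawn inside each arm's
selection window. Covariates are drawn independently within group — the
source reports only marginals, so no between-covariate correlation is
modelled. Analyses use complete cases per variable, which reproduces the
varying published denominators.

Genotypes: controls are Hardy–Weinberg at the stated MAF; cases are drawn
from the control distribution re-weighted by the target odds ratio per
genotype (OR for each non-reference genotype under the genotypic model,
ORᵏ for k copies under the additive model) and renormalized. This
retrospective tilt is the exact case-control counterpart of injecting the
effect through a logistic disease model with the intercept solved to match
the group sizes — it yields the target per-genotype case-vs-control odds
ratio exactly in expectation with no root-solve. The planted validation
variant uses MAF 0.006 under the genotypic model, chosen so the control
carrier frequency (≈ 1.2%, ~4 carriers of 339) and the case carrier count
(~55 of 338 at OR 16.89) match the published interval width for the
validated frameshift variant.

Call sets plant case- or control-exclusive variants per tier with
annotations that survive the cascade, plus decoys that each violate exactly
one named filter (synonymous, predicted-tolerable, shared-in-both-groups,
intronic). The ground-truth survivor list is emitted by construction and is
property-tested against an independent brute-force application of the
filter predicates. VCFs are version 4.2 with left-anchored indels; one
seeded `numpy` generator per call, no global RNG state, and seeds recorded
in the VCF header.

What the generators do **not** emulate: linkage disequilibrium beyond the
perfect-LD assumption, covariate–covariate and covariate–genotype
correlation, genotyping error, and population structure. Passing tests
therefore demonstrate that the statistical machinery recovers known planted
structure under the study's marginal conditions, not that the published
coefficient values are reproducible — those require the real
individual-level cohort, which is deliberately not consumed.

## Calibration surface

With 500 simulated validation cohorts, the adjusted genotype lnOR's 95% CI
covers ln(16.89) at close to the nominal rate. Replicates in which no
control carrier is drawn produce separated fits whose CIs are suppressed
(per the separation contract above) and count as non-covering; the slight
conservatism of the Wald interval at ~4 expected control carriers keeps the
observed rate in the mid-90s. The Nagelkerke increment from the planted
variant is positive in essentially all replicates, with a median near 0.09
— consistent in magnitude with the published 0.11 → 0.20 shift.

## Sample-size calculation

The design is an allele-based two-proportion pooled z-test: case
risk-allele frequency by retrospective tilt q·RR/(1 + q(RR − 1)), controls
at the population frequency, per-group n the smallest integer meeting the
target power, inflated by 1/r² for imperfect LD. The source cites no
formula or software for its printed anchors (n = 22 at RR 14.78 / MAF
0.0056; n = 184 at RR 1.77 / MAF 0.190), and those inputs are jointly
infeasible under an unaffected-control penetrance formulation at 47.7%
prevalence (the implied heterozygote risk exceeds 1 and the implied
unaffected-control allele frequency is negative). The population-control
tilt is the feasible interpretation that preserves the anchors' ordering
and magnitudes (this package computes 61 and 135); prevalence is used only
by the opt-in unaffected-control adjustment, which raises on infeasibility.
Simulation at the returned n recovers the target power.

## Problem sizes

The test suite uses the study's own sizes throughout (25 vs 25 discovery,
338 vs 339 validation): 500 replicates for CI calibration, 1000 for the
interaction type-I error, 2000 for power simulation and null-CI coverage,
100 random call sets (≤ 200 variants) for cascade/oracle equivalence, and
200 seeds for Hardy–Weinberg goodness-of-fit.
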