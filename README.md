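# fhpanel

Tiered exome-variant prioritization and genetic + non-genetic case-control
risk modelling for hypercholesterolemia.

## What this is for

Familial hypercholesterolemia (FH) studies of the nested case-control kind
sequence the phenotypic extremes of a population cohort — participants with
the highest LDL-cholesterol (LDL-C > 4.9 mmol/L *and* total cholesterol
> 7.5 mmol/L, the Simon Broome-derived cut-offs) against participants in a
normolipidemic window (TC < 5.2 mmol/L, LDL-C 2.6–3.4 mmol/L) — then triage
the exome variants into candidate panels and validate the survivors by
genotyping in a larger cohort. `fhpanel` implements both stages as a tested,
reusable library for analysts who want the full pipeline without the wet lab:

* **Discovery** — a filtering cascade over annotated call sets (VCF 4.2 +
  ANNOVAR-style annotation tables): keep exonic, drop synonymous, drop
  variants predicted tolerable by *both* SIFT and PolyPhen-2 (frameshift and
  stop variants bypass the predictors), classify by carrier exclusivity
  (case-only ⇒ risk-increasing, control-only ⇒ risk-reducing), rank by FH
  gene tier (tier 1: *LDLR*, *APOB*, *PCSK9*, *LDLRAP1*; tier 2:
  LDL-regulating genes; tier 3: other lipid genes) and functional class,
  and apply a high-frequency rule (> 10 case carriers and ≥ 40% of the case
  arm) to tier-3 candidates.
* **Validation** — crude odds ratios with Wald tests from 2×2 tables
  (OR = ad/bc, se = √(1/a+1/b+1/c+1/d), χ² = (ln OR / se)², 95% CI
  = exp(ln OR ± 1.96 se)), Bonferroni correction across the genotyped panel,
  multivariable logistic models with Nagelkerke pseudo-R²
  (R²\_CS / (1 − exp(2 ℓ₀/n))) and AUROC with a DeLong 95% CI, backward
  elimination with a change-in-estimate guard, variance-explained increments
  from adding a variant, and multiplicative gene–environment interaction
  tests.
* **Design** — allele-based sample-size calculation under an additive model
  with perfect marker–risk LD.
* **Synthetic data** — generators for cohorts that reproduce published
  marginal 2×2 counts exactly (or draw them stochastically), Hardy–Weinberg
  genotypes with a planted odds ratio, and call sets with case-exclusive
  planted variants plus decoys that each violate exactly one filter, with
  ground truth emitted alongside. Every downstream stage is testable with
  no external data.

## Worked example

`examples/04_risk_models.py` simulates a 677-participant validation cohort
at the published covariate marginals with a planted rare variant (control
carrier frequency ≈ 1.2%, odds ratio 16.89) and compares the clinical-only
model against the model with the variant added:

```
clinical only (n=649):
             predictor  aor  ci_low  ci_high      p
             age_years 1.03    1.00     1.06 0.0263
          tobacco_ever 1.71    1.20     2.46 0.0032
      dm_on_medication 0.49    0.33     0.73 0.0004
  ...
  Nagelkerke R2 = 0.064   AUC = 0.63 (95% CI 0.58, 0.67)

clinical + variant (n=649):
          gt_osbpl7_01 13.25    5.14    34.15 0.0000
  ...
  Nagelkerke R2 = 0.158   AUC = 0.68 (95% CI 0.64, 0.72)

delta Nagelkerke R2 from adding the variant: 0.094
variant x tobacco multiplicative interaction Wald p = 0.998
```

The adjusted OR of 13.25 is one draw around the planted 16.89; adding the
variant lifts the explained variance by ~0.09 and the AUC by 0.05, the
qualitative signature of a strong rare risk variant on top of modest
clinical predictors. The other examples cover cohort simulation (01), the
prioritization cascade with its per-stage audit (02), univariable tables
(03), and power curves (05).

A thin CLI wraps the same functions and writes JSON run manifests:

```bash
fhpanel simulate --mode cohort --seed 3 --out-dir run/
fhpanel associate --cohort run/cohort.csv --out-dir run/
fhpanel power --rr 1.77 --maf 0.19
```

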