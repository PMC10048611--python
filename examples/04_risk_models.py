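"""Clinical vs clinical+genetic risk models on a simulated validation cohort.

Draws a stochastic 677-participant cohort at the published covariate
marginals with a planted rare frameshift-like variant (control carrier
frequency ~1.2%, odds ratio 16.89), fits the clinical-only model and the
model with the variant added, and reports Nagelkerke R2, AUROC with its
DeLong CI, the variance-explained increment, and an interaction test.
"""

import numpy as np

from fhpanel import riskmodel, synthetic

CLINICAL = ["age_years", "fasting_glucose_mmol_l", "tobacco_ever",
            "dm_on_medication", "famhx_hyperlipidemia"]

gspec = synthetic.GenotypeSpec(maf=0.006, effect_or=16.89)
cohort = synthetic.generate_cohort(
    synthetic.table1_cohort_spec("stochastic", seed=7, genotypes={"osbpl7_01": gspec})
)
X = riskmodel.encode_predictors(cohort, CLINICAL + ["gt_osbpl7_01"])
y = riskmodel.outcome_vector(cohort)

base, plus = riskmodel.fit_nested(X, y, CLINICAL, ["gt_osbpl7_01"])
for label, fit in (("clinical only", base), ("clinical + variant", plus)):
    s = riskmodel.model_summary(fit)
    print(f"\n{label} (n={s['n']}):")
    print(s["terms"].assign(
        aor=s["terms"].aor.round(2), ci_low=s["terms"].ci_low.round(2),
        ci_high=s["terms"].ci_high.round(2), p=s["terms"].p.round(4),
    ).to_string(index=False))
    print(f"  Nagelkerke R2 = {s['nagelkerke_r2']:.3f}   "
          f"AUC = {s['auc']:.2f} (95% CI {s['auc_ci95'][0]:.2f}, {s['auc_ci95'][1]:.2f})")

print(f"\ndelta Nagelkerke R2 from adding the variant: "
      f"{riskmodel.delta_r2(base, plus):.3f}")
p_int = riskmodel.interaction_test(X, y, "gt_osbpl7_01", "tobacco_ever",
                                   adjusters=CLINICAL)
print(f"variant x tobacco multiplicative interaction Wald p = {p_int:.3f}")
print("\nA positive R2 increment with an adjusted OR near the planted 16.89 is")
print("expected; no interaction was simulated, so its p should be unremarkable.")
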