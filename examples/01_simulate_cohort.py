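"""Generate the validation cohort with exact printed marginals.

Builds the 677-participant case-control table (338 high-LDL cases vs 339
low-LDL controls) in exact mode, where every binary covariate reproduces
its published 2x2 cell counts bit-for-bit, then prints a few marginals.
"""

from fhpanel import synthetic

cohort = synthetic.generate_cohort(synthetic.table1_cohort_spec("exact", seed=0))

print(f"participants: {len(cohort)}  "
      f"(HLDL {int((cohort.group == 'HLDL').sum())}, "
      f"LLDL {int((cohort.group == 'LLDL').sum())})")
for col in ("tobacco_ever", "dm_on_medication", "famhx_hyperlipidemia"):
    case = cohort[cohort.group == "HLDL"][col]
    ctrl = cohort[cohort.group == "LLDL"][col]
    print(f"{col:24s} cases yes/no/missing = "
          f"{int((case=='yes').sum())}/{int((case=='no').sum())}/{int((case=='').sum())}"
          f"   controls = "
          f"{int((ctrl=='yes').sum())}/{int((ctrl=='no').sum())}/{int((ctrl=='').sum())}")
print("\nEach yes/no pair matches the published univariable table exactly;")
print("missing cells reproduce its varying per-covariate denominators.")
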