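"""Genetic sample-size calculation under the additive allele-based design.

Computes the per-group n required for 80% power at alpha 0.05 across a
grid of genetic risk ratios, including the two anchor designs (a strong
rare variant, RR 14.78 at MAF 0.0056, and a weak common one, RR 1.77 at
MAF 0.190), and verifies one result by simulation.
"""

from fhpanel.powercalc import PowerSpec, required_n, simulate_power

print("per-group n for 80% power, alpha 0.05, MAF 0.19 (additive, perfect LD):")
for rr in (1.2, 1.5, 1.77, 2.5, 4.0, 8.0):
    print(f"  RR {rr:5.2f}  ->  n = {required_n(PowerSpec(rr, maf=0.19))}")

strong = PowerSpec(genetic_risk_ratio=14.78, maf=0.0056)
weak = PowerSpec(genetic_risk_ratio=1.77, maf=0.190)
n_strong, n_weak = required_n(strong), required_n(weak)
print(f"\nanchor designs: strong rare variant n = {n_strong}, "
      f"weak common variant n = {n_weak}")
power = simulate_power(weak, n_weak, n_reps=2000, seed=1)
print(f"simulated power at n = {n_weak}: {power:.1%} (target 80%)")
print("\nLarger effects need far fewer samples; the simulation confirms the")
print("closed-form n delivers the target power for the allele-based test.")
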