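"""Equilibrium hydrogen pressure from the cell's NADH/NAD+ poise.

For a non-bifurcating NADH-dependent hydrogenase (NADH + H+ <-> NAD+ + H2)
the highest hydrogen partial pressure the enzyme can reach is set by the
Nernst equilibrium between the NAD+/NADH and 2H+/H2 couples. This prints
the predicted ceiling for the three assayed ratios, and inverts the
relation for the hydrogen window observed in syntrophic cultures.
"""

from hydbeta import Conditions, equilibrium_h2_pressure, ratio_for_pressure

conditions = Conditions(temperature_K=298.15, pH=7.5)

print("Predicted equilibrium hydrogen partial pressure (pH 7.5, 25 C):")
for ratio in (5.0, 1.0, 0.2):
    res = equilibrium_h2_pressure(ratio, conditions)
    print(f"  NADH/NAD+ = {ratio:>4}  ->  p(H2) = {res.p_h2_Pa:7.2f} Pa"
          f"   (couple potential {res.E_couple_mV:.1f} mV)")

print()
print("NADH/NAD+ ratios implied by culture hydrogen pressures 5.9-36.6 Pa:")
lo = ratio_for_pressure(5.9, conditions)
hi = ratio_for_pressure(36.6, conditions)
print(f"  {lo:.2f} to {hi:.2f}")
print()
print("Reading: hydrogen production from NADH alone only stays favourable at")
print("tens of pascals, which is why these organisms need a hydrogen-consuming")
print("partner; ratios above ~1 suffice to explain the observed pressures.")
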