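"""Worked biochemistry arithmetic around an enzyme purification.

Predicted masses from sequence, spectrophotometric specific activities,
purification fold/yield, and per-subcomplex stoichiometry conversions.
"""

from hydbeta import (
    AssayMeasurement,
    PurificationStep,
    per_subcomplex,
    protein_mass_kda,
    purification_stats,
    specific_activity,
    theoretical_pi,
)

tag = "MGSSHHHHHHSQDPNSSSARL"
print(f"His-tag peptide {tag}:")
print(f"  predicted mass {protein_mass_kda(tag):.2f} kDa, pI {theoretical_pi(tag):.2f}")

print()
print("NAD+ reduction followed at 340 nm (epsilon 6.2 /mM/cm):")
m = AssayMeasurement(delta_A_per_min=0.62, epsilon_mM_cm=6.2, path_cm=1.0,
                     volume_ml=1.0, protein_mg=0.1)
print(f"  specific activity {specific_activity(m):.2f} U/mg  (U = umol/min)")

print()
print("Toy purification table (fold and yield are relative to the load):")
steps = [
    PurificationStep("cell extract", 100.0, 50.0),
    PurificationStep("Ni eluate", 1.0, 31.0),
]
for row in purification_stats(steps):
    print(f"  {row['name']:>12}: {row['specific_activity']:5.2f} U/mg, "
          f"{row['fold']:.1f}-fold, {row['yield_pct']:.0f}% yield")

print()
print("Iron per complex vs per subcomplex:")
print(f"  71.7 Fe per alpha2beta2 heterotetramer -> "
      f"{per_subcomplex(71.7, 2, ndigits=1)} per alpha-beta heterodimer")
print(f"  1.06 FMN per heterotetramer -> {per_subcomplex(1.06, 2):.2f} per heterodimer")
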