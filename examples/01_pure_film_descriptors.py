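"""Characterize a pure lipid film: modulus, state, characteristic points.

Generates a brain-sphingomyelin-like compression run with realistic
instrument noise and extracts everything a film-balance study reports
for a single isotherm.
"""

from monothermo import describe, pure_preset, simulate_pure_isotherm

iso = simulate_pure_isotherm(
    pure_preset("sm-brain"),
    noise=(0.05, 1.0),  # pi noise (mN/m), replicate area offset (A^2)
    seed=42,
    components=(("SM_brain", 1.0),),
)
d = describe(iso, noise_sigma=0.05)

print(f"lift-off area      {d.lift_off_area:7.1f}  A^2/molecule")
print(f"limiting area      {d.limiting_area:7.1f}  A^2/molecule")
print(f"collapse pressure  {d.collapse_pressure:7.1f}  mN/m ({d.collapse_mode})")
print(f"Cs^-1 max          {d.cs_max:7.0f}  mN/m at {d.cs_max_pressure:.1f} mN/m")
print(f"physical state     {d.state:>7s}")
print(f"transitions        {[round(t, 1) for t in d.transitions]}  mN/m")

# The film lifts off near 91 A^2, runs through a liquid-expanded ->
# liquid-condensed transition plateau near 5 mN/m, reaches a modulus
# maximum around 150 mN/m (liquid-condensed) and collapses at 69 mN/m.
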