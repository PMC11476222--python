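"""Compute theoretical deprotonated-ion m/z and isotope patterns for
ganglioside species written in shorthand nomenclature.

The m/z values printed here are what a negative-mode Orbitrap should show
for these ions; the ppm column is the deviation you would report if the
instrument read the second value.
"""

from gangliotk import (
    adduct_mz,
    isotope_pattern,
    parse_ion,
    ppm_error,
    species_neutral_mass,
)

ions = [
    "GM3(d18:1_18:0)-H",       # monosialo, singly deprotonated
    "GD2(d18:1_18:0)-2H",      # disialo, doubly deprotonated
    "GM1(d18:1_16:0)-H",
    "Hex1Cer(d17:0_18:2+2O)-H",  # hydroxylated acyl (+2O modifier)
]

print(f"{'ion':30s} {'neutral M':>12s} {'m/z':>10s}")
for name in ions:
    species, adduct = parse_ion(name)
    neutral = species_neutral_mass(species)
    mz = adduct_mz(neutral, adduct)
    print(f"{name:30s} {neutral:12.4f} {mz:10.4f}")

# mass accuracy of a hypothetical observation, in ppm
species, adduct = parse_ion("GM1(d18:1_16:0)-H")
theo = adduct_mz(species_neutral_mass(species), adduct)
obs = 1516.8451
print(f"\nobserved {obs} vs theoretical {theo:.4f}: "
      f"{ppm_error(theo, obs):.1f} ppm")

# isotope envelope of the GM1 ion (first four peaks, charge 1-)
pat = isotope_pattern(species.composition)
print("\nGM1(d18:1_16:0) [M-H]- isotope envelope (m/z, rel. abundance):")
for mz, ab in pat.mz_peaks(1)[:4]:
    print(f"  {mz:10.4f}  {ab:6.3f}")
print("Peaks are ~1.0034 m/z apart at charge 1; the A+1 peak is large "
      "because the molecule carries ~70 carbons.")
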