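# gangliotk

Targeted quantitation of gangliosides and other sphingolipids from
negative-mode LC-MS runs.

Gangliosides — glycosphingolipids carrying one or more sialic acids on a
glycan headgroup attached to a ceramide — are profiled by extracting ion
chromatograms for theoretically predicted ions from high-resolution
centroided runs. This package implements the full in-silico side of such a
workflow for analytical chemists and lipidomics groups:

- **Nomenclature & chemistry** — parse shorthand species names like
  `GM3(d18:1_18:0)` or `Hex1Cer(d17:0_18:2+2O)`, assemble exact elemental
  compositions from a ganglioside-class glycan registry (derived from the
  biosynthesis pathway: GM/GD/GT/GQ carry 1/2/3/4 NeuAc), and compute
  monoisotopic masses, aggregated isotope distributions and deprotonated-ion
  m/z values ([M−H]⁻, [M−2H]²⁻).
- **Target databases** — enumerate species × ceramide-variant × charge-state
  targets inside the 500–2000 m/z acquisition window; match observed m/z at
  ppm tolerance.
- **XIC engine** — read centroided mzML, extract 10 ppm ion chromatograms,
  detect and trapezoid-integrate elution peaks, and verify isotope envelopes
  by cosine similarity.
- **Quantitation** — internal-standard calibration (OLS or 1/x-weighted),
  ICH-style LOD/LOQ (3.3·s_y/slope, 10·s_y/slope), percent recovery, and
  percent relative abundance per species with replicate statistics.
- **Post-filtering** — clean identification-software exports with the
  inclusion criteria RT > 2 min, area > 1000, score < 0.5 (strict).
- **Synthetic fixtures** — simulate centroided runs with Gaussian elution of
  full isotope envelopes plus noise, calibration series, and labeled results
  tables, each with a machine-readable truth record.

## The core computations

For a species of class *G* with sphingoid base *b* (formula
C<sub>c</sub>H<sub>2c+3−2u</sub>NO<sub>h</sub>, h ∈ {1,2,3} for m/d/t) and
fatty acyl *a* (free acid C<sub>c'</sub>H<sub>2c'−2u'</sub>O<sub>2+x</sub>),
the neutral composition is

    M(G, b, a) = b + a − H2O + n_Hex·C6H10O5 + n_HexNAc·C8H13NO5
                 + n_NeuAc·C11H17NO8 (+ HPO3 / SO3)

with residue counts taken from the class registry. Ion m/z follows the
proton-subtraction convention

    m/z = (M − n·1.00727646) / n        for [M−nH]ⁿ⁻,

with an optional H-atom (1.0078250) convention for matching legacy outputs.
Mass accuracy is reported as ppm = 10⁶·|obs − theo|/theo. Isotope envelopes
are aggregated by nominal mass shift (A, A+1, …) via per-element multinomial
convolution, with abundance-weighted centroid masses and spacing 1.003355/n
on the ion axis.

## Worked example

```python
from gangliotk import parse_ion, species_neutral_mass, adduct_mz, ppm_error

species, adduct = parse_ion("GM1(d18:1_16:0)-H")
mz = adduct_mz(species_neutral_mass(species), adduct)
print(f"{mz:.4f}")                          # 1516.8381
print(round(ppm_error(mz, 1516.8451), 1))   # 4.6
```

The first number is the theoretical m/z of singly deprotonated
GM1(d18:1/16:0) — ceramide d18:1/16:0 plus three hexoses, one HexNAc and
one NeuAc, minus one proton. The second says an instrument reading
1516.8451 for this ion is 4.6 ppm high, comfortably inside a 10 ppm
extraction window.

The `examples/` directory contains one short script per capability
(theoretical m/z, target enumeration, XIC extraction and integration,
calibration/LOD/LOQ/recovery, results filtering, and the full pipeline),
each printing the numbers it computes and what they mean. A thin CLI mirrors
the stages:

```bash
gangliotk build-db --classes GM3,GM1,GD1 --acyl-range 16 20 -o targets.csv
gangliotk simulate --seed 5 -o run.mzML --truth truth.tsv
gangliotk extract --mzml run.mzML --targets targets.csv -o areas.tsv
gangliotk filter --in areas.tsv -o filtered.tsv
gangliotk profile --areas filtered.tsv -o profile.tsv
```

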