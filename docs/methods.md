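# Methods

This note documents the models, conventions and defaults behind gangliotk,
the choices made where the design was genuinely open, and what the synthetic
fixtures do and do not establish about real data.

## Composition assembly and mass conventions

Species are assembled from three parts: a sphingoid base
C_c H_(2c+3−2u) N O_h (h = 1/2/3 for the m/d/t hydroxylation prefixes), a
fatty acyl written as its free acid C_c' H_(2c'−2u') O_(2+x) (the `+xO`
shorthand adds hydroxylations as bare oxygens, without committing to their
positions), and a glycan headgroup. The amide condensation removes one
water; glycan residues enter as condensed (anhydro) units — Hex C6H10O5,
HexNAc C8H13NO5, NeuAc C11H17NO8 — so no further water bookkeeping is
needed. Phosphate (HPO3) and sulfate (SO3) enter as substituents. The class
→ residue-count registry is data (`data/ganglioside_classes.tsv`), editable
without code changes; it encodes the biosynthesis-pathway arithmetic
(GM2 = GM3 + HexNAc, GM1 = GM2 + Hex, GD/GT/GQ add NeuAc, GA is the asialo
series), which the tests verify as exact mass identities.

Atomic masses and isotope abundances come from a bundled CODATA/IUPAC table
(`data/atomic_masses.tsv`), versioned with the package so results are
reproducible offline and do not drift with external libraries.

Deprotonated-ion m/z uses the electron-corrected proton mass,
m/z = (M − n·1.00727646)/n. Published ion tables are not uniform here: some
subtract H-atom masses (1.0078250) instead, a ~0.7 mDa/charge difference
(≤ 1 ppm above ~750 m/z). The proton convention is the physically correct
default; `convention="hydrogen"` is available for byte-matching legacy
outputs, and reference-value tests assert agreement within 1 ppm under
*either* convention rather than adjudicating the source's mixture.

`ppm_error` returns the absolute value; the sign (instrument reading high
vs low) is deliberately not preserved, matching how mass-accuracy columns
are usually reported.

Linkage isomers (GD1a/GD1b, GT1a/b/c, GQ1b/c) have identical compositions;
the registry resolves their names to one composition class and carries
elution-order notes (GD1a before GD1b on ZIC-HILIC) as annotation only.
The deuterated internal standard GM1-d3 is modeled as a protium→deuterium
swap on the composition (`GM1-d3(...)` in the grammar), shifting the mass by
3 × 1.00628 Da.

## Isotope distributions

Envelopes are computed by per-element multinomial convolution
(exponentiation-by-squaring of the one-atom distribution), binned by
nominal mass shift (A, A+1, A+2, …) with abundance-weighted centroid
masses. Fine structure inside a bin (e.g. ¹³C₂ vs ¹⁸O) is deliberately not
resolved — at the 120k resolution these lipids are acquired with, bins are
what the instrument sees. Abundances are normalized to the base peak;
peaks below 1e-4 of it are truncated by default. During convolution, terms
below 1e-15 are pruned; this perturbs centroid masses of sub-ppb bins by
~1e-8 Da and abundances by < 1e-15, far below anything reportable. On the
ion axis the spacing is 1.003355/n for charge n. Correctness is established
against exhaustive isotopologue enumeration on small formulas (≤ 12 atoms)
to 1e-9 in abundance.

## Target enumeration and matching

The default sweep uses bases {d18:1, d18:0, d17:0, t18:0, m17:1}, acyl
carbons 12–26 with 0–2 double bonds, and charge states by sialylation:
−H for neutral/monosialo classes, −H and −2H for classes with ≥ 2 NeuAc
(doubly deprotonated ions are only abundant for multiply sialylated
species). Ions outside the 500–2000 m/z acquisition window are dropped.
These ranges are this package's choice of a panel wide enough to cover
commonly printed species tables while staying small; they are config, not
chemistry. Matching applies the ppm tolerance on the ion m/z (instrument
semantics), sorted by ppm error with ties broken toward fewer sialic acids
then name — when an observed mass is equidistant from a simpler and a more
decorated candidate, the simpler explanation ranks first.

A caveat inherent to targeted sweeps: enumerated variants one double bond
apart differ by 2 H (≈ 2.016 Da), which at high m/z falls within 10 ppm of
another variant's A+2 isotope peak; such targets can pick up a neighbor's
envelope with a depressed isotope score (~0.85–0.95). The isotope-score
threshold (default 0.7) removes cases where the envelope clearly disagrees;
genuinely resolving such interference requires chromatographic separation
or narrower tolerance, not arithmetic.

## XIC extraction, peak picking, integration

XICs sum centroid intensities within |Δm/z|/m/z ≤ tol·1e-6 per MS1 scan,
zero-filled where nothing falls in the window, so every trace has one point
per scan. Peak detection finds local maxima above a height floor and walks
outward to where the trace falls to 1% of the apex or to a local minimum
between neighboring peaks (peaks never overlap). Integration is trapezoidal
over the detected bounds; for a Gaussian sampled at σ/10 this loses only
the tails beyond ~3σ, ≈ 0.25% of the area. Only centroided MS1 input is
accepted; profile-mode spectra raise an error, since the method operates on
detected ion m/z values. Retention times are minutes everywhere (mzML scan
times in seconds are converted on read).

When a target's RT window contains several peaks, the most intense
candidate that clears the isotope-score threshold is quantified, with all
candidates reported for audit — the manual judgment of a "true" analyte
peak operationalized as max-area-plus-envelope-agreement. Isotope scoring
is the cosine between theoretical abundances and apex-scan intensities read
at each isotope m/z position with the same ppm tolerance.

## mzML I/O

The reader is a compact built-in mzML parser (streaming ElementTree +
base64/zlib decoding of 32/64-bit float arrays, plain or indexed files).
The writer emits plain mzML with uncompressed 64-bit arrays and the CV
terms readers need. Round-trips are bit-exact, and the test suite
cross-checks the written format against Bioconductor's mzR as an
independent reader.

## Calibration, LOD/LOQ, recovery, profiles

Calibration regresses the response ratio (analyte area / internal-standard
area) on concentration. Unweighted OLS is the default; 1/x weighting is
available for series whose scatter grows with concentration. The default
design is the six-level series 30/100/300/500/700/1000 ng/µL. LOD and LOQ
use the ICH residual-scatter convention, 3.3·s_y/slope and 10·s_y/slope
with s_y = √(SS_res/(n−2)); R² is computed on unweighted residuals in both
modes. Percent recovery is 100·measured/spiked, summarized as mean ± sd
(ddof = 1) across replicates. Relative abundance is per-replicate
area / total area × 100 (summing to 100 per replicate by construction),
reported as mean ± sd across replicates, ranked descending; percentages are
stored at full precision and rendered at 1–3 decimals.

## Post-search filtering

Inclusion criteria are strict inequalities — RT **>** 2 min, area **>**
1000, score **<** 0.5 — because the defining wording is "more than /
greater than / less than"; rows exactly on a threshold are removed, and
dedicated boundary tests pin this down. The score column is treated as a
generic keep-if-smaller identification score with a configurable column
name, since the exporting software's internal score definition is
proprietary. Filtering is pure (input table untouched) and emits a
machine-readable report of rows removed per criterion. Adduct restriction
keeps −H/−2H rows, removes other recognizable adduct tokens (+H, +HCOO, …),
and sets aside unparseable strings as flagged rows rather than silently
dropping them.

## Synthetic fixtures and what they show

`simulate_run` places each species' isotope envelope (first four peaks,
charge-scaled spacing, rescaled so the *monoisotopic* trace carries the
nominal apex intensity) on a Gaussian elution profile over a 25 min run of
0.01 min MS1 scans, with optional additive baseline centroids, fractional
multiplicative intensity scatter, and ppm-scale mass jitter; all randomness
flows from one seeded generator and identical config + seed reproduces the
run exactly. The analytic Gaussian area, apex·σ·√(2π), is recorded per
species in a truth table, and all downstream accuracy tests compare against
that truth rather than hard-coded numbers. The default fixture panel
mirrors a concordant printed species set (hexosylceramides through GT1)
with GD1 present as two RT-separated isomer peaks at one m/z, the earlier
one more intense.

What passing fixture tests establish: the extraction/integration/profile
arithmetic is correct to ≤ 2% under clean Gaussian elution, and the filter
logic implements its criteria exactly. What they do not establish: behavior
under chromatographic tailing, co-elution, carryover, detector saturation
or matrix interference — none of which the simulator models. Published
run-level outcomes that depend on real acquisitions (calibration R² ranges,
identification counts, cell-line profiles) are therefore covered by
property-based substitutes (noiseless R² = 1, Monte-Carlo slope recovery,
end-to-end truth recovery), not by reproduction.

## Problem sizes and numerical choices

Tests run the simulator at scan intervals of σ/10 (0.005 min) over 18–25
min runs (~3600–5000 scans, ≤ 10 species), where integration error is
dominated by the 1%-of-apex bounds (~0.25%), and use 300–1000 Monte-Carlo
calibration fits — sizes chosen so the whole suite stays interactive while
estimates sit well inside their asserted bands. Degenerate inputs fail
loudly rather than silently: empty runs, inverted integration bounds,
zero-spread calibration designs, all-zero replicates, unknown element
symbols and malformed names all raise with specific messages. Chain lengths
outside 12–26 carbons warn but do not error (odd standards occur); bulk
enumeration suppresses that warning internally.

## Known limitations

- No cross-run retention-time alignment; multi-replicate profiles join on
  species name.
- No MS2/AIF interpretation; identification confidence beyond the isotope
  score must come from upstream software.
- Positive-mode adducts, in-source fragments and fine-structure isotopes
  are out of scope.
- The isobaric-variant interference described above is inherent to
  ppm-window extraction over dense target sweeps.
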