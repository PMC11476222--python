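"""Simulate a centroided negative-mode run, write/read it as mzML, extract
a 10 ppm ion chromatogram and integrate the elution peak.

The simulated species elutes as a Gaussian, so the analytic area
(apex * sigma * sqrt(2*pi)) is known exactly and the trapezoidal estimate
can be judged against it.
"""

import tempfile
from pathlib import Path

from gangliotk import detect_peaks, extract_xic, isotope_score
from gangliotk.mzml_io import read_mzml, write_mzml
from gangliotk.simulate import SimConfig, default_panel, simulate_run

cfg = SimConfig(species=default_panel()[:4], scan_interval=0.005, seed=42)
run, truth = simulate_run(cfg)
print(f"simulated {len(run)} scans, {len(truth)} species")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "run.mzML"
    write_mzml(run, path)
    run = read_mzml(path)  # same run, via the open interchange format

sim = cfg.species[2]  # GM3(d18:1_18:0)-H
target = sim.target()
xic = extract_xic(run, target.theoretical_mz, tolerance_ppm=10.0)
peaks = detect_peaks(xic, min_height=100.0)
peak = peaks[0]
peak.isotope_score = isotope_score(run, target, peak)

rel_err = abs(peak.area - sim.true_area) / sim.true_area
print(f"\n{target.name}: XIC at m/z {target.theoretical_mz:.4f}")
print(f"  apex RT   {peak.apex_rt:.3f} min (injected {sim.true_rt})")
print(f"  area      {peak.area:.0f} (analytic {sim.true_area:.0f}, "
      f"{100 * rel_err:.2f}% off)")
print(f"  isotope score {peak.isotope_score:.4f} "
      "(1.0 = envelope exactly proportional to theory)")
print("Trapezoidal integration over 1%-of-apex bounds loses only the far "
      "Gaussian tails, hence the sub-percent area error.")
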