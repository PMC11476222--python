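"""XIC extraction, peak detection, integration, isotope scoring."""

import numpy as np
import pytest

from gangliotk.chem import ADDUCT_H
from gangliotk.nomenclature import parse_species
from gangliotk.simulate import SimConfig, SimSpecies, simulate_run
from gangliotk.targets import make_target
from gangliotk.xic import (
    Chromatogram,
    Peak,
    SpectrumRun,
    detect_peaks,
    extract_xic,
    integrate_peak,
    isotope_score,
    quantify_target,
)


def run_with_single_centroid(mz, intensity, rt=5.0):
    spectra = [
        (rt - 0.1, np.array([]), np.array([])),
        (rt, np.array([mz]), np.array([intensity])),
        (rt + 0.1, np.array([]), np.array([])),
    ]
    return SpectrumRun(spectra=spectra)


def test_extract_exact_centroid():
    run = run_with_single_centroid(1000.0, 5.0e4)
    xic = extract_xic(run, 1000.0, 10.0)
    assert list(xic.intensities) == [0.0, 5.0e4, 0.0]
    assert list(xic.rts) == [4.9, 5.0, 5.1]


def test_extract_outside_window_is_zero():
    offset = 1000.0 * (1 + 20e-6)  # 20 ppm high
    run = run_with_single_centroid(offset, 5.0e4)
    xic = extract_xic(run, 1000.0, 10.0)
    assert xic.intensities.sum() == 0.0


def test_extract_validates_inputs():
    run = run_with_single_centroid(1000.0, 1.0)
    with pytest.raises(ValueError):
        extract_xic(run, 1000.0, 0.0)
    with pytest.raises(ValueError):
        extract_xic(SpectrumRun(spectra=[]), 1000.0, 10.0)


def test_run_rts_must_increase():
    with pytest.raises(ValueError, match="strictly increase"):
        SpectrumRun(spectra=[
            (1.0, np.array([500.0]), np.array([1.0])),
            (1.0, np.array([500.0]), np.array([1.0])),
        ])


def test_xic_matches_injected_profile(clean_run):
    """Fixture bookkeeping oracle: in a noise-free simulated run the XIC of
    a species equals its injected Gaussian profile exactly (floor aside)."""
    run, truth, cfg = clean_run
    row = truth.iloc[2]  # GM3
    s = cfg.species[2]
    xic = extract_xic(run, row.theoretical_mz, 10.0)
    expected = s.apex_intensity * np.exp(
        -0.5 * ((xic.rts - s.true_rt) / s.rt_sigma) ** 2
    )
    expected[expected < cfg.intensity_floor] = 0.0
    assert np.allclose(xic.intensities, expected, rtol=1e-12)


def test_detect_flat_trace_empty():
    xic = Chromatogram(
        rts=np.linspace(0, 10, 100), intensities=np.zeros(100),
        mz=1000.0, tolerance_ppm=10.0,
    )
    assert detect_peaks(xic) == []


def test_detect_single_gaussian(single_gaussian_xic):
    xic, true_area, center, sigma = single_gaussian_xic
    peaks = detect_peaks(xic, min_height=100.0)
    assert len(peaks) == 1
    p = peaks[0]
    assert abs(p.apex_rt - center) <= sigma / 10  # within one scan
    assert p.left_rt < p.apex_rt < p.right_rt
    assert p.height == pytest.approx(xic.intensities.max())


def test_detect_two_gaussians_ordered():
    rts = np.arange(0.0, 10.0, 0.01)
    y = (1e6 * np.exp(-0.5 * ((rts - 4.0) / 0.05) ** 2)
         + 5e5 * np.exp(-0.5 * ((rts - 5.0) / 0.05) ** 2))
    xic = Chromatogram(rts=rts, intensities=y, mz=1000.0, tolerance_ppm=10.0)
    peaks = detect_peaks(xic, min_height=1000.0)
    assert len(peaks) == 2
    assert peaks[0].apex_rt == pytest.approx(4.0, abs=0.01)
    assert peaks[1].apex_rt == pytest.approx(5.0, abs=0.01)
    assert peaks[0].right_rt <= peaks[1].left_rt  # non-overlapping


def test_integrate_triangle_analytic():
    rts = np.array([0.0, 0.5, 1.0])
    y = np.array([0.0, 100.0, 0.0])
    xic = Chromatogram(rts=rts, intensities=y, mz=1000.0, tolerance_ppm=10.0)
    # triangle of height h over width w has area h*w/2
    assert integrate_peak(xic, (0.0, 1.0)) == pytest.approx(50.0)


def test_integrate_gaussian_within_one_percent(single_gaussian_xic):
    xic, true_area, center, sigma = single_gaussian_xic
    peaks = detect_peaks(xic, min_height=100.0)
    assert abs(peaks[0].area - true_area) / true_area < 0.01


def test_integrate_zero_trace_and_inverted_bounds():
    rts = np.linspace(0, 1, 11)
    xic = Chromatogram(rts=rts, intensities=np.zeros(11), mz=1000.0,
                       tolerance_ppm=10.0)
    assert integrate_peak(xic, (0.0, 1.0)) == 0.0
    with pytest.raises(ValueError, match="inverted"):
        integrate_peak(xic, (1.0, 0.0))


def test_xic_linearity(clean_run):
    run, truth, _ = clean_run
    mz = truth.iloc[0].theoretical_mz
    xic = extract_xic(run, mz, 10.0)
    scaled = SpectrumRun(
        spectra=[(rt, m, 3.0 * i) for rt, m, i in run.spectra]
    )
    xic3 = extract_xic(scaled, mz, 10.0)
    assert np.allclose(xic3.intensities, 3.0 * xic.intensities)


def test_tolerance_monotonicity(clean_run):
    run, truth, _ = clean_run
    mz = truth.iloc[4].theoretical_mz
    narrow = extract_xic(run, mz, 5.0).intensities
    wide = extract_xic(run, mz, 10.0).intensities
    assert np.all(wide >= narrow)


def _peak_at(rt):
    return Peak(apex_rt=rt, left_rt=rt - 0.2, right_rt=rt + 0.2,
                area=1.0, height=1.0)


def test_isotope_score_closed_forms():
    target = make_target(parse_species("GM3(d18:1_18:0)"), ADDUCT_H)
    iso = target.isotope_mz_peaks()
    theo = np.array([a for _, a in iso])
    rt = 5.0

    def run_with(obs_intensities):
        mzs = np.array([m for m, _ in iso])
        keep = obs_intensities > 0
        return SpectrumRun(spectra=[(rt, mzs[keep], obs_intensities[keep])])

    # proportional envelope -> exactly parallel vectors
    prop = run_with(theo * 7.5e4)
    assert isotope_score(prop, target, _peak_at(rt)) == pytest.approx(1.0)
    # only the monoisotopic peak present -> ab1/||ab||
    mono = np.zeros_like(theo)
    mono[0] = 1e5
    score = isotope_score(run_with(mono), target, _peak_at(rt))
    assert score == pytest.approx(theo[0] / np.linalg.norm(theo), abs=1e-12)
    # signal only at A+1 -> ab2/||ab||
    a1 = np.zeros_like(theo)
    a1[1] = 1e5
    score = isotope_score(run_with(a1), target, _peak_at(rt))
    assert score == pytest.approx(theo[1] / np.linalg.norm(theo), abs=1e-12)
    # no signal at all -> 0
    empty = SpectrumRun(spectra=[(rt, np.array([]), np.array([]))])
    assert isotope_score(empty, target, _peak_at(rt)) == 0.0


def test_end_to_end_on_fixture(clean_run):
    """Apex within one scan of truth and area within 2% for every injected
    species, at noise-free settings."""
    run, truth, cfg = clean_run
    scan = cfg.scan_interval
    for s in cfg.species:
        _, cands = quantify_target(run, s.target())
        best = min(cands, key=lambda c: abs(c.apex_rt - s.true_rt))
        assert abs(best.apex_rt - s.true_rt) <= scan + 1e-12
        assert abs(best.area - s.true_area) / s.true_area <= 0.02


def test_quantify_picks_most_intense_in_window(clean_run):
    run, truth, cfg = clean_run
    # GD1 has two isomer peaks at one m/z; max-area candidate is selected
    gd1 = [s for s in cfg.species
           if s.species.class_name == "GD1"]
    best, cands = quantify_target(run, gd1[0].target())
    assert len(cands) == 2
    assert best.area == max(c.area for c in cands)
    assert best.apex_rt == pytest.approx(13.0, abs=0.01)  # earlier = larger
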