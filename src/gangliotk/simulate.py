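"""Synthetic fixtures: centroided negative-mode runs, calibration series,
and LipidSearch-style result tables, each with a machine-readable truth
record.

The run simulator places each species' isotope envelope (charge-scaled
spacing) on a Gaussian elution profile and writes centroided MS1 scans,
emulating a 25 min negative-mode acquisition over 500-2000 m/z.  The
analytic area of a Gaussian elution profile,

    true_area = apex_intensity * rt_sigma * sqrt(2*pi),

is recorded in the truth table and serves as the oracle for extraction and
integration accuracy.  All randomness flows from a single seeded generator,
so identical config + seed reproduces the run exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import AdductIon, adduct_mz
from .nomenclature import LipidSpecies, parse_species, render_species
from .targets import TargetEntry, make_target
from .xic import SpectrumRun

__all__ = [
    "SimSpecies",
    "SimConfig",
    "simulate_run",
    "simulate_calibration",
    "simulate_results_table",
    "default_panel",
    "CALIBRATION_LEVELS",
]

#: Default calibration design, ng/uL (six standard levels).
CALIBRATION_LEVELS = (30.0, 100.0, 300.0, 500.0, 700.0, 1000.0)

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class SimSpecies:
    """One species injected into a simulated run."""

    species: LipidSpecies
    adduct: AdductIon
    true_rt: float          # minutes
    rt_sigma: float         # minutes
    apex_intensity: float   # counts
    concentration: float = 0.0  # ng/uL, carried through to truth table

    @property
    def true_area(self) -> float:
        """Analytic area of the Gaussian elution profile."""
        return self.apex_intensity * self.rt_sigma * SQRT_2PI

    def target(self) -> TargetEntry:
        return make_target(self.species, self.adduct)


@dataclass
class SimConfig:
    """Acquisition + noise model for a simulated run.

    Noise defaults emulate a quiet Orbitrap MS1 trace: a sparse additive
    baseline of low-intensity chemical-noise centroids, a few percent
    multiplicative scan-to-scan intensity scatter, and ~1 ppm mass jitter.
    Set the three noise fields to zero for exact-bookkeeping fixtures.
    """

    species: list[SimSpecies] = field(default_factory=list)
    run_length: float = 25.0      # minutes (matches the LC runtime)
    scan_interval: float = 0.01   # minutes between MS1 scans
    mz_range: tuple[float, float] = (500.0, 2000.0)
    baseline_mean: float = 0.0    # mean intensity of additive noise centroids
    baseline_peaks_per_scan: int = 20
    multiplicative_sd: float = 0.0  # fractional intensity scatter
    mass_error_ppm_sd: float = 0.0
    intensity_floor: float = 1.0  # centroids below this are not written
    seed: int = 0


def simulate_run(
    cfg: SimConfig, mzml_path: str | Path | None = None
) -> tuple[SpectrumRun, pd.DataFrame]:
    """Simulate a centroided run; optionally write it as mzML.

    Returns (run, truth) where ``truth`` has one row per injected species:
    name, adduct, charge, theoretical m/z, true RT/sigma/apex/area and
    concentration.
    """
    if cfg.scan_interval <= 0:
        raise ValueError("scan interval must be positive")
    if cfg.run_length <= 0:
        raise ValueError("run length must be positive")
    rng = np.random.default_rng(cfg.seed)
    targets = [s.target() for s in cfg.species]
    for s, t in zip(cfg.species, targets):
        if not (cfg.mz_range[0] <= t.theoretical_mz <= cfg.mz_range[1]):
            raise ValueError(
                f"{t.name} m/z {t.theoretical_mz:.4f} outside scan range"
            )
    rts = np.arange(0.0, cfg.run_length, cfg.scan_interval)
    spectra: list[tuple[float, np.ndarray, np.ndarray]] = []
    for rt in rts:
        mzs: list[float] = []
        intens: list[float] = []
        for s, t in zip(cfg.species, targets):
            g = math.exp(-0.5 * ((rt - s.true_rt) / s.rt_sigma) ** 2)
            scale = s.apex_intensity * g
            if cfg.multiplicative_sd > 0:
                scale *= max(0.0, 1.0 + rng.normal(0.0, cfg.multiplicative_sd))
            if scale < cfg.intensity_floor:
                continue
            # A..A+3 cover >= 99% of the envelope; abundances are rescaled
            # so the *monoisotopic* peak carries apex_intensity exactly —
            # the truth-area oracle refers to the monoisotopic XIC trace.
            iso = t.isotope_mz_peaks()[:4]
            ab0 = iso[0][1]
            for mz, ab in iso:
                inten = scale * ab / ab0
                if inten < cfg.intensity_floor:
                    continue
                if cfg.mass_error_ppm_sd > 0:
                    mz = mz * (1.0 + rng.normal(0.0, cfg.mass_error_ppm_sd)
                               * 1e-6)
                mzs.append(mz)
                intens.append(inten)
        if cfg.baseline_mean > 0 and cfg.baseline_peaks_per_scan > 0:
            n = cfg.baseline_peaks_per_scan
            mzs.extend(rng.uniform(*cfg.mz_range, size=n))
            intens.extend(rng.exponential(cfg.baseline_mean, size=n))
        mz_arr = np.asarray(mzs)
        order = np.argsort(mz_arr)
        spectra.append(
            (float(rt), mz_arr[order], np.asarray(intens)[order])
        )
    run = SpectrumRun(
        spectra=spectra,
        polarity="negative",
        metadata={"simulated": True, "seed": cfg.seed,
                  "scan_interval": cfg.scan_interval},
    )
    truth = pd.DataFrame(
        [
            {
                "species": render_species(s.species),
                "adduct": s.adduct.label,
                "charge": s.adduct.charge,
                "theoretical_mz": t.theoretical_mz,
                "true_rt": s.true_rt,
                "rt_sigma": s.rt_sigma,
                "apex_intensity": s.apex_intensity,
                "true_area": s.true_area,
                "concentration": s.concentration,
            }
            for s, t in zip(cfg.species, targets)
        ]
    )
    if mzml_path is not None:
        from .mzml_io import write_mzml

        write_mzml(run, mzml_path)
    return run, truth


def default_panel(
    apex: float = 1.0e6, rt_sigma: float = 0.05
) -> list[SimSpecies]:
    """A fixture panel mirroring the concordant printed species: the hexosyl
    ceramides and the GM/GD/GT series, with GD1 present as two RT-separated
    linkage isomers at the same m/z (GD1a eluting before GD1b, as on
    ZIC-HILIC).  Intensities descend so relative abundances are distinct."""
    rows = [
        ("Hex1Cer(d17:0_18:2+2O)", "-H", 4.0, 1.00),
        ("Hex2Cer(m17:1_12:0)", "-H", 5.0, 0.80),
        ("GM3(d18:1_18:0)", "-H", 6.0, 0.65),
        ("GM2(d18:1_16:0)", "-H", 7.5, 0.50),
        ("GM1(d18:1_16:0)", "-H", 9.0, 0.40),
        ("GD3(d18:1_16:0)", "-2H", 10.5, 0.30),
        ("GD2(d18:1_18:0)", "-2H", 12.0, 0.25),
        ("GD1(d18:1_20:0)", "-2H", 13.0, 0.15),  # GD1a: earlier isomer
        ("GD1(d18:1_20:0)", "-2H", 14.5, 0.10),  # GD1b: later isomer
        ("GT1(d18:1_18:0)", "-2H", 16.0, 0.08),
    ]
    return [
        SimSpecies(
            species=parse_species(name),
            adduct=AdductIon.from_label(adduct),
            true_rt=rt,
            rt_sigma=rt_sigma,
            apex_intensity=apex * frac,
        )
        for name, adduct, rt, frac in rows
    ]


def simulate_calibration(
    slope: float,
    intercept: float = 0.0,
    sigma: float = 0.0,
    concentrations: tuple[float, ...] = CALIBRATION_LEVELS,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Response ratios slope*c + intercept + N(0, sigma) at each level."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not concentrations:
        raise ValueError("concentration list is empty")
    rng = np.random.default_rng(seed)
    return [
        (c, slope * c + intercept + (rng.normal(0.0, sigma) if sigma else 0.0))
        for c in concentrations
    ]


def simulate_results_table(
    n_true: int, n_false: int, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """A LipidSearch-style results table with labeled true/false rows.

    True rows satisfy all three inclusion criteria (RT > 2 min, area >
    1000, score < 0.5) with margin.  Each false row violates exactly one
    criterion, chosen uniformly; a third of the violations sit exactly on
    the threshold, exercising the strict-inequality boundary.

    Returns (table, labels) with labels[i] True for rows built to survive.
    """
    if n_true < 0 or n_false < 0:
        raise ValueError("row counts must be non-negative")
    rng = np.random.default_rng(seed)
    classes = ["GM3", "GM2", "GM1", "GD3", "GD2", "GD1", "GT1", "Hex1Cer"]
    rows = []
    labels = []

    def draw_good():
        return (
            float(rng.uniform(3.0, 20.0)),            # rt, clear of 2 min
            float(10 ** rng.uniform(3.5, 6.5)),       # area, clear of 1000
            float(rng.uniform(0.02, 0.40)),           # score, clear of 0.5
        )

    for i in range(n_true + n_false):
        rt, area, score = draw_good()
        is_true = i < n_true
        if not is_true:
            crit = rng.integers(0, 3)
            on_boundary = rng.integers(0, 3) == 0
            if crit == 0:
                rt = 2.0 if on_boundary else float(rng.uniform(0.1, 1.99))
            elif crit == 1:
                area = 1000.0 if on_boundary else float(rng.uniform(5.0, 999.0))
            else:
                score = 0.5 if on_boundary else float(rng.uniform(0.51, 3.0))
        cls = classes[int(rng.integers(0, len(classes)))]
        rows.append(
            {
                "lipid_ion": f"{cls}(d18:1_{int(rng.integers(14, 25))}:0)-H",
                "class": cls,
                "adduct": "-H" if rng.random() < 0.7 else "-2H",
                "rt": rt,
                "area": area,
                "score": score,
                "sample": "sim",
                "replicate": 1,
            }
        )
        labels.append(is_true)
    order = rng.permutation(len(rows))
    table = pd.DataFrame([rows[i] for i in order]).reset_index(drop=True)
    labels_arr = np.array([labels[i] for i in order])
    return table, labels_arr
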