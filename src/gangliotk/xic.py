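"""Extracted ion chromatograms: ppm-window extraction, peak detection,
trapezoidal integration, and isotope-envelope verification.

Operates on centroided MS1 spectra only; profile-mode data are rejected at
read time.  Retention times are minutes everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .targets import TargetEntry

__all__ = [
    "SpectrumRun",
    "Chromatogram",
    "Peak",
    "extract_xic",
    "detect_peaks",
    "integrate_peak",
    "isotope_score",
    "quantify_target",
]


@dataclass
class SpectrumRun:
    """An ordered centroided MS1 run.

    ``spectra`` is a list of (rt minutes, mz array, intensity array); RTs
    are strictly increasing and each spectrum's centroids are m/z-sorted.
    """

    spectra: list[tuple[float, np.ndarray, np.ndarray]]
    polarity: str = "negative"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [rt for rt, _, _ in self.spectra]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("spectrum retention times must strictly increase")
        for i, (rt, mz, inten) in enumerate(self.spectra):
            mz = np.asarray(mz, dtype=float)
            inten = np.asarray(inten, dtype=float)
            if mz.shape != inten.shape:
                raise ValueError(f"spectrum {i}: mz/intensity length mismatch")
            if mz.size and np.any(np.diff(mz) < 0):
                order = np.argsort(mz)
                mz, inten = mz[order], inten[order]
            self.spectra[i] = (float(rt), mz, inten)

    @property
    def rts(self) -> np.ndarray:
        return np.array([rt for rt, _, _ in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)

    def scan_interval(self) -> float:
        """Median time between consecutive scans, minutes."""
        rts = self.rts
        if len(rts) < 2:
            return 0.0
        return float(np.median(np.diff(rts)))


@dataclass
class Chromatogram:
    """RT-intensity trace for one extraction window: one point per MS1
    spectrum, zero-filled where no centroid fell inside the window."""

    rts: np.ndarray
    intensities: np.ndarray
    mz: float
    tolerance_ppm: float
    target: TargetEntry | None = None

    def __len__(self) -> int:
        return len(self.rts)


@dataclass
class Peak:
    """An integrated chromatographic peak."""

    apex_rt: float
    left_rt: float
    right_rt: float
    area: float
    height: float
    isotope_score: float | None = None

    def __post_init__(self) -> None:
        if not (self.left_rt <= self.apex_rt <= self.right_rt):
            raise ValueError("peak bounds must bracket the apex")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


def _window_sum(mz: np.ndarray, inten: np.ndarray, center: float,
                tol_ppm: float) -> float:
    half = center * tol_ppm * 1e-6
    lo = np.searchsorted(mz, center - half, side="left")
    hi = np.searchsorted(mz, center + half, side="right")
    return float(inten[lo:hi].sum())


def extract_xic(
    run: SpectrumRun, mz: float, tolerance_ppm: float = 10.0
) -> Chromatogram:
    """Sum centroid intensities with |dm/z|/mz <= tolerance*1e-6 per scan."""
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    if len(run) == 0:
        raise ValueError("run contains no spectra")
    rts = np.empty(len(run))
    vals = np.empty(len(run))
    for i, (rt, smz, sint) in enumerate(run.spectra):
        rts[i] = rt
        vals[i] = _window_sum(smz, sint, mz, tolerance_ppm)
    return Chromatogram(rts=rts, intensities=vals, mz=mz,
                        tolerance_ppm=tolerance_ppm)


def detect_peaks(
    xic: Chromatogram,
    min_height: float = 0.0,
    min_points: int = 3,
    boundary_fraction: float = 0.01,
) -> list[Peak]:
    """Local maxima above ``min_height``, with bounds where the trace falls
    to ``boundary_fraction`` of the apex (or a local minimum between
    neighboring peaks, so detected peaks never overlap)."""
    y = xic.intensities
    if len(y) < min_points:
        raise ValueError(f"chromatogram has fewer than {min_points} points")
    idx, _ = find_peaks(y, height=max(min_height, np.finfo(float).tiny))
    peaks: list[Peak] = []
    for k, i in enumerate(idx):
        floor = y[i] * boundary_fraction
        left = i
        lo_stop = idx[k - 1] if k > 0 else 0
        while left > lo_stop and y[left - 1] <= y[left] and y[left - 1] > floor:
            left -= 1
        right = i
        hi_stop = idx[k + 1] if k + 1 < len(idx) else len(y) - 1
        while (right < hi_stop and y[right + 1] <= y[right]
               and y[right + 1] > floor):
            right += 1
        if right - left + 1 < min_points:
            continue
        area = integrate_peak(xic, (xic.rts[left], xic.rts[right]))
        peaks.append(
            Peak(
                apex_rt=float(xic.rts[i]),
                left_rt=float(xic.rts[left]),
                right_rt=float(xic.rts[right]),
                area=area,
                height=float(y[left:right + 1].max()),
            )
        )
    return peaks


def integrate_peak(xic: Chromatogram, bounds: tuple[float, float]) -> float:
    """Trapezoidal area (intensity * minutes) over [left_rt, right_rt]."""
    left, right = bounds
    if left > right:
        raise ValueError(f"inverted bounds: {bounds}")
    mask = (xic.rts >= left) & (xic.rts <= right)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(xic.intensities[mask], xic.rts[mask]))


def isotope_score(
    run: SpectrumRun,
    target: TargetEntry,
    peak: Peak,
    tolerance_ppm: float = 10.0,
) -> float:
    """Cosine similarity between the target's theoretical isotope envelope
    and the observed apex-spectrum intensities at the isotope m/z positions
    (each read at the same ppm tolerance).

    1.0 means the observed envelope is proportional to theory; a species
    showing only its monoisotopic peak scores ab1/||ab||; signal at the
    wrong isotope positions scores lower still.
    """
    iso = target.isotope_mz_peaks()
    if len(iso) < 2:
        raise ValueError("target isotope pattern must have >= 2 peaks")
    apex_idx = int(np.argmin(np.abs(run.rts - peak.apex_rt)))
    _, smz, sint = run.spectra[apex_idx]
    theo = np.array([a for _, a in iso])
    obs = np.array([_window_sum(smz, sint, m, tolerance_ppm) for m, _ in iso])
    if obs.max() <= 0:
        return 0.0
    denom = float(np.linalg.norm(theo) * np.linalg.norm(obs))
    return float(np.dot(theo, obs) / denom)


def quantify_target(
    run: SpectrumRun,
    target: TargetEntry,
    tolerance_ppm: float = 10.0,
    min_height: float = 0.0,
    min_isotope_score: float | None = 0.7,
) -> tuple[Peak | None, list[Peak]]:
    """Extract, detect and pick the quantitation peak for one target.

    Candidates are peaks inside the target's RT window (all of them when
    no window is annotated).  The most intense candidate that clears the
    isotope-score threshold is selected; all candidates are returned for
    audit.  This operationalizes the judgment of a "true" analyte peak as
    max area within window plus isotope-envelope agreement.
    """
    xic = extract_xic(run, target.theoretical_mz, tolerance_ppm)
    candidates = [
        p for p in detect_peaks(xic, min_height=min_height)
        if target.in_rt_window(p.apex_rt)
    ]
    for p in candidates:
        p.isotope_score = isotope_score(run, target, p, tolerance_ppm)
    keep = candidates
    if min_isotope_score is not None:
        keep = [p for p in candidates
                if (p.isotope_score or 0.0) >= min_isotope_score]
    best = max(keep, key=lambda p: p.area, default=None)
    return best, candidates
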