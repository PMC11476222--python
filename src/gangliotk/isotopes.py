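"""Aggregated isotopic distributions by per-element multinomial convolution.

Isotopologues are binned by nominal mass shift relative to the monoisotopic
peak (A, A+1, A+2, ...), each bin carrying an abundance-weighted centroid
mass.  This is the resolution at which an Orbitrap-style instrument observes
isotope envelopes of intact glycosphingolipids; fine structure (e.g. the
13C2 vs 18O splitting inside A+2) is deliberately not resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import ATOMIC_ISOTOPES, ElementalComposition

__all__ = ["IsotopePattern", "isotope_pattern", "DEFAULT_THRESHOLD"]

#: Default truncation threshold, relative to the base (most abundant) peak.
DEFAULT_THRESHOLD = 1e-4

# Bins with probability below this are dropped *during* convolution only;
# it is far below any reportable threshold so it does not affect results.
_PRUNE = 1e-15


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated isotope envelope of a neutral composition.

    ``peaks`` are (mass Da, relative abundance) sorted by mass ascending,
    with the most abundant peak normalized to 1 and peaks below
    ``truncation_threshold`` (relative to it) removed.
    """

    peaks: tuple[tuple[float, float], ...]
    truncation_threshold: float

    @property
    def masses(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.peaks)

    @property
    def abundances(self) -> tuple[float, ...]:
        return tuple(a for _, a in self.peaks)

    def mz_peaks(
        self, n_protons_removed: int, *, proton_mass: float = 1.00727646
    ) -> tuple[tuple[float, float], ...]:
        """Project the neutral envelope onto the [M-nH]n- ion axis.

        Isotope spacing on the m/z axis is ~1.003355/n, i.e. it follows the
        charge state.
        """
        n = n_protons_removed
        return tuple(((m - n * proton_mass) / n, a) for m, a in self.peaks)


def _single_atom_bins(symbol: str) -> dict[int, tuple[float, float]]:
    """shift -> (probability, probability-weighted mass) for one atom."""
    isos = ATOMIC_ISOTOPES[symbol]
    nominal0 = isos[0][0]  # lightest isotope; principal for C,H,N,O,S,P
    return {nom - nominal0: (ab, ab * mass) for nom, mass, ab in isos}


def _convolve(
    a: dict[int, tuple[float, float]], b: dict[int, tuple[float, float]]
) -> dict[int, tuple[float, float]]:
    out: dict[int, tuple[float, float]] = {}
    for s1, (p1, m1) in a.items():
        for s2, (p2, m2) in b.items():
            p = p1 * p2
            if p < _PRUNE:
                continue
            # weighted-mass sums add as E[p*(m1+m2)] = p2*m1sum + p1*m2sum
            wm = p2 * m1 + p1 * m2
            s = s1 + s2
            if s in out:
                q, qm = out[s]
                out[s] = (q + p, qm + wm)
            else:
                out[s] = (p, wm)
    return out


def _element_distribution(symbol: str, n: int) -> dict[int, tuple[float, float]]:
    """Multinomial isotope distribution of n atoms of one element,
    computed by exponentiation-by-squaring of the one-atom distribution."""
    result: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    base = _single_atom_bins(symbol)
    while n > 0:
        if n & 1:
            result = _convolve(result, base)
        n >>= 1
        if n:
            base = _convolve(base, base)
    return result


def isotope_pattern(
    comp: ElementalComposition,
    threshold: float = DEFAULT_THRESHOLD,
) -> IsotopePattern:
    """Aggregated isotope pattern of a neutral elemental composition.

    Peaks are binned by nominal mass shift; each bin's mass is the
    abundance-weighted centroid over the isotopologues it contains.
    Abundances are normalized so the base peak is 1; bins below
    ``threshold`` (relative to the base peak) are dropped.
    """
    if not comp:
        raise ValueError("composition is empty")
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    dist: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for sym, n in comp:
        dist = _convolve(dist, _element_distribution(sym, n))
    bins = sorted(dist.items())
    centroids = [(wm / p, p) for _, (p, wm) in bins if p > 0]
    base = max(p for _, p in centroids)
    peaks = tuple(
        (mass, p / base) for mass, p in centroids if p / base >= threshold
    )
    return IsotopePattern(peaks=peaks, truncation_threshold=threshold)
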