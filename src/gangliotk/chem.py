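"""Exact elemental-composition arithmetic and deprotonated-ion m/z.

Monoisotopic masses come from a bundled table of isotope masses and
abundances (CODATA/IUPAC values, versioned with the package) so that
results are reproducible offline.  The only ion chemistry modeled here is
negative-mode deprotonation ([M-H]- and [M-2H]2-), which is how sialylated
glycosphingolipids are observed in ESI negative mode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

__all__ = [
    "ATOMIC_ISOTOPES",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "H_ATOM_MASS",
    "ElementalComposition",
    "AdductIon",
    "ADDUCT_H",
    "ADDUCT_2H",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
]

#: Mass of a proton (electron-corrected), Da.  Default convention for
#: deprotonated-ion m/z.
PROTON_MASS = 1.00727646

#: Mass of a neutral hydrogen atom, Da.  Alternative ("legacy") convention:
#: some published tables subtract H-atom masses instead of proton masses.
H_ATOM_MASS = 1.0078250319


def _load_isotope_table() -> dict[str, list[tuple[int, float, float]]]:
    table: dict[str, list[tuple[int, float, float]]] = {}
    path = resources.files("gangliotk").joinpath("data/atomic_masses.tsv")
    lines = path.read_text().splitlines()
    header = lines[0].split("\t")
    assert header == ["element", "nominal", "mass", "abundance"]
    for line in lines[1:]:
        if not line.strip():
            continue
        sym, nominal, mass, ab = line.split("\t")
        table.setdefault(sym, []).append((int(nominal), float(mass), float(ab)))
    for sym, isos in table.items():
        isos.sort(key=lambda t: t[0])
    return table


#: element symbol -> list of (nominal mass number, exact mass Da, abundance),
#: sorted by nominal mass.  "D" is the deuterium label used for isotope-coded
#: internal standards (e.g. GM1-d3).
ATOMIC_ISOTOPES: dict[str, list[tuple[int, float, float]]] = _load_isotope_table()

#: element -> exact mass of the most abundant (principal) isotope, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    sym: max(isos, key=lambda t: t[2])[1] for sym, isos in ATOMIC_ISOTOPES.items()
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(KeyError):
    """Raised when a composition refers to an element symbol not in the
    bundled mass table."""


def _check_symbol(symbol: str) -> str:
    # "H2" is accepted as an alias for the deuterium label.
    if symbol == "H2":
        symbol = "D"
    if symbol not in ATOMIC_ISOTOPES:
        raise UnknownElementError(f"unknown element symbol: {symbol!r}")
    return symbol


@dataclass(frozen=True)
class ElementalComposition:
    """An element -> count map with exact monoisotopic-mass semantics.

    Instances are immutable; addition, subtraction and integer scaling
    return new compositions.  All counts are non-negative: subtracting
    more atoms than are present raises ``ValueError`` (this catches
    assembly bookkeeping mistakes such as removing two waters for one
    condensation).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for sym, n in self.counts.items():
            sym = _check_symbol(sym)
            if not isinstance(n, int):
                raise TypeError(f"count for {sym} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for {sym}: {n}")
            if n:
                clean[sym] = clean.get(sym, 0) + n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula string such as ``"C6H10O5"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(
                    f"cannot parse formula {formula!r} at position {pos}"
                )
            sym = _check_symbol(m.group(1))
            counts[sym] = counts.get(sym, 0) + (int(m.group(2)) if m.group(2) else 1)
            pos = m.end()
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        return cls(counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) - n
            if merged[sym] < 0:
                raise ValueError(
                    f"subtraction would leave a negative {sym} count"
                )
        return ElementalComposition(merged)

    def __mul__(self, k: int) -> "ElementalComposition":
        if not isinstance(k, int) or k < 0:
            raise ValueError("scaling factor must be a non-negative integer")
        return ElementalComposition({s: n * k for s, n in self.counts.items()})

    __rmul__ = __mul__

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self.counts.items()))

    def __bool__(self) -> bool:
        return bool(self.counts)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def formula(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        order = sorted(
            self.counts, key=lambda s: (s != "C", s != "H", s)
        )
        return "".join(
            f"{s}{self.counts[s]}" if self.counts[s] != 1 else s for s in order
        )

    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self)

    def replace_hydrogens_with_deuterium(self, n: int) -> "ElementalComposition":
        """Swap ``n`` protium atoms for deuterium (isotope-coded standards)."""
        if n < 0:
            raise ValueError("n must be >= 0")
        if self.counts.get("H", 0) < n:
            raise ValueError("not enough hydrogens to label")
        out = dict(self.counts)
        out["H"] = out["H"] - n
        out["D"] = out.get("D", 0) + n
        return ElementalComposition(out)


def monoisotopic_mass(comp: ElementalComposition | Mapping[str, int]) -> float:
    """Exact monoisotopic mass in Da: sum of principal-isotope masses."""
    if not isinstance(comp, ElementalComposition):
        comp = ElementalComposition(dict(comp))
    return sum(MONOISOTOPIC_MASS[sym] * n for sym, n in comp.counts.items())


@dataclass(frozen=True)
class AdductIon:
    """A negative-mode deprotonation adduct: [M-nH]n-."""

    n_protons_removed: int
    label: str = ""

    def __post_init__(self) -> None:
        n = self.n_protons_removed
        if not isinstance(n, int) or n < 1:
            raise ValueError(f"n_protons_removed must be an integer >= 1, got {n!r}")
        object.__setattr__(self, "label", self.label or f"-{n if n > 1 else ''}H")

    @property
    def charge(self) -> int:
        return -self.n_protons_removed

    @classmethod
    def from_label(cls, label: str) -> "AdductIon":
        m = re.fullmatch(r"-(\d*)H", label.strip())
        if not m:
            raise ValueError(f"unsupported adduct label: {label!r}")
        return cls(int(m.group(1)) if m.group(1) else 1)


ADDUCT_H = AdductIon(1)
ADDUCT_2H = AdductIon(2)


def adduct_mz(
    neutral_mass: float,
    adduct: AdductIon,
    *,
    convention: str = "proton",
) -> float:
    """m/z of the n-fold deprotonated ion of a neutral of mass M.

        m/z = (M - n * m_p) / n

    ``convention`` selects the per-charge mass subtracted: ``"proton"``
    (1.00727646 Da, electron-corrected, the physically correct default) or
    ``"hydrogen"`` (1.0078250 Da, H-atom subtraction, provided for
    byte-matching outputs of tools that use that convention).  The two
    differ by ~0.7 mDa per charge (< 1 ppm for species above ~750 m/z).
    """
    n = adduct.n_protons_removed
    if convention == "proton":
        per_charge = PROTON_MASS
    elif convention == "hydrogen":
        per_charge = H_ATOM_MASS
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if neutral_mass <= n * per_charge:
        raise ValueError(
            f"neutral mass {neutral_mass} too small to remove {n} proton(s)"
        )
    return (neutral_mass - n * per_charge) / n


def ppm_error(theoretical: float, observed: float) -> float:
    """Absolute mass accuracy in parts-per-million.

        ppm = 1e6 * |observed - theoretical| / theoretical

    The absolute value is returned; the sign convention (whether the
    instrument read high or low) is not preserved.
    """
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * abs(observed - theoretical) / theoretical
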