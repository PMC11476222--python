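"""Theoretical target database: species x adduct enumeration and matching.

A target entry fixes everything needed to pull a species out of a run: the
deprotonated-ion m/z, its isotope envelope (charge-scaled spacing), and an
optional retention-time window.  Enumeration sweeps ceramide variants
(chain length / unsaturation) and charge states across an acquisition m/z
window; matching is done at ppm tolerance on the ion m/z, which is the
tolerance semantics high-resolution instruments use.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .chem import AdductIon, adduct_mz, ppm_error
from .isotopes import IsotopePattern, isotope_pattern, DEFAULT_THRESHOLD
from .nomenclature import (
    ClassRegistry,
    DEFAULT_REGISTRY,
    FattyAcyl,
    LipidSpecies,
    SphingoidBase,
    parse_species,
    render_species,
    species_neutral_mass,
)

__all__ = [
    "TargetEntry",
    "EnumerationConfig",
    "enumerate_targets",
    "match_mz",
    "write_target_db",
    "read_target_db",
    "DEFAULT_BASES",
]

#: Default sphingoid-base panel covering the printed species tables.
DEFAULT_BASES = ("d18:1", "d18:0", "d17:0", "t18:0", "m17:1")

#: Number of isotope peaks serialized per target.
N_ISO_COLUMNS = 3


@dataclass(frozen=True)
class TargetEntry:
    """One (species, adduct) quantitation target."""

    species: LipidSpecies
    adduct: AdductIon
    theoretical_mz: float
    isotope_pattern: IsotopePattern
    rt_window: tuple[float, float] | None = None  # (center min, half-width min)

    @property
    def name(self) -> str:
        return render_species(self.species, self.adduct)

    def isotope_mz_peaks(self) -> tuple[tuple[float, float], ...]:
        """Isotope envelope on the ion m/z axis (spacing 1.003355/|z|)."""
        return self.isotope_pattern.mz_peaks(self.adduct.n_protons_removed)

    def in_rt_window(self, rt: float) -> bool:
        if self.rt_window is None:
            return True
        center, half = self.rt_window
        return abs(rt - center) <= half


def make_target(
    species: LipidSpecies,
    adduct: AdductIon,
    rt_window: tuple[float, float] | None = None,
    *,
    convention: str = "proton",
    iso_threshold: float = DEFAULT_THRESHOLD,
) -> TargetEntry:
    """Build a target with recomputed m/z and isotope pattern."""
    mz = adduct_mz(species_neutral_mass(species), adduct, convention=convention)
    return TargetEntry(
        species=species,
        adduct=adduct,
        theoretical_mz=mz,
        isotope_pattern=isotope_pattern(species.composition, iso_threshold),
        rt_window=rt_window,
    )


@dataclass
class EnumerationConfig:
    """Sweep definition for building a target database.

    ``adducts_by_class`` overrides the default charge-state policy, which
    assigns -H to neutral/monosialo classes and both -H and -2H to classes
    with two or more sialic acids (multiply deprotonated ions are only
    abundant for multiply sialylated species).
    """

    classes: Sequence[str]
    bases: Sequence[str] = DEFAULT_BASES
    acyl_carbons: tuple[int, int] = (12, 26)
    acyl_double_bonds: tuple[int, int] = (0, 2)
    extra_oxygen_variants: tuple[int, ...] = (0,)
    adducts_by_class: dict[str, tuple[str, ...]] | None = None
    mz_window: tuple[float, float] = (500.0, 2000.0)  # FTMS acquisition range
    rt_windows: dict[str, tuple[float, float]] = field(default_factory=dict)
    registry: ClassRegistry = field(default=DEFAULT_REGISTRY, repr=False)
    convention: str = "proton"

    def adducts_for(self, class_name: str) -> tuple[AdductIon, ...]:
        if self.adducts_by_class and class_name in self.adducts_by_class:
            labels = self.adducts_by_class[class_name]
            return tuple(AdductIon.from_label(lb) for lb in labels)
        entry = self.registry.resolve(class_name)
        if entry.n_neuac >= 2:
            return (AdductIon(1), AdductIon(2))
        return (AdductIon(1),)


def enumerate_targets(cfg: EnumerationConfig) -> list[TargetEntry]:
    """Enumerate all (class, base, acyl, adduct) targets whose theoretical
    m/z lies inside the acquisition window, in deterministic order
    (class, base, acyl carbons, double bonds, charge)."""
    if not cfg.classes or not cfg.bases:
        raise ValueError("classes and bases must be non-empty")
    lo_c, hi_c = cfg.acyl_carbons
    lo_db, hi_db = cfg.acyl_double_bonds
    if lo_c > hi_c:
        raise ValueError("empty acyl carbon range")
    out: list[TargetEntry] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # bulk sweeps cross the chain-range note
        for class_name in cfg.classes:
            entry = cfg.registry.resolve(class_name)
            for base_str in cfg.bases:
                base = _parse_base(base_str)
                acyls: Iterable[FattyAcyl | None]
                if entry.has_acyl:
                    acyls = (
                        FattyAcyl(c, db, xo)
                        for c in range(lo_c, hi_c + 1)
                        for db in range(lo_db, hi_db + 1)
                        for xo in cfg.extra_oxygen_variants
                    )
                else:
                    acyls = (None,)
                for acyl in acyls:
                    sp = LipidSpecies(
                        class_name=class_name, base=base, acyl=acyl,
                        registry=cfg.registry,
                    )
                    for adduct in cfg.adducts_for(class_name):
                        mz = adduct_mz(
                            species_neutral_mass(sp), adduct,
                            convention=cfg.convention,
                        )
                        if not (cfg.mz_window[0] <= mz <= cfg.mz_window[1]):
                            continue
                        out.append(
                            make_target(
                                sp, adduct,
                                rt_window=cfg.rt_windows.get(class_name),
                                convention=cfg.convention,
                            )
                        )
    if not out:
        warnings.warn("target enumeration produced no entries", stacklevel=2)
    return out


def _parse_base(token: str) -> SphingoidBase:
    from .nomenclature import _CHAIN_RE, _HYDROXYL_COUNT

    m = _CHAIN_RE.fullmatch(token.strip())
    if not m or m.group("hcls") not in _HYDROXYL_COUNT or m.group("mod"):
        raise ValueError(f"malformed sphingoid base token {token!r}")
    return SphingoidBase(m.group("hcls"), int(m.group("c")), int(m.group("db")))


def match_mz(
    observed: float,
    targets: Sequence[TargetEntry],
    tolerance_ppm: float = 10.0,
) -> list[tuple[TargetEntry, float]]:
    """All targets within ``tolerance_ppm`` of an observed m/z, sorted by
    ascending ppm error; ties broken by fewer sialic acids, then name."""
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    hits = [
        (t, ppm_error(t.theoretical_mz, observed))
        for t in targets
        if ppm_error(t.theoretical_mz, observed) <= tolerance_ppm
    ]
    hits.sort(key=lambda te: (te[1], te[0].species.class_entry.n_neuac,
                              te[0].name))
    return hits


_CSV_COLUMNS = (
    ["class", "species_name", "base", "acyl", "adduct", "charge",
     "theoretical_mz"]
    + [f"iso_mz_{i}" for i in range(1, N_ISO_COLUMNS + 1)]
    + [f"iso_ab_{i}" for i in range(1, N_ISO_COLUMNS + 1)]
    + ["rt_center", "rt_halfwidth"]
)


def write_target_db(targets: Sequence[TargetEntry], path: str | Path) -> None:
    """Serialize targets to CSV (m/z to 6 decimal places, lossless on
    round-trip at that precision)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for t in targets:
            iso = t.isotope_mz_peaks()[:N_ISO_COLUMNS]
            iso_mz = [f"{m:.6f}" for m, _ in iso]
            iso_ab = [f"{a:.6f}" for _, a in iso]
            iso_mz += [""] * (N_ISO_COLUMNS - len(iso_mz))
            iso_ab += [""] * (N_ISO_COLUMNS - len(iso_ab))
            rt_c, rt_h = ("", "")
            if t.rt_window is not None:
                rt_c, rt_h = f"{t.rt_window[0]:.4f}", f"{t.rt_window[1]:.4f}"
            w.writerow(
                [
                    t.species.class_name,
                    render_species(t.species),
                    str(t.species.base),
                    str(t.species.acyl) if t.species.acyl else "",
                    t.adduct.label,
                    t.adduct.charge,
                    f"{t.theoretical_mz:.6f}",
                ]
                + iso_mz + iso_ab + [rt_c, rt_h]
            )


def read_target_db(
    path: str | Path, registry: ClassRegistry = DEFAULT_REGISTRY
) -> list[TargetEntry]:
    """Read a target CSV written by :func:`write_target_db`.

    Species, adduct and isotope patterns are rebuilt from the stored name
    (compositions are recomputable); the stored m/z is kept and checked
    against the recomputed value elsewhere.
    """
    out: list[TargetEntry] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(
                f"target CSV {path} missing columns: {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sp = parse_species(row["species_name"], registry)
                adduct = AdductIon.from_label(row["adduct"])
                mz = float(row["theoretical_mz"])
                rt_window = None
                if row["rt_center"]:
                    rt_window = (float(row["rt_center"]),
                                 float(row["rt_halfwidth"]))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
            out.append(
                TargetEntry(
                    species=sp,
                    adduct=adduct,
                    theoretical_mz=mz,
                    isotope_pattern=isotope_pattern(sp.composition),
                    rt_window=rt_window,
                )
            )
    return out
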