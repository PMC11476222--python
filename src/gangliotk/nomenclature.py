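"""Shorthand sphingolipid nomenclature and the ganglioside class registry.

Species are written ``CLASS(base_acyl)`` in LipidSearch-style shorthand,
e.g. ``GM3(d18:1_18:0)``: the sphingoid base prefix m/d/t encodes 1/2/3
hydroxyls, ``18:1`` is carbons:double-bonds, and the fatty acyl may carry a
``+nO`` hydroxylation modifier (``Hex1Cer(d17:0_18:2+2O)``).  An optional
trailing adduct token (``-H``, ``-2H``) names the observed deprotonated ion.

Class names map to glycan headgroup residue counts through a registry
derived from the ganglioside biosynthesis pathway: GM/GD/GT/GQ series carry
1/2/3/4 sialic acids (NeuAc), GA is the asialo series, and the trailing
number reflects glycan length.  Letter suffixes (GD1a/GD1b, ...) denote
linkage isomers with identical composition and mass; the registry exposes
them as isomer groups with retention-order annotations, since only
chromatography separates them.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

from .chem import ElementalComposition, AdductIon, monoisotopic_mass

__all__ = [
    "SphingoidBase",
    "FattyAcyl",
    "LipidSpecies",
    "ClassRegistry",
    "DEFAULT_REGISTRY",
    "RESIDUE_COMPOSITIONS",
    "WATER",
    "parse_species",
    "parse_ion",
    "render_species",
    "ceramide_composition",
    "species_neutral_mass",
    "ParseError",
]

WATER = ElementalComposition.from_formula("H2O")

#: Condensed (anhydro) residue compositions added per glycosidic linkage,
#: plus the phosphate/sulfate substituents.
RESIDUE_COMPOSITIONS: dict[str, ElementalComposition] = {
    "hex": ElementalComposition.from_formula("C6H10O5"),
    "hexnac": ElementalComposition.from_formula("C8H13NO5"),
    "neuac": ElementalComposition.from_formula("C11H17NO8"),
    "phosphate": ElementalComposition.from_formula("HPO3"),
    "sulfate": ElementalComposition.from_formula("SO3"),
}

#: Chain-length range considered biologically ordinary; parses outside it
#: succeed with a warning (odd standards like m17:1 or t16:1 do occur).
CHAIN_CARBON_RANGE = (12, 26)


class ParseError(ValueError):
    """Raised for malformed species names; carries the offending position."""

    def __init__(self, message: str, name: str, position: int):
        super().__init__(f"{message} in {name!r} at position {position}")
        self.name = name
        self.position = position


_HYDROXYL_COUNT = {"m": 1, "d": 2, "t": 3}


@dataclass(frozen=True)
class SphingoidBase:
    """Long-chain amino alcohol: formula C_c H_(2c+3-2*db) N O_h."""

    hydroxyl_class: str  # one of "m", "d", "t" (1/2/3 hydroxyls)
    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.hydroxyl_class not in _HYDROXYL_COUNT:
            raise ValueError(
                f"hydroxyl class must be m/d/t, got {self.hydroxyl_class!r}"
            )
        if self.carbons < 1 or self.double_bonds < 0:
            raise ValueError("invalid sphingoid chain")
        if 2 * self.carbons + 3 - 2 * self.double_bonds < 0:
            raise ValueError("more double bonds than the chain can hold")

    @property
    def hydroxyls(self) -> int:
        return _HYDROXYL_COUNT[self.hydroxyl_class]

    @property
    def composition(self) -> ElementalComposition:
        return ElementalComposition(
            {
                "C": self.carbons,
                "H": 2 * self.carbons + 3 - 2 * self.double_bonds,
                "N": 1,
                "O": self.hydroxyls,
            }
        )

    def __str__(self) -> str:
        return f"{self.hydroxyl_class}{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class FattyAcyl:
    """N-acyl chain, written as the free acid C_c H_(2c-2*db) O_2; the
    ``+nO`` shorthand modifier adds hydroxylations as extra oxygens."""

    carbons: int
    double_bonds: int
    extra_oxygens: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 1 or self.double_bonds < 0 or self.extra_oxygens < 0:
            raise ValueError("invalid fatty acyl descriptor")
        if 2 * self.carbons - 2 * self.double_bonds < 0:
            raise ValueError("more double bonds than the chain can hold")

    @property
    def composition(self) -> ElementalComposition:
        return ElementalComposition(
            {
                "C": self.carbons,
                "H": 2 * self.carbons - 2 * self.double_bonds,
                "O": 2 + self.extra_oxygens,
            }
        )

    def __str__(self) -> str:
        mod = f"+{self.extra_oxygens}O" if self.extra_oxygens else ""
        return f"{self.carbons}:{self.double_bonds}{mod}"


def _warn_chain_range(kind: str, carbons: int) -> None:
    lo, hi = CHAIN_CARBON_RANGE
    if not lo <= carbons <= hi:
        warnings.warn(
            f"{kind} chain length {carbons} outside usual range {lo}-{hi}",
            stacklevel=3,
        )


def ceramide_composition(
    base: SphingoidBase, acyl: FattyAcyl
) -> ElementalComposition:
    """Elemental composition of a ceramide: base + free fatty acid - H2O
    (the amide condensation)."""
    _warn_chain_range("sphingoid base", base.carbons)
    _warn_chain_range("fatty acyl", acyl.carbons)
    return base.composition + acyl.composition - WATER


@dataclass(frozen=True)
class ClassEntry:
    name: str
    residues: dict[str, int]
    has_acyl: bool
    isomer_group: tuple[str, ...] = ()
    elution_note: str = ""

    @property
    def n_neuac(self) -> int:
        return self.residues.get("neuac", 0)

    def glycan_composition(self) -> ElementalComposition:
        comp = ElementalComposition()
        for key, n in self.residues.items():
            if n:
                comp = comp + n * RESIDUE_COMPOSITIONS[key]
        return comp


class ClassRegistry:
    """Sphingolipid class -> glycan residue counts, loaded from a TSV so the
    panel can be extended without code changes.  Linkage-isomer names
    (GD1a, GT1b, ...) resolve to their composition class."""

    def __init__(self, entries: dict[str, ClassEntry]):
        self.entries = entries
        self._aliases: dict[str, str] = {}
        for name, e in entries.items():
            for iso in e.isomer_group:
                self._aliases[iso] = name

    @classmethod
    def from_tsv(cls, text: str) -> "ClassRegistry":
        entries: dict[str, ClassEntry] = {}
        reader = csv.DictReader(text.splitlines(), delimiter="\t", restval="")
        required = {"class", "hex", "hexnac", "neuac", "sulfate", "phosphate",
                    "has_acyl"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"registry TSV missing columns: {sorted(missing)}")
        for row in reader:
            name = row["class"].strip()
            if not name:
                continue
            entries[name] = ClassEntry(
                name=name,
                residues={
                    k: int(row[k]) for k in
                    ("hex", "hexnac", "neuac", "sulfate", "phosphate")
                },
                has_acyl=bool(int(row["has_acyl"])),
                isomer_group=tuple(
                    s for s in (row.get("isomer_group") or "").split(",") if s
                ),
                elution_note=(row.get("elution_note") or "").strip(),
            )
        return cls(entries)

    @classmethod
    def default(cls) -> "ClassRegistry":
        path = resources.files("gangliotk").joinpath(
            "data/ganglioside_classes.tsv"
        )
        return cls.from_tsv(path.read_text())

    def resolve(self, name: str) -> ClassEntry:
        key = self._aliases.get(name, name)
        if key not in self.entries:
            raise KeyError(f"unknown sphingolipid class: {name!r}")
        return self.entries[key]

    def __contains__(self, name: str) -> bool:
        return name in self.entries or name in self._aliases

    def class_names(self) -> list[str]:
        return list(self.entries)

    def all_names(self) -> list[str]:
        return list(self.entries) + list(self._aliases)


DEFAULT_REGISTRY = ClassRegistry.default()


@dataclass(frozen=True)
class LipidSpecies:
    """A sphingolipid species: class + ceramide descriptor.

    ``acyl`` is absent for lyso-type classes (SPHP, sphingosine phosphate).
    ``n_deuterium`` models isotope-coded internal standards (GM1-d3) as a
    protium-to-deuterium swap on the derived composition.
    """

    class_name: str
    base: SphingoidBase
    acyl: FattyAcyl | None = None
    n_deuterium: int = 0
    registry: ClassRegistry = field(
        default=DEFAULT_REGISTRY, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        entry = self.registry.resolve(self.class_name)
        if entry.has_acyl and self.acyl is None:
            raise ValueError(f"class {self.class_name} requires a fatty acyl")
        if not entry.has_acyl and self.acyl is not None:
            raise ValueError(f"class {self.class_name} takes no fatty acyl")

    @property
    def class_entry(self) -> ClassEntry:
        return self.registry.resolve(self.class_name)

    @property
    def composition(self) -> ElementalComposition:
        entry = self.class_entry
        if self.acyl is not None:
            core = ceramide_composition(self.base, self.acyl)
        else:
            core = self.base.composition
        comp = core + entry.glycan_composition()
        if self.n_deuterium:
            comp = comp.replace_hydrogens_with_deuterium(self.n_deuterium)
        return comp

    @property
    def name(self) -> str:
        return render_species(self)

    def neutral_mass(self) -> float:
        return species_neutral_mass(self)


def species_neutral_mass(sp: LipidSpecies) -> float:
    """Monoisotopic neutral mass in Da of the assembled species."""
    return monoisotopic_mass(sp.composition)


_CHAIN_RE = re.compile(
    r"(?P<hcls>[a-z]?)(?P<c>\d+):(?P<db>\d+)(?P<mod>\+\d+O)?"
)


def _parse_chain_pair(
    inner: str, name: str, offset: int
) -> tuple[SphingoidBase, FattyAcyl | None]:
    # base/acyl separator: "_" (tables), "-" or "/" (running text)
    m = _CHAIN_RE.match(inner)
    if not m or not m.group("hcls"):
        raise ParseError("expected sphingoid base like 'd18:1'", name, offset)
    if m.group("hcls") not in _HYDROXYL_COUNT:
        raise ParseError(
            f"unknown hydroxyl class {m.group('hcls')!r}", name, offset
        )
    if m.group("mod"):
        raise ParseError("+nO modifier is only valid on the acyl", name, offset)
    base = SphingoidBase(m.group("hcls"), int(m.group("c")), int(m.group("db")))
    rest = inner[m.end():]
    if not rest:
        return base, None
    if rest[0] not in "_-/":
        raise ParseError("expected '_' between base and acyl", name,
                         offset + m.end())
    acyl_str = rest[1:]
    am = _CHAIN_RE.fullmatch(acyl_str)
    if not am or am.group("hcls"):
        raise ParseError("malformed fatty acyl token", name,
                         offset + m.end() + 1)
    extra = int(am.group("mod")[1:-1]) if am.group("mod") else 0
    acyl = FattyAcyl(int(am.group("c")), int(am.group("db")), extra)
    return base, acyl


_DEUTERIUM_SUFFIX = re.compile(r"[-+]d(\d+)$")


def parse_ion(
    name: str, registry: ClassRegistry = DEFAULT_REGISTRY
) -> tuple[LipidSpecies, AdductIon | None]:
    """Parse ``CLASS(base_acyl[+nO])[-H|-2H]``; whitespace is tolerated
    anywhere (printed tables sometimes break names, e.g. "GM 2 (...)").

    Returns the species and the trailing adduct token (or None)."""
    stripped = re.sub(r"\s+", "", name)
    open_i = stripped.find("(")
    close_i = stripped.rfind(")")
    if open_i <= 0 or close_i < open_i:
        raise ParseError("expected CLASS(...)", name, max(open_i, 0))
    class_token = stripped[:open_i]
    n_deu = 0
    dm = _DEUTERIUM_SUFFIX.search(class_token)
    if dm:
        n_deu = int(dm.group(1))
        class_token = class_token[: dm.start()]
    if class_token not in registry:
        raise ParseError(f"unknown class {class_token!r}", name, 0)
    base, acyl = _parse_chain_pair(
        stripped[open_i + 1 : close_i], name, open_i + 1
    )
    trailing = stripped[close_i + 1 :]
    adduct: AdductIon | None = None
    if trailing:
        try:
            adduct = AdductIon.from_label(trailing)
        except ValueError:
            raise ParseError(
                f"unrecognized adduct token {trailing!r}", name, close_i + 1
            ) from None
    entry = registry.resolve(class_token)
    if not entry.has_acyl and acyl is not None:
        raise ParseError(f"class {class_token} takes no acyl", name, open_i + 1)
    if entry.has_acyl and acyl is None:
        raise ParseError(f"class {class_token} requires base_acyl", name,
                         open_i + 1)
    species = LipidSpecies(
        class_name=class_token, base=base, acyl=acyl, n_deuterium=n_deu,
        registry=registry,
    )
    return species, adduct


def parse_species(
    name: str, registry: ClassRegistry = DEFAULT_REGISTRY
) -> LipidSpecies:
    """Parse a species name, discarding any trailing adduct token."""
    return parse_ion(name, registry)[0]


def render_species(sp: LipidSpecies, adduct: AdductIon | None = None) -> str:
    """Canonical shorthand: ``CLASS(base_acyl[+nO])`` plus optional
    deuterium and adduct suffixes.  ``parse(render(x)) == x``."""
    label = f"-d{sp.n_deuterium}" if sp.n_deuterium else ""
    chains = str(sp.base) if sp.acyl is None else f"{sp.base}_{sp.acyl}"
    out = f"{sp.class_name}{label}({chains})"
    if adduct is not None:
        out += adduct.label
    return out
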