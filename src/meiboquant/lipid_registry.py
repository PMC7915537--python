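"""Meibum lipid species table, exact masses, and peak assignment.

Mouse meibum is dominated by wax esters (WE), cholesteryl esters (CE),
free cholesterol (Chl), triacylglycerols (TAG) and cholesteryl esters of
(O)-acylated omega-hydroxy fatty acids (Chl-OAHFA).  In positive-mode
APCI all sterol lipids share a common analytical ion — dehydrated,
protonated cholesterol, C27H45+ at m/z 369.3521 — produced by water loss
from Chl and fatty-acid loss from CE/Chl-OAHFA.  This module defines the
species, computes the m/z of their detection channels from elemental
formulas, and maps observed (m/z, retention time) pairs to species
labels at the granularity used for reporting (co-eluting Cn:0/C(n+2):1
CE pairs are grouped under one label).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "ElementalFormula",
    "LipidSpecies",
    "IonChannel",
    "AssignmentEntry",
    "AssignmentTable",
    "LipidRegistry",
    "monoisotopic_mass",
    "adduct_mz",
    "build_default_registry",
    "build_assignment_table",
    "assign_peak",
    "PROTON",
    "STEROL_FRAGMENT_MZ",
    "CE_LABEL_GROUPS",
    "UNIDENTIFIED",
]

# Monoisotopic atomic masses (IUPAC); the electron mass is deliberately
# not subtracted when forming cation m/z values — the conventional
# "formula sum" m/z used in routine lipidomics reporting.
ATOMIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.9949146196,
    "N": 14.0030740048,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

PROTON = ATOMIC_MASS["H"]
_H2O = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]
_NH4 = ATOMIC_MASS["N"] + 4 * ATOMIC_MASS["H"]

#: m/z of the common sterol analytical ion C27H45+ (protonated,
#: dehydrated cholesterol), shared by Chl, CE and Chl-OAHFA.
STEROL_FRAGMENT_MZ = 27 * ATOMIC_MASS["C"] + 45 * ATOMIC_MASS["H"]

UNIDENTIFIED = "unidentified"

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count mapping, e.g. C55H99O2."""

    counts: Mapping[str, int]

    def __post_init__(self):
        for el, n in self.counts.items():
            if el not in ATOMIC_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el}")
        object.__setattr__(self, "counts", dict(self.counts))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text.replace(" ", "")):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            el = m.group(1)
            counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
        if pos != len(text.replace(" ", "")):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ValueError(f"subtraction yields negative count for {el}")
        return ElementalFormula({el: n for el, n in merged.items() if n})

    def to_string(self) -> str:
        order = ["C", "H", "N", "O", "Na", "K"]
        parts = []
        for el in order:
            n = self.counts.get(el, 0)
            if n:
                parts.append(f"{el}{n if n > 1 else ''}")
        return "".join(parts)


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass in Da of a (possibly empty) elemental formula."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    return sum(ATOMIC_MASS[el] * n for el, n in formula.counts.items())


# ---------------------------------------------------------------------------
# Species

LIPID_CLASSES = ("Chl", "CE", "WE", "TAG", "Chl-OAHFA", "OAHFA", "DiAD")

STEROL_CLASSES = ("Chl", "CE", "Chl-OAHFA")


@dataclass(frozen=True)
class LipidSpecies:
    """A named meibum lipid with its neutral formula and nominal RT."""

    id: str
    lipid_class: str
    neutral_formula: ElementalFormula
    fa_carbons: int | None = None
    fa_double_bonds: int | None = None
    nominal_rt_min: float | None = None

    def __post_init__(self):
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if not self.neutral_formula.counts:
            raise ValueError("species formula must be non-empty")
        if self.lipid_class == "CE" and self.fa_carbons is not None:
            if not 10 <= self.fa_carbons <= 34:
                raise ValueError("CE fatty-acid chain length must be C10..C34")

    @property
    def ecl(self) -> float | None:
        """Equivalent chain length (carbons - 2 per double bond).

        In reverse-phase chromatography one double bond shortens the
        apparent chain by roughly two methylenes, so Cn:0 co-elutes
        with C(n+2):1 — exactly the pairs reported as single labels.
        """
        if self.fa_carbons is None:
            return None
        return self.fa_carbons - 2 * (self.fa_double_bonds or 0)

    def fa_formula(self) -> ElementalFormula:
        """Formula of the free fatty acid moiety CnH(2n-2x)O2."""
        if self.fa_carbons is None:
            raise ValueError(f"species {self.id} has no fatty-acid moiety")
        n, x = self.fa_carbons, self.fa_double_bonds or 0
        return ElementalFormula({"C": n, "H": 2 * n - 2 * x, "O": 2})


ADDUCTS = ("M+H", "M-H2O+H", "M-FA+H", "M+NH4", "M+Na", "M+K")


def adduct_mz(species: LipidSpecies, adduct: str) -> float:
    """m/z of a named adduct or fragment cation of a species.

    ``M-H2O+H`` is the sterol dehydration fragment (Chl only);
    ``M-FA+H`` is loss of the fatty-acid moiety (CE, Chl-OAHFA, TAG),
    which for CE again yields the C27H45+ sterol ion.
    """
    neutral = monoisotopic_mass(species.neutral_formula)
    if adduct == "M+H":
        return neutral + PROTON
    if adduct == "M+NH4":
        return neutral + _NH4
    if adduct == "M+Na":
        return neutral + ATOMIC_MASS["Na"]
    if adduct == "M+K":
        return neutral + ATOMIC_MASS["K"]
    if adduct == "M-H2O+H":
        if species.lipid_class != "Chl":
            raise ValueError(
                f"dehydration fragment is a sterol channel; not valid for "
                f"{species.lipid_class} species {species.id}"
            )
        return neutral - _H2O + PROTON
    if adduct == "M-FA+H":
        if species.lipid_class in ("CE", "Chl-OAHFA"):
            # the acid moiety is everything except the cholesteryl part:
            # acid = M - (cholesterol - H2O), so the fragment cation is
            # dehydrated, protonated cholesterol whatever the chain is
            cholesteryl = monoisotopic_mass("C27H46O") - _H2O
            acid = neutral - cholesteryl
            return neutral - acid + PROTON
        if species.lipid_class == "TAG":
            return neutral - monoisotopic_mass(species.fa_formula()) + PROTON
        raise ValueError(
            f"fatty-acid loss fragment not defined for class "
            f"{species.lipid_class} (species {species.id})"
        )
    raise ValueError(f"unknown adduct {adduct!r}")


def sterol_fragment_adduct(species: LipidSpecies) -> str:
    """Which adduct produces the m/z 369.35 ion for a sterol species."""
    if species.lipid_class == "Chl":
        return "M-H2O+H"
    if species.lipid_class in ("CE", "Chl-OAHFA"):
        return "M-FA+H"
    raise ValueError(f"{species.id} ({species.lipid_class}) is not a sterol lipid")


@dataclass(frozen=True)
class IonChannel:
    """A single EIC detection channel: target m/z with a window width."""

    species_id: str
    adduct: str
    target_mz: float
    window_mda: float = 50.0  # total width; the trace sums +/- window/2

    def __post_init__(self):
        if self.target_mz <= 0:
            raise ValueError("target_mz must be positive")
        if self.window_mda <= 0:
            raise ValueError("window_mda must be positive")

    @property
    def half_width_da(self) -> float:
        return self.window_mda / 2000.0

    def contains(self, mz: float) -> bool:
        return abs(mz - self.target_mz) <= self.half_width_da


# ---------------------------------------------------------------------------
# Retention-time model
#
# Nominal retention times are anchored on the printed standard-mix times
# (Chl 6.93 min, cholesteryl oleate 21.03 min, cholesteryl nervonate
# 28.48 min, triolein 18.64 min, lignoceryl oleate 22.35 min) and
# extended across homologs linearly in equivalent chain length.

RT_CHL = 6.93
RT_CHOLESTERYL_OLEATE = 21.03   # CE 18:1, ECL 16
RT_CHOLESTERYL_NERVONATE = 28.48  # CE 24:1, ECL 22
RT_TRIOLEIN = 18.64
RT_LIGNOCERYL_OLEATE = 22.35    # WE 42:1, ECL 40

_CE_RT_SLOPE = (RT_CHOLESTERYL_NERVONATE - RT_CHOLESTERYL_OLEATE) / 6.0


def ce_rt_from_ecl(ecl: float) -> float:
    return RT_CHOLESTERYL_OLEATE + _CE_RT_SLOPE * (ecl - 16.0)


def we_rt_from_ecl(ecl: float) -> float:
    return RT_LIGNOCERYL_OLEATE + 0.5 * (ecl - 40.0)


def ce_formula(fa_carbons: int, fa_double_bonds: int) -> ElementalFormula:
    """Neutral cholesteryl-ester formula C(27+n)H(44+2n-2x)O2."""
    n, x = fa_carbons, fa_double_bonds
    return ElementalFormula({"C": 27 + n, "H": 44 + 2 * n - 2 * x, "O": 2})


def we_formula(total_carbons: int, double_bonds: int) -> ElementalFormula:
    """Neutral wax-ester formula CnH(2n-2x)O2."""
    n, x = total_carbons, double_bonds
    return ElementalFormula({"C": n, "H": 2 * n - 2 * x, "O": 2})


def tag_formula(acyl_carbons: int, double_bonds: int) -> ElementalFormula:
    """Neutral triacylglycerol formula C(n+3)H(2n+2-2x)O6."""
    n, x = acyl_carbons, double_bonds
    return ElementalFormula({"C": n + 3, "H": 2 * n + 2 - 2 * x, "O": 6})


# ---------------------------------------------------------------------------
# Registry


@dataclass
class LipidRegistry:
    species: dict[str, LipidSpecies] = field(default_factory=dict)
    channels: list[IonChannel] = field(default_factory=list)

    def add(self, species: LipidSpecies, adducts: Iterable[str]) -> None:
        if species.id in self.species:
            raise ValueError(f"duplicate species id {species.id}")
        self.species[species.id] = species
        for adduct in adducts:
            self.channels.append(
                IonChannel(species.id, adduct, adduct_mz(species, adduct))
            )

    def get(self, species_id: str) -> LipidSpecies:
        return self.species[species_id]

    def channels_for(self, species_id: str) -> list[IonChannel]:
        return [c for c in self.channels if c.species_id == species_id]

    def channel(self, species_id: str, adduct: str) -> IonChannel:
        for c in self.channels:
            if c.species_id == species_id and c.adduct == adduct:
                return c
        raise KeyError(f"no channel {adduct} for species {species_id}")

    def species_of_class(self, lipid_class: str) -> list[LipidSpecies]:
        return [s for s in self.species.values() if s.lipid_class == lipid_class]

    def sterol_channel(self) -> IonChannel:
        """The shared m/z 369.35 channel (one trace covers all sterols)."""
        return IonChannel("sterols", "M-FA+H", STEROL_FRAGMENT_MZ)

    # -- serialization ------------------------------------------------------

    def to_records(self) -> list[dict]:
        rows = []
        for ch in self.channels:
            s = self.species[ch.species_id]
            rows.append(
                {
                    "id": s.id,
                    "class": s.lipid_class,
                    "fa_carbons": s.fa_carbons,
                    "fa_db": s.fa_double_bonds,
                    "formula": s.neutral_formula.to_string(),
                    "adduct": ch.adduct,
                    "target_mz": round(ch.target_mz, 5),
                    "window_mda": ch.window_mda,
                    "rt_min": s.nominal_rt_min,
                }
            )
        return rows

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"version": 1, "channels": self.to_records()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LipidRegistry":
        with open(path) as fh:
            payload = json.load(fh)
        reg = cls()
        for row in payload["channels"]:
            if row["id"] not in reg.species:
                reg.species[row["id"]] = LipidSpecies(
                    id=row["id"],
                    lipid_class=row["class"],
                    neutral_formula=ElementalFormula.parse(row["formula"]),
                    fa_carbons=row["fa_carbons"],
                    fa_double_bonds=row["fa_db"],
                    nominal_rt_min=row["rt_min"],
                )
            reg.channels.append(
                IonChannel(row["id"], row["adduct"], row["target_mz"], row["window_mda"])
            )
        return reg


def ce_id(fa_carbons: int, fa_double_bonds: int) -> str:
    return f"CE {fa_carbons}:{fa_double_bonds}"


#: The six monounsaturated/diunsaturated WE channels routinely profiled
#: (printed m/z 619.64, 633.65, 647.67, 675.70, 701.72, 729.75).
_WE_TABLE = [("WE 42:1", 42, 1), ("WE 43:1", 43, 1), ("WE 44:1", 44, 1),
             ("WE 46:1", 46, 1), ("WE 48:2", 48, 2), ("WE 50:2", 50, 2)]


def build_default_registry() -> LipidRegistry:
    """The default species/channel table.

    Contains free cholesterol, all CE with C10-C34 fatty acids at 0-1
    double bonds (each with both its proton-adduct channel and the
    shared 369.35 fragment channel), the six named WE, one endogenous
    TAG (C55H101O6+ channel) plus triolein as the TAG standard, and one
    Chl-OAHFA.
    """
    reg = LipidRegistry()
    reg.add(
        LipidSpecies("Chl", "Chl", ElementalFormula.parse("C27H46O"),
                     nominal_rt_min=RT_CHL),
        adducts=["M-H2O+H"],
    )
    for n in range(10, 35):
        for x in (0, 1):
            sp = LipidSpecies(
                ce_id(n, x), "CE", ce_formula(n, x), fa_carbons=n,
                fa_double_bonds=x, nominal_rt_min=ce_rt_from_ecl(n - 2 * x),
            )
            reg.add(sp, adducts=["M+H", "M-FA+H"])
    for sid, n, x in _WE_TABLE:
        reg.add(
            LipidSpecies(sid, "WE", we_formula(n, x), fa_carbons=n,
                         fa_double_bonds=x, nominal_rt_min=we_rt_from_ecl(n - 2 * x)),
            adducts=["M+H"],
        )
    # endogenous TAG 52:3 (C55H100O6 neutral -> C55H101O6+ at 857.76)
    reg.add(
        LipidSpecies("TAG 52:3", "TAG", tag_formula(52, 3), nominal_rt_min=17.50),
        adducts=["M+H"],
    )
    reg.add(
        LipidSpecies("TAG 54:3", "TAG", tag_formula(54, 3),
                     nominal_rt_min=RT_TRIOLEIN),
        adducts=["M+H"],
    )
    # Chl-OAHFA with the printed C75H135O4+ proton-adduct channel; its
    # fatty-acid loss also feeds the 369.35 sterol channel.  The stored
    # m/z is the formula sum (1100.036); the printed 1100.02 differs by
    # ~16 mDa and is treated as a rounding/typesetting artifact.
    reg.add(
        LipidSpecies("Chl-OAHFA 48:2", "Chl-OAHFA",
                     ElementalFormula.parse("C75H134O4"),
                     fa_carbons=48, fa_double_bonds=2, nominal_rt_min=44.8),
        adducts=["M+H", "M-FA+H"],
    )
    return reg


# ---------------------------------------------------------------------------
# Assignment table (reporting labels 1-21)

#: Reporting groups for CE: co-eluting saturated/monounsaturated pairs
#: are summed under a single label, matching routine profiling output.
CE_LABEL_GROUPS: list[tuple[str, list[tuple[int, int]]]] = [
    ("C10:0-CE", [(10, 0)]),
    ("C12:0/C14:1-CE", [(12, 0), (14, 1)]),
    ("C14:0/C16:1-CE", [(14, 0), (16, 1)]),
    ("C15:0-CE", [(15, 0)]),
    ("C16:0/C18:1-CE", [(16, 0), (18, 1)]),
    ("C17:0-CE", [(17, 0)]),
    ("C18:0/C20:1-CE", [(18, 0), (20, 1)]),
    ("C19:0-CE", [(19, 0)]),
    ("C20:0/C22:1-CE", [(20, 0), (22, 1)]),
    ("C21:0-CE", [(21, 0)]),
    ("C22:0/C24:1-CE", [(22, 0), (24, 1)]),
    ("C23:0-CE", [(23, 0)]),
    ("C24:0/C26:1-CE", [(24, 0), (26, 1)]),
    ("C25:0-CE", [(25, 0)]),
    ("C26:0/C28:1-CE", [(26, 0), (28, 1)]),
    ("C27:0-CE", [(27, 0)]),
    ("C28:0/C30:1-CE", [(28, 0), (30, 1)]),
    ("C29:0-CE", [(29, 0)]),
    ("C30:0/C32:1-CE", [(30, 0), (32, 1)]),
    ("C34:1-CE", [(34, 1)]),
]

#: Retention-time window of the CE elution region (min), covering
#: equivalent chain lengths 8 (CE 10:1) through 34 (CE 34:0).
CE_RT_RANGE = (10.5, 44.0)


@dataclass(frozen=True)
class AssignmentEntry:
    label: str
    target_mz: float
    mz_tol_da: float
    rt_range: tuple[float, float]
    species_id: str | None = None


@dataclass
class AssignmentTable:
    entries: list[AssignmentEntry]

    def lookup(self, mz: float, rt: float) -> AssignmentEntry | None:
        best = None
        for e in self.entries:
            if abs(mz - e.target_mz) <= e.mz_tol_da and e.rt_range[0] <= rt <= e.rt_range[1]:
                if best is None or abs(mz - e.target_mz) < abs(mz - best.target_mz):
                    best = e
        return best


def build_assignment_table(
    registry: LipidRegistry, mz_tol_da: float = 0.025, rt_tol_min: float = 0.5
) -> AssignmentTable:
    """Assignment entries for both detection modes.

    Proton-adduct entries discriminate by m/z (the 50 mDa channel width
    is selective enough) over the whole CE elution band; entries on the
    shared 369.35 fragment channel discriminate by retention time only,
    so they carry narrow RT windows around the nominal times.
    """
    entries: list[AssignmentEntry] = []
    chl = registry.get("Chl")
    entries.append(
        AssignmentEntry("Chl", STEROL_FRAGMENT_MZ, mz_tol_da,
                        (chl.nominal_rt_min - rt_tol_min, chl.nominal_rt_min + rt_tol_min),
                        species_id="Chl")
    )
    for label, members in CE_LABEL_GROUPS:
        for n, x in members:
            sid = ce_id(n, x)
            sp = registry.get(sid)
            entries.append(
                AssignmentEntry(label, registry.channel(sid, "M+H").target_mz,
                                mz_tol_da, CE_RT_RANGE, species_id=sid)
            )
            entries.append(
                AssignmentEntry(label, STEROL_FRAGMENT_MZ, mz_tol_da,
                                (sp.nominal_rt_min - rt_tol_min,
                                 sp.nominal_rt_min + rt_tol_min),
                                species_id=sid)
            )
    for sid, _, _ in _WE_TABLE:
        sp = registry.get(sid)
        entries.append(
            AssignmentEntry(sid, registry.channel(sid, "M+H").target_mz,
                            mz_tol_da, (0.0, 60.0), species_id=sid)
        )
    return AssignmentTable(entries)


def assign_peak(mz: float, rt: float, table: AssignmentTable) -> str:
    """Species/group label for an observed peak, or ``unidentified``."""
    entry = table.lookup(mz, rt)
    return entry.label if entry is not None else UNIDENTIFIED
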