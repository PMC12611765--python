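"""Lipid shorthand chemistry: elemental formulas, monoisotopic masses,
adduct m/z, lipid-name parsing and Kendrick mass analysis.

Shorthand grammar
-----------------
``<class> <chains><mods>`` where the class token is one of the supported
lipid classes (``TG``, ``DG``, ``CE``, ``PC``, ``PE``, ``LPC``, ``LPE``,
``PS``, ``PI``, ``PG``, ``SM``, ``Cer``, ``FA``), optionally carrying an
ether prefix (``O-`` alkyl ether, ``P-`` plasmalogen/vinyl ether) either
on the class (``O-PC 34:1``) or on the chain block (``PC O-34:1``).
Chains are ``C:D`` tokens joined by ``/`` (sn-positions known) or ``_``
(unknown); a single ``C:D`` token denotes a species-level sum
composition.  Oxidation modifications follow in angle brackets, e.g.
``<OOH>``, ``<2OH>``, ``<OH,oxo>`` and may sit on a chain or on the
species.  Free fatty acids are written without a space (``FA18:2<OOH>``),
matching the convention used for oxidized-fragment descriptors.

Monoisotopic atomic masses are pinned to the IUPAC/AME2020 values listed
in ``ATOMIC_MASS`` so every derived number in this package is bit-stable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "ATOMIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ElementalFormula",
    "Adduct",
    "ADDUCTS",
    "ModificationSet",
    "FattyAcyl",
    "LipidSpecies",
    "UnknownLipidClass",
    "MalformedChainToken",
    "UnsupportedClass",
    "ZeroCharge",
    "NonPositiveMz",
    "parse_lipid_name",
    "format_lipid_name",
    "species_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "kendrick_mass_defect",
    "NAMED_COMPOUNDS",
]

# IUPAC 2021 / AME2020 monoisotopic masses, Da
ATOMIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503224,
    "D": 2.01410177812,
    "N": 14.00307400446,
    "O": 15.99491461960,
    "P": 30.97376199786,
    "S": 31.97207117443,
    "Na": 22.98976928196,
}

ELECTRON_MASS = 0.000548579909
PROTON_MASS = ATOMIC_MASS["H"] - ELECTRON_MASS  # 1.00727645...

_ELEMENT_ORDER = ("C", "H", "D", "N", "O", "P", "S", "Na")


class UnknownLipidClass(ValueError):
    """Lipid class token is not in the supported table."""


class MalformedChainToken(ValueError):
    """A chain token does not conform to the C:D[<mods>] grammar."""


class UnsupportedClass(ValueError):
    """No backbone/headgroup composition is defined for this class."""


class ZeroCharge(ValueError):
    """Adduct charge must be non-zero."""


class NonPositiveMz(ValueError):
    """m/z must be positive."""


@dataclass(frozen=True)
class ElementalFormula:
    """Integer element counts; the basis of all mass arithmetic.

    Counts are non-negative; subtraction that would drive any count
    negative raises ``ValueError``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for el, n in self.counts.items():
            if el not in ATOMIC_MASS:
                raise ValueError(f"unsupported element {el!r}")
            if int(n) != n or n < 0:
                raise ValueError(f"count for {el} must be a non-negative integer, got {n}")
            if n:
                clean[el] = int(n)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a plain formula string such as ``C59H90O4`` or ``C10H6D6O4``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            new = counts.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative count for {el}: {self} - {other}"
                )
            counts[el] = new
        return ElementalFormula(counts)

    def __mul__(self, k: int) -> "ElementalFormula":
        if int(k) != k or k < 0:
            raise ValueError("multiplier must be a non-negative integer")
        return ElementalFormula({el: n * int(k) for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __str__(self) -> str:
        parts = []
        for el in _ELEMENT_ORDER:
            n = self.counts.get(el, 0)
            if n:
                parts.append(el + (str(n) if n != 1 else ""))
        return "".join(parts)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Sum of tabulated monoisotopic atomic masses, Da."""
    return sum(ATOMIC_MASS[el] * n for el, n in formula.counts.items())


def _F(text: str) -> ElementalFormula:
    return ElementalFormula.parse(text)


@dataclass(frozen=True)
class Adduct:
    """An ionising adduct: neutral-formula delta plus a signed charge.

    ``gain`` / ``loss`` are the atoms added to / removed from the neutral
    molecule M.  The electron bookkeeping is selected at m/z-computation
    time: the physically correct proton-mass convention (default)
    accounts for the electrons carried by the charge; the hydrogen-atom
    convention ignores them (some instrument software prints such
    values).
    """

    name: str
    charge: int
    gain: ElementalFormula = field(default_factory=ElementalFormula)
    loss: ElementalFormula = field(default_factory=ElementalFormula)

    def __post_init__(self):
        if self.charge == 0:
            raise ZeroCharge("adduct charge must be non-zero")


ADDUCTS: Mapping[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", +1, gain=_F("H")),
    "[M+NH4]+": Adduct("[M+NH4]+", +1, gain=_F("NH4")),
    "[M+Na]+": Adduct("[M+Na]+", +1, gain=_F("Na")),
    "[M-H]-": Adduct("[M-H]-", -1, loss=_F("H")),
}


def get_adduct(name: str) -> Adduct:
    """Look up an adduct by label; accepts ASCII or Unicode minus."""
    key = name.replace("−", "-").replace(" ", "")
    if key not in ADDUCTS:
        raise KeyError(f"unknown adduct {name!r}; known: {sorted(ADDUCTS)}")
    return ADDUCTS[key]


def adduct_mz(
    formula: ElementalFormula,
    adduct: Adduct | str,
    electron_convention: str = "proton",
) -> float:
    """m/z of the adduct ion of the neutral molecule with this formula.

    electron_convention:
      ``"proton"`` (default) — subtract/add electron masses for the
      charge, so [M+H]+ adds the proton mass 1.0072765 Da;
      ``"hydrogen"`` — neutral-atom masses only, so [M+H]+ adds the
      hydrogen atom mass 1.0078250 Da.
    """
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    if electron_convention not in ("proton", "hydrogen"):
        raise ValueError("electron_convention must be 'proton' or 'hydrogen'")
    m = monoisotopic_mass(formula) + monoisotopic_mass(adduct.gain) - monoisotopic_mass(adduct.loss)
    if electron_convention == "proton":
        m -= adduct.charge * ELECTRON_MASS
    return m / abs(adduct.charge)


def kendrick_mass_defect(mz: float, base: str = "CH2") -> tuple[float, float]:
    """Kendrick mass and mass defect of an m/z value.

    The Kendrick mass rescales m/z so the repeating unit (default CH2)
    has integer mass: KM = mz * nominal(base)/exact(base).  The defect is
    nominal(KM) - KM with nominal = nearest integer, so it lies in
    [-0.5, 0.5); members of a CH2-homologous series share a defect.
    """
    if mz <= 0:
        raise NonPositiveMz(f"m/z must be positive, got {mz}")
    f = ElementalFormula.parse(base)
    nominal = round(monoisotopic_mass(f))
    km = mz * nominal / monoisotopic_mass(f)
    defect = round(km) - km
    return km, defect


# ---------------------------------------------------------------------------
# modifications


@dataclass(frozen=True, order=True)
class ModificationSet:
    """Counts of oxidation modifications on a lipid or fatty acyl.

    <OH> hydroxyl (+O), <oxo> keto (+O -2H), <OOH> hydroperoxyl (+2O),
    <epoxy> epoxide (+O).  Double-bond notation in the shorthand is left
    unchanged by any modification.
    """

    n_OH: int = 0
    n_oxo: int = 0
    n_OOH: int = 0
    n_epoxy: int = 0

    def __post_init__(self):
        for v in (self.n_OH, self.n_oxo, self.n_OOH, self.n_epoxy):
            if v < 0:
                raise ValueError("modification counts must be >= 0")

    @property
    def total_groups(self) -> int:
        return self.n_OH + self.n_oxo + self.n_OOH + self.n_epoxy

    @property
    def added_oxygens(self) -> int:
        return self.n_OH + self.n_oxo + 2 * self.n_OOH + self.n_epoxy

    @property
    def delta_formula_oh(self) -> tuple[int, int]:
        """(delta O, delta H) relative to the unmodified species."""
        return self.added_oxygens, -2 * self.n_oxo

    def __bool__(self) -> bool:
        return self.total_groups > 0

    def shorthand(self) -> str:
        if not self:
            return ""
        parts = []
        for count, tag in ((self.n_OH, "OH"), (self.n_oxo, "oxo"),
                           (self.n_OOH, "OOH"), (self.n_epoxy, "epoxy")):
            if count == 1:
                parts.append(tag)
            elif count > 1:
                parts.append(f"{count}{tag}")
        return "<" + ",".join(parts) + ">"

    @classmethod
    def parse(cls, text: str) -> "ModificationSet":
        """Parse the angle-bracket payload, e.g. ``"OOH"`` or ``"2OH,oxo"``."""
        counts = {"OH": 0, "oxo": 0, "OOH": 0, "epoxy": 0}
        aliases = {"keto": "oxo", "Ep": "epoxy"}
        for token in text.split(","):
            token = token.strip()
            if not token:
                continue
            m = re.fullmatch(r"(\d*)([A-Za-z]+)", token)
            if not m:
                raise MalformedChainToken(f"bad modification token {token!r}")
            n = int(m.group(1)) if m.group(1) else 1
            tag = aliases.get(m.group(2), m.group(2))
            if tag not in counts:
                raise MalformedChainToken(f"unknown modification {m.group(2)!r}")
            counts[tag] += n
        return cls(counts["OH"], counts["oxo"], counts["OOH"], counts["epoxy"])


EMPTY_MODS = ModificationSet()


@dataclass(frozen=True)
class FattyAcyl:
    """A fatty acyl/alkyl/alkenyl chain of a glycero- or sphingolipid."""

    carbons: int
    double_bonds: int
    bond_type: str = "acyl"  # acyl | ether | vinyl-ether | amide
    modifications: ModificationSet = EMPTY_MODS

    def __post_init__(self):
        if self.carbons < 2:
            raise MalformedChainToken(f"chain needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0 or self.double_bonds > self.carbons - 2:
            raise MalformedChainToken(
                f"double bonds must be in [0, carbons-2], got {self.carbons}:{self.double_bonds}"
            )
        if self.bond_type not in ("acyl", "ether", "vinyl-ether", "amide"):
            raise ValueError(f"bad bond_type {self.bond_type!r}")

    def free_formula(self) -> ElementalFormula:
        """Formula of the free chain before linkage (acid or fatty alcohol),
        with oxidation modifications applied."""
        n, d = self.carbons, self.double_bonds
        if self.bond_type in ("acyl", "amide"):
            base = {"C": n, "H": 2 * n - 2 * d, "O": 2}
        elif self.bond_type == "ether":
            base = {"C": n, "H": 2 * n + 2 - 2 * d, "O": 1}
        else:  # vinyl-ether: one extra implicit double bond at the ether
            base = {"C": n, "H": 2 * n - 2 * d, "O": 1}
        dO, dH = self.modifications.delta_formula_oh
        base["O"] += dO
        base["H"] += dH
        return ElementalFormula(base)

    def token(self) -> str:
        prefix = {"acyl": "", "amide": "", "ether": "O-", "vinyl-ether": "P-"}[self.bond_type]
        return f"{prefix}{self.carbons}:{self.double_bonds}{self.modifications.shorthand()}"


# class composition table: (core formula, number of chains, condensed
# waters).  Cores are the fully hydrated head+backbone; each ester/
# amide/ether linkage condenses out one H2O against the free chain.
# FA is the free acid itself: one chain, no condensation.
_WATER = _F("H2O")

_CLASS_TABLE: dict[str, tuple[ElementalFormula, int, int]] = {
    "FA": (ElementalFormula(), 1, 0),
    "TG": (_F("C3H8O3"), 3, 3),
    "DG": (_F("C3H8O3"), 2, 2),
    "CE": (_F("C27H46O"), 1, 1),       # cholesterol
    "PC": (_F("C8H20NO6P"), 2, 2),     # glycerophosphocholine
    "LPC": (_F("C8H20NO6P"), 1, 1),
    "PE": (_F("C5H14NO6P"), 2, 2),
    "LPE": (_F("C5H14NO6P"), 1, 1),
    "PS": (_F("C6H14NO8P"), 2, 2),
    "PI": (_F("C9H19O11P"), 2, 2),
    "PG": (_F("C6H15O8P"), 2, 2),
    # sphingolipids: core includes the d18:1 long-chain base (18 C, 1 DB
    # counted in species-level totals) plus the headgroup; one N-amide chain.
    "SM": (_F("C23H49N2O5P"), 1, 1),   # sphingosylphosphorylcholine
    "Cer": (_F("C18H37NO2"), 1, 1),    # sphingosine
}

_SPHINGO_BASE_C = 18
_SPHINGO_BASE_DB = 1
_SPHINGO_CLASSES = ("SM", "Cer")
_ETHER_CAPABLE = ("PC", "PE", "LPC", "LPE")

# named compounds quantified by the targeted assays; treated as opaque
# species with a registry formula
NAMED_COMPOUNDS: Mapping[str, ElementalFormula] = {
    "CoQ10": _F("C59H90O4"),
    "CoQ10H2": _F("C59H92O4"),
    "CoQ10-d6": _F("C59H84D6O4"),
    "CoQ9": _F("C54H82O4"),
    "CoQ9H2": _F("C54H84O4"),
    "CoQ8": _F("C49H74O4"),
    "CoQ8H2": _F("C49H76O4"),
    "vitamin K1": _F("C31H46O2"),
    "MK-4": _F("C31H40O2"),
    "alpha-tocopherol": _F("C29H50O2"),
}


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed shorthand lipid.

    Either chain-resolved (``chains`` given; totals derived) or a
    species-level sum composition (``chains`` is None; totals explicit).
    ``ether`` marks O-/P- subclasses for species-level names.
    ``modifications`` holds species-level oxidation; chain-resolved
    species keep modifications on their chains instead.
    """

    lipid_class: str
    chains: tuple[FattyAcyl, ...] | None = None
    total_carbons: int = 0
    total_double_bonds: int = 0
    ether: str | None = None  # None | "O" | "P"
    modifications: ModificationSet = EMPTY_MODS
    sn_known: bool = True
    named: bool = False       # registry compound (CoQ10 etc.)

    def __post_init__(self):
        if self.named:
            return
        if self.lipid_class not in _CLASS_TABLE:
            raise UnknownLipidClass(f"unknown lipid class {self.lipid_class!r}")
        if self.chains is not None:
            chains = tuple(self.chains)
            object.__setattr__(self, "chains", chains)
            object.__setattr__(self, "total_carbons", sum(c.carbons for c in chains))
            object.__setattr__(
                self, "total_double_bonds", sum(c.double_bonds for c in chains)
            )
            ether = None
            for c in chains:
                if c.bond_type == "ether":
                    ether = "O"
                elif c.bond_type == "vinyl-ether":
                    ether = "P"
            object.__setattr__(self, "ether", ether)

    @property
    def all_modifications(self) -> ModificationSet:
        """Species plus chain modifications pooled."""
        mods = self.modifications
        if self.chains:
            for c in self.chains:
                m = c.modifications
                mods = ModificationSet(
                    mods.n_OH + m.n_OH, mods.n_oxo + m.n_oxo,
                    mods.n_OOH + m.n_OOH, mods.n_epoxy + m.n_epoxy,
                )
        return mods

    @property
    def is_oxidized(self) -> bool:
        return bool(self.all_modifications)

    def name(self) -> str:
        return format_lipid_name(self)

    def __str__(self) -> str:
        return format_lipid_name(self)


def species_formula(species: LipidSpecies) -> ElementalFormula:
    """Elemental formula of a lipid species (chain-resolved or sum
    composition), applying oxidation modification deltas.

    Composition model: class core (backbone + headgroup, fully hydrated)
    plus free-chain formulas, condensing one water per ester/amide/ether
    linkage.  Species-level sphingolipid totals include a d18:1
    long-chain base.
    """
    if species.named:
        return NAMED_COMPOUNDS[species.lipid_class]
    if species.lipid_class not in _CLASS_TABLE:
        raise UnsupportedClass(f"no composition for class {species.lipid_class!r}")
    core, n_chains, n_waters = _CLASS_TABLE[species.lipid_class]

    if species.chains is not None:
        if len(species.chains) != n_chains:
            raise UnsupportedClass(
                f"{species.lipid_class} expects {n_chains} chains, got {len(species.chains)}"
            )
        f = core
        for c in species.chains:
            f = f + c.free_formula()
        f = f - n_waters * _WATER
    else:
        n, d = species.total_carbons, species.total_double_bonds
        if species.lipid_class in _SPHINGO_CLASSES:
            n -= _SPHINGO_BASE_C
            d -= _SPHINGO_BASE_DB
            if n < 2 or d < 0:
                raise MalformedChainToken(
                    f"sphingolipid totals must include the d18:1 base: {species}"
                )
        if n < 2 * n_chains:
            raise MalformedChainToken(f"too few carbons for {species.lipid_class}: {n}")
        # all-acyl sum composition: free acids condensed
        f = core + ElementalFormula({"C": n, "H": 2 * n - 2 * d, "O": 2 * n_chains}) - n_waters * _WATER
        if species.ether == "O":
            f = f + _F("H2") - _F("O")
        elif species.ether == "P":
            f = f - _F("O")
    dO, dH = species.modifications.delta_formula_oh
    counts = dict(f.counts)
    counts["O"] = counts.get("O", 0) + dO
    counts["H"] = counts.get("H", 0) + dH
    return ElementalFormula(counts)


# ---------------------------------------------------------------------------
# parsing / formatting

_CHAIN_RE = re.compile(r"^(O-|P-)?(\d+):(\d+)(?:<([^>]*)>)?$")


def _parse_chain(token: str, bond_type_default: str = "acyl") -> FattyAcyl:
    m = _CHAIN_RE.match(token)
    if not m:
        raise MalformedChainToken(f"bad chain token {token!r}")
    prefix, c, d, mods = m.groups()
    bond_type = {"O-": "ether", "P-": "vinyl-ether", None: bond_type_default}[prefix]
    return FattyAcyl(
        int(c), int(d), bond_type,
        ModificationSet.parse(mods) if mods else EMPTY_MODS,
    )


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse shorthand such as ``TG 18:1/18:1/18:1``, ``CE 20:4<OOH>``,
    ``PC O-34:1``, ``FA18:2<OOH>`` or a named compound (``CoQ10``)."""
    text = name.strip()
    if text in NAMED_COMPOUNDS:
        return LipidSpecies(lipid_class=text, named=True)

    m = re.match(r"^(O-|P-)?([A-Za-z]+)\s*(.*)$", text)
    if not m:
        raise UnknownLipidClass(f"cannot parse lipid name {name!r}")
    class_prefix, cls, rest = m.groups()
    if cls not in _CLASS_TABLE:
        raise UnknownLipidClass(f"unknown lipid class {cls!r} in {name!r}")
    rest = rest.strip()
    if not rest:
        raise MalformedChainToken(f"missing chain composition in {name!r}")

    # species-level trailing modifications, e.g. "TG 56:6<OOH>" — only
    # when there is a single species-level token (no separators)
    sep = "/" if "/" in rest else ("_" if "_" in rest else None)
    if sep:
        tokens = rest.split(sep)
        chains = []
        for i, tok in enumerate(tokens):
            chain = _parse_chain(tok)
            if class_prefix and i == 0 and chain.bond_type == "acyl":
                chain = replace(chain, bond_type={"O-": "ether", "P-": "vinyl-ether"}[class_prefix])
            chains.append(chain)
        if cls in _SPHINGO_CLASSES:
            # chain tokens are LCB then N-acyl; model N-acyl as amide on a
            # fixed d18:1 base (core) — require the base token to be 18:1
            if len(chains) != 2 or (chains[0].carbons, chains[0].double_bonds) != (
                _SPHINGO_BASE_C, _SPHINGO_BASE_DB,
            ):
                raise MalformedChainToken(
                    f"{cls} chain-resolved names use a d18:1 base, got {name!r}"
                )
            chains = [replace(chains[1], bond_type="amide")]
        n_expected = _CLASS_TABLE[cls][1]
        if cls not in _SPHINGO_CLASSES and len(chains) != n_expected:
            raise MalformedChainToken(
                f"{cls} expects {n_expected} chains, got {len(chains)} in {name!r}"
            )
        return LipidSpecies(lipid_class=cls, chains=tuple(chains), sn_known=(sep == "/"))

    mm = _CHAIN_RE.match(rest)
    if not mm:
        raise MalformedChainToken(f"bad composition {rest!r} in {name!r}")
    chain_prefix, c, d, mods = mm.groups()
    prefix = class_prefix or chain_prefix
    ether = {"O-": "O", "P-": "P", None: None}[prefix]
    modset = ModificationSet.parse(mods) if mods else EMPTY_MODS
    n_links = _CLASS_TABLE[cls][1]
    if n_links == 1 and cls not in _SPHINGO_CLASSES:
        # single-chain classes are inherently chain-resolved
        bond_type = {"O": "ether", "P": "vinyl-ether", None: "acyl"}[ether]
        chain = FattyAcyl(int(c), int(d), bond_type, modset)
        return LipidSpecies(lipid_class=cls, chains=(chain,))
    return LipidSpecies(
        lipid_class=cls,
        total_carbons=int(c),
        total_double_bonds=int(d),
        ether=ether,
        modifications=modset,
    )


def format_lipid_name(species: LipidSpecies) -> str:
    """Canonical shorthand for a species; inverse of :func:`parse_lipid_name`."""
    if species.named:
        return species.lipid_class
    cls = species.lipid_class
    spacer = "" if cls == "FA" else " "
    if species.chains is not None:
        if cls in _SPHINGO_CLASSES:
            base = f"{_SPHINGO_BASE_C}:{_SPHINGO_BASE_DB}"
            body = base + "/" + species.chains[0].token()
        else:
            sep = "/" if species.sn_known else "_"
            body = sep.join(c.token() for c in species.chains)
        return f"{cls}{spacer}{body}"
    prefix = {"O": "O-", "P": "P-", None: ""}[species.ether]
    return (
        f"{cls}{spacer}{prefix}{species.total_carbons}:{species.total_double_bonds}"
        f"{species.modifications.shorthand()}"
    )
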