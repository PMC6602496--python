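"""Amino-acid and modification mass bookkeeping and theoretical b/y fragment m/z.

All masses are monoisotopic (the predicted peaks are centroided monoisotopic
fragment peaks); average masses are unsupported. Modification positions follow
the PEPREC convention: ``0`` is the peptide N-terminus, residues are 1-based,
and ``n + 1`` is the C-terminus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Iterable, Mapping

import yaml
from pyteomics import mass as _ptmass

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "CANONICAL_RESIDUES",
    "ResidueMassTable",
    "Modification",
    "ModificationRegistry",
    "Peptide",
    "FragmentIon",
    "FragmentConfig",
    "PeptideError",
    "load_residue_masses",
    "parse_modification_string",
    "format_modification_string",
    "peptide_neutral_mass",
    "fragment_mz",
    "theoretical_fragments",
]

#: Mass of a proton in Da (CODATA).
PROTON_MASS: float = 1.00727646688
#: Monoisotopic mass of H2O in Da.
WATER_MASS: float = _ptmass.calculate_mass(formula="H2O")

CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

N_TERM = "N-term"
C_TERM = "C-term"

#: Default peptide length bounds (inclusive).
MIN_PEPTIDE_LENGTH = 3
MAX_PEPTIDE_LENGTH = 100


class PeptideError(ValueError):
    """Raised for invalid peptides, modifications or fragment requests."""


@dataclass(frozen=True)
class ResidueMassTable:
    """Immutable map from canonical residue letter to monoisotopic residue mass (Da).

    ``water`` and ``proton`` are carried along so all fragment arithmetic can be
    done from one object. Leucine and isoleucine share a mass; they remain
    distinct letters for sequence purposes.
    """

    masses: Mapping[str, float]
    water: float = WATER_MASS
    proton: float = PROTON_MASS

    def __post_init__(self) -> None:
        object.__setattr__(self, "masses", MappingProxyType(dict(self.masses)))
        missing = set(CANONICAL_RESIDUES) - set(self.masses)
        if missing:
            raise PeptideError(f"residue mass table missing residues: {sorted(missing)}")
        for aa, m in self.masses.items():
            if not m > 0:
                raise PeptideError(f"non-positive mass for residue {aa!r}: {m}")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.masses[residue]
        except KeyError:
            raise PeptideError(f"unknown residue {residue!r}") from None


_DEFAULT_TABLE = ResidueMassTable(
    {aa: _ptmass.std_aa_mass[aa] for aa in CANONICAL_RESIDUES}
)


def load_residue_masses() -> ResidueMassTable:
    """Return the canonical monoisotopic residue-mass table (singleton)."""
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class Modification:
    """A named mass modification.

    ``targets`` holds residue letters and/or the anchors ``"N-term"`` /
    ``"C-term"``. ``fixed`` marks modifications a model flavor applies
    automatically (isobaric labels); ``is_label`` marks isobaric label
    chemistry for feature counting and relabeling.
    """

    name: str
    delta_mass: float
    targets: frozenset[str]
    fixed: bool = False
    is_label: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise PeptideError("modification name must be nonempty")
        if not self.targets:
            raise PeptideError(f"modification {self.name!r} has no targets")
        object.__setattr__(self, "targets", frozenset(self.targets))


# Built-in modifications. Monoisotopic deltas from Unimod elemental compositions:
#   TMT6plex        H(20) C(8) 13C(4) 15N(1) N(1) O(2)  -> 229.162932
#   iTRAQ4plex      H(12) C(4) 13C(3) 15N(1) N(1) O(1)  -> 144.102063
#   Phospho         H(1) O(3) P(1)                      ->  79.966331
#   Carbamidomethyl H(3) C(2) N(1) O(1)                 ->  57.021464
#   Oxidation       O(1)                                ->  15.994915
_BUILTIN_MODS = (
    Modification("TMT6plex", 229.162932, frozenset({N_TERM, "K"}), fixed=True, is_label=True),
    Modification("iTRAQ4plex", 144.102063, frozenset({N_TERM, "K"}), fixed=True, is_label=True),
    Modification("Phospho", 79.966331, frozenset({"S", "T", "Y"})),
    Modification("Carbamidomethyl", 57.021464, frozenset({"C"})),
    Modification("Oxidation", 15.994915, frozenset({"M"})),
)


class ModificationRegistry:
    """Registry of known modifications, keyed by unique name.

    Extensible from a YAML config (see :meth:`from_yaml`); each entry gives a
    name, either an explicit ``delta_mass`` or an elemental ``composition``
    (parsed with pyteomics), a list of targets, and optional flags.
    """

    def __init__(self, mods: Iterable[Modification] = ()) -> None:
        self._mods: dict[str, Modification] = {}
        for mod in mods:
            self.add(mod)

    @classmethod
    def default(cls) -> "ModificationRegistry":
        return cls(_BUILTIN_MODS)

    def add(self, mod: Modification) -> None:
        if mod.name in self._mods:
            raise PeptideError(f"duplicate modification name {mod.name!r}")
        self._mods[mod.name] = mod

    def __getitem__(self, name: str) -> Modification:
        try:
            return self._mods[name]
        except KeyError:
            known = ", ".join(sorted(self._mods))
            raise PeptideError(
                f"unknown modification {name!r} (known: {known})"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._mods

    def __iter__(self):
        return iter(self._mods.values())

    def names(self) -> list[str]:
        return sorted(self._mods)

    @classmethod
    def from_yaml(cls, path, include_builtin: bool = True) -> "ModificationRegistry":
        """Load a registry from a YAML file.

        Expected structure::

            modifications:
              - name: MyLabel
                composition: H3C2NO   # or: delta_mass: 57.021464
                targets: [N-term, K]
                fixed: true
                is_label: true
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        reg = cls.default() if include_builtin else cls()
        for entry in doc.get("modifications", []):
            if "delta_mass" in entry:
                delta = float(entry["delta_mass"])
            elif "composition" in entry:
                delta = _ptmass.calculate_mass(formula=entry["composition"])
            else:
                raise PeptideError(
                    f"modification entry {entry.get('name')!r} needs delta_mass or composition"
                )
            reg.add(
                Modification(
                    name=entry["name"],
                    delta_mass=delta,
                    targets=frozenset(entry["targets"]),
                    fixed=bool(entry.get("fixed", False)),
                    is_label=bool(entry.get("is_label", False)),
                )
            )
        return reg


DEFAULT_REGISTRY = ModificationRegistry.default()


@dataclass(frozen=True)
class Peptide:
    """A modified peptide sequence with its precursor charge.

    ``modifications`` is a tuple of ``(position, name)`` pairs with position 0
    meaning N-terminus, 1..n the residues, and n+1 the C-terminus. At most one
    modification per position.
    """

    sequence: str
    modifications: tuple[tuple[int, str], ...] = ()
    charge: int = 2

    def __post_init__(self) -> None:
        seq = self.sequence
        n = len(seq)
        if not (MIN_PEPTIDE_LENGTH <= n <= MAX_PEPTIDE_LENGTH):
            raise PeptideError(
                f"peptide length {n} outside bounds "
                f"[{MIN_PEPTIDE_LENGTH}, {MAX_PEPTIDE_LENGTH}]: {seq!r}"
            )
        for i, aa in enumerate(seq):
            if aa not in CANONICAL_RESIDUES:
                raise PeptideError(
                    f"invalid residue {aa!r} at position {i + 1} in {seq!r}"
                )
        if self.charge < 1:
            raise PeptideError(f"precursor charge must be >= 1, got {self.charge}")
        mods = tuple(sorted((int(p), str(m)) for p, m in self.modifications))
        positions = [p for p, _ in mods]
        if len(set(positions)) != len(positions):
            raise PeptideError(f"more than one modification at a position: {mods}")
        for p, name in mods:
            if not (0 <= p <= n + 1):
                raise PeptideError(
                    f"modification position {p} out of range for length-{n} peptide"
                )
        object.__setattr__(self, "modifications", mods)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def key(self) -> tuple[str, tuple[tuple[int, str], ...], int]:
        """Identity key: (sequence, sorted modifications, precursor charge)."""
        return (self.sequence, self.modifications, self.charge)

    def validate_targets(self, registry: ModificationRegistry = DEFAULT_REGISTRY) -> None:
        """Check every modification against its registry target rule."""
        n = len(self.sequence)
        for pos, name in self.modifications:
            mod = registry[name]
            if pos == 0:
                site = N_TERM
            elif pos == n + 1:
                site = C_TERM
            else:
                site = self.sequence[pos - 1]
            if site not in mod.targets:
                raise PeptideError(
                    f"modification {name!r} not allowed at {site} "
                    f"(position {pos}) of {self.sequence!r}"
                )

    def with_modification(self, pos: int, name: str) -> "Peptide":
        return replace(self, modifications=self.modifications + ((pos, name),))


@dataclass(frozen=True)
class FragmentIon:
    """A b or y fragment ion coordinate with its m/z."""

    series: str  # "b" or "y"
    index: int  # 1 .. n-1
    charge: int
    mz: float

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise PeptideError(f"unknown ion series {self.series!r}")
        if self.index < 1 or self.charge < 1 or self.mz <= 0:
            raise PeptideError(f"invalid fragment ion {self!r}")


@dataclass(frozen=True)
class FragmentConfig:
    """Which fragment charges to enumerate.

    Default is singly charged fragments only; when ``include_doubly_charged``
    is set, 2+ fragments are added for precursors of charge >= 3.
    """

    include_doubly_charged: bool = False


def parse_modification_string(
    s: str, registry: ModificationRegistry = DEFAULT_REGISTRY
) -> list[tuple[int, Modification]]:
    """Parse a PEPREC-style modification string.

    ``"-"`` means no modifications; otherwise ``pos|name`` pairs joined with
    ``|``, e.g. ``"0|TMT6plex|20|TMT6plex"``. Position range checking is
    deferred to :class:`Peptide` validation.
    """
    s = s.strip()
    if s in ("-", ""):
        return []
    fields = s.split("|")
    if len(fields) % 2 != 0:
        raise PeptideError(f"malformed modification string (odd field count): {s!r}")
    out: list[tuple[int, Modification]] = []
    for pos_s, name in zip(fields[::2], fields[1::2]):
        try:
            pos = int(pos_s)
        except ValueError:
            raise PeptideError(f"non-integer modification position {pos_s!r} in {s!r}") from None
        out.append((pos, registry[name]))
    return out


def format_modification_string(p: Peptide) -> str:
    """Inverse of :func:`parse_modification_string` for a peptide's mods."""
    if not p.modifications:
        return "-"
    return "|".join(f"{pos}|{name}" for pos, name in p.modifications)


def _seq_mods(p: "Peptide | str") -> tuple[str, tuple[tuple[int, str], ...]]:
    """Accept a Peptide or a bare sequence string (no mods, no length bounds).

    The string form exists so mass arithmetic stays usable for fragments and
    degenerate cases (single residues, dipeptides) that fall below the
    request-level peptide length bounds.
    """
    if isinstance(p, str):
        return p, ()
    return p.sequence, p.modifications


def _mod_deltas(
    mods: tuple[tuple[int, str], ...], registry: ModificationRegistry
) -> list[tuple[int, float]]:
    return [(pos, registry[name].delta_mass) for pos, name in mods]


def peptide_neutral_mass(
    p: Peptide | str,
    table: ResidueMassTable | None = None,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> float:
    """Monoisotopic neutral mass: residue masses + water + modification deltas."""
    table = table or _DEFAULT_TABLE
    sequence, mods = _seq_mods(p)
    total = table.water
    for i, aa in enumerate(sequence):
        try:
            total += table[aa]
        except PeptideError:
            raise PeptideError(
                f"residue {aa!r} at position {i + 1} not in mass table"
            ) from None
    total += sum(d for _, d in _mod_deltas(mods, registry))
    return total


def fragment_mz(
    p: Peptide | str,
    series: str,
    index: int,
    frag_charge: int = 1,
    table: ResidueMassTable | None = None,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> float:
    """m/z of the b- or y-ion at ``index`` (1..n-1) with ``frag_charge`` protons.

    N-terminal modifications count toward b ions, C-terminal toward y ions,
    and residue modifications toward whichever fragment contains the residue.
    """
    table = table or _DEFAULT_TABLE
    sequence, mods = _seq_mods(p)
    n = len(sequence)
    if not (1 <= index <= n - 1):
        raise PeptideError(f"fragment index {index} out of range for length {n}")
    if frag_charge < 1:
        raise PeptideError(f"fragment charge must be >= 1, got {frag_charge}")
    deltas = _mod_deltas(mods, registry)
    if series == "b":
        neutral = sum(table[aa] for aa in sequence[:index])
        neutral += sum(d for pos, d in deltas if pos <= index)  # incl. N-term (pos 0)
    elif series == "y":
        neutral = sum(table[aa] for aa in sequence[n - index:]) + table.water
        neutral += sum(d for pos, d in deltas if pos > n - index)  # incl. C-term (pos n+1)
    else:
        raise PeptideError(f"unknown ion series {series!r}")
    return (neutral + frag_charge * table.proton) / frag_charge


def theoretical_fragments(
    p: Peptide,
    config: FragmentConfig = FragmentConfig(),
    table: ResidueMassTable | None = None,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> list[FragmentIon]:
    """Complete b1..b(n-1), y1..y(n-1) ion list, sorted by series then index.

    2+ fragments are appended per series (after the 1+ ions) when enabled and
    the precursor charge is at least 3.
    """
    charges = [1]
    if config.include_doubly_charged and p.charge >= 3:
        charges.append(2)
    n = len(p.sequence)
    out: list[FragmentIon] = []
    for series in ("b", "y"):
        for z, i in itertools.product(charges, range(1, n)):
            out.append(
                FragmentIon(series, i, z, fragment_mz(p, series, i, z, table, registry))
            )
    return out
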