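"""Deterministic feature encoding of (peptide, fragmentation site) pairs.

Each cleavage site ``i`` (between residues i and i+1, 1-based) is encoded as a
fixed-length numeric vector combining global peptide descriptors, aggregate
physicochemical properties of the prefix (b-side) and suffix (y-side), local
residue properties around the site, and modification mass summaries. No
feature derives from the observed spectrum or from collision energy: the
encoder sees only the peptide, the site and the precursor charge, so trained
models transfer to spectra of any (unknown) collision energy at the cost of
averaging over it.

The schema is versioned; model archives record the version they were trained
with and refuse to load under a different encoder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .chem import (
    CANONICAL_RESIDUES,
    DEFAULT_REGISTRY,
    ModificationRegistry,
    Peptide,
    PeptideError,
)

__all__ = [
    "FEATURE_SCHEMA_VERSION",
    "PROPERTY_NAMES",
    "PropertyTable",
    "default_property_table",
    "feature_names",
    "encode_fragment_site",
    "encode_peptide_matrix",
]

FEATURE_SCHEMA_VERSION = "pb-1"

PROPERTY_NAMES = ("basicity", "hydrophobicity", "helicity", "pI")

_MAX_CHARGE_ONEHOT = 6

# Residue physicochemical scales, one row per canonical residue:
#   basicity       — gas-phase basicity, min-max normalized to [0, 1]
#   hydrophobicity — Kyte–Doolittle GRAVY values
#   helicity       — helix propensity (1 = strongest former), Pace–Scholtz derived
#   pI             — isoelectric point of the free amino acid
_PROPERTY_ROWS = {
    #        bas    hyd    hel    pI
    "A": (0.25, 1.80, 1.00, 6.00),
    "C": (0.29, 2.50, 0.54, 5.07),
    "D": (0.42, -3.50, 0.46, 2.77),
    "E": (0.48, -3.50, 0.73, 3.22),
    "F": (0.38, 2.80, 0.59, 5.48),
    "G": (0.00, -0.40, 0.00, 5.97),
    "H": (0.84, -3.20, 0.52, 7.59),
    "I": (0.34, 4.50, 0.52, 6.02),
    "K": (0.91, -3.90, 0.74, 9.74),
    "L": (0.34, 3.80, 0.79, 5.98),
    "M": (0.40, 1.90, 0.76, 5.74),
    "N": (0.56, -3.50, 0.39, 5.41),
    "P": (0.60, -1.60, 0.06, 6.30),
    "Q": (0.58, -3.50, 0.61, 5.65),
    "R": (1.00, -4.50, 0.68, 10.76),
    "S": (0.36, -0.80, 0.45, 5.68),
    "T": (0.39, -0.70, 0.48, 5.60),
    "V": (0.31, 4.20, 0.56, 5.96),
    "W": (0.48, -0.90, 0.51, 5.89),
    "Y": (0.41, -1.30, 0.49, 5.66),
}


@dataclass(frozen=True)
class PropertyTable:
    """Residue → named physicochemical property vector."""

    values: Mapping[str, tuple[float, ...]]
    names: tuple[str, ...] = PROPERTY_NAMES

    def __post_init__(self) -> None:
        for aa in CANONICAL_RESIDUES:
            if aa not in self.values:
                raise PeptideError(f"property table missing residue {aa!r}")
            row = self.values[aa]
            if len(row) != len(self.names) or not all(np.isfinite(row)):
                raise PeptideError(f"bad property row for residue {aa!r}: {row}")

    def row(self, aa: str) -> np.ndarray:
        return np.asarray(self.values[aa], dtype=float)

    @classmethod
    def from_csv(cls, path) -> "PropertyTable":
        """Load from a long-format CSV with columns residue, property, value."""
        df = pd.read_csv(path)
        wide = df.pivot(index="residue", columns="property", values="value")
        names = tuple(wide.columns)
        values = {aa: tuple(wide.loc[aa]) for aa in wide.index}
        return cls(values=values, names=names)


_DEFAULT_TABLE = PropertyTable(_PROPERTY_ROWS)


def default_property_table() -> PropertyTable:
    return _DEFAULT_TABLE


def feature_names(table: PropertyTable = _DEFAULT_TABLE) -> list[str]:
    """Ordered feature schema. Length is fixed for all peptides."""
    names = ["length", "site_index", "relative_position"]
    names += [f"charge_{z}" for z in range(1, _MAX_CHARGE_ONEHOT + 1)]
    names += [f"composition_{aa}" for aa in CANONICAL_RESIDUES]
    for region in ("prefix", "suffix"):
        for prop in table.names:
            for stat in ("sum", "min", "max", "mean"):
                names.append(f"{region}_{prop}_{stat}")
    for offset in (-1, 0, 1, 2):
        for prop in table.names:
            names.append(f"site{offset:+d}_{prop}")
    names += ["prefix_mod_mass", "suffix_mod_mass", "n_phospho", "n_label"]
    return names


_N_FEATURES = len(feature_names())


def encode_fragment_site(
    p: Peptide,
    index: int,
    table: PropertyTable = _DEFAULT_TABLE,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> np.ndarray:
    """Encode cleavage site ``index`` (1..n−1) of peptide ``p``.

    Deterministic and invariant to modification list ordering; out-of-range
    local positions are zero-padded.
    """
    n = len(p.sequence)
    if not (1 <= index <= n - 1):
        raise PeptideError(f"site index {index} out of range for length {n}")
    props = np.stack([table.row(aa) for aa in p.sequence])  # (n, P)
    out: list[float] = [float(n), float(index), index / n]

    z = min(p.charge, _MAX_CHARGE_ONEHOT)
    out += [1.0 if z == k else 0.0 for k in range(1, _MAX_CHARGE_ONEHOT + 1)]

    counts = {aa: 0 for aa in CANONICAL_RESIDUES}
    for aa in p.sequence:
        counts[aa] += 1
    out += [float(counts[aa]) for aa in CANONICAL_RESIDUES]

    for block in (props[:index], props[index:]):
        for c in range(props.shape[1]):
            col = block[:, c]
            out += [float(col.sum()), float(col.min()), float(col.max()), float(col.mean())]

    for offset in (-1, 0, 1, 2):
        ridx = index + offset  # 1-based residue position
        if 1 <= ridx <= n:
            out += list(props[ridx - 1])
        else:
            out += [0.0] * len(table.names)

    prefix_mass = suffix_mass = 0.0
    n_phospho = n_label = 0
    for pos, name in p.modifications:
        mod = registry[name]
        if pos <= index:  # N-term (0) and residues 1..index belong to the prefix
            prefix_mass += mod.delta_mass
        else:  # residues index+1..n and C-term (n+1)
            suffix_mass += mod.delta_mass
        if name.startswith("Phospho"):
            n_phospho += 1
        if mod.is_label:
            n_label += 1
    out += [prefix_mass, suffix_mass, float(n_phospho), float(n_label)]

    vec = np.asarray(out, dtype=float)
    assert vec.size == _N_FEATURES
    return vec


def encode_peptide_matrix(
    p: Peptide,
    table: PropertyTable = _DEFAULT_TABLE,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> np.ndarray:
    """Stack of per-site feature vectors; shape (n−1, n_features)."""
    return np.stack(
        [encode_fragment_site(p, i, table, registry) for i in range(1, len(p.sequence))]
    )
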