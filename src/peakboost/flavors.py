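"""Model flavors: instrument/fragmentation/label contexts with their own predictors.

Six built-in flavors cover collision-based fragmentation on three instrument
classes and the isobaric-label variants. A flavor binds the fixed label
modifications its training data carries and a default peak-matching tolerance
appropriate for its mass analyzer (ion traps are low resolution, Orbitrap and
QTOF high resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .chem import DEFAULT_REGISTRY, ModificationRegistry, Peptide, PeptideError

__all__ = [
    "ModelFlavor",
    "FLAVORS",
    "get_flavor",
    "apply_flavor_labels",
    "relabel_for_flavor",
]


@dataclass(frozen=True)
class ModelFlavor:
    name: str
    fragmentation_method: str
    mass_analyzer: str
    #: Names of label modifications applied automatically at the N-terminus
    #: and every lysine.
    fixed_labels: tuple[str, ...]
    #: Default annotation tolerance in Da.
    tolerance_da: float


_FLAVOR_LIST = (
    ModelFlavor("CID", "CID", "Linear ion trap", (), 0.5),
    ModelFlavor("HCD", "HCD", "Orbitrap", (), 0.02),
    ModelFlavor("TripleTOF5600", "CID", "Quadrupole Time-of-Flight", (), 0.02),
    ModelFlavor("TMT", "HCD", "Orbitrap", ("TMT6plex",), 0.02),
    ModelFlavor("iTRAQ", "HCD", "Orbitrap", ("iTRAQ4plex",), 0.02),
    ModelFlavor("iTRAQphospho", "HCD", "Orbitrap", ("iTRAQ4plex",), 0.02),
)

FLAVORS: dict[str, ModelFlavor] = {f.name: f for f in _FLAVOR_LIST}


def get_flavor(name: str) -> ModelFlavor:
    try:
        return FLAVORS[name]
    except KeyError:
        raise PeptideError(
            f"unknown model flavor {name!r} (available: {', '.join(FLAVORS)})"
        ) from None


def apply_flavor_labels(
    p: Peptide,
    flavor: ModelFlavor,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> Peptide:
    """Add the flavor's fixed label at the N-terminus and at every lysine.

    Identity for unlabeled flavors and idempotent: positions that already
    carry the same label are left alone. A position carrying a *different*
    modification raises, listing the clash.
    """
    if not flavor.fixed_labels:
        return p
    existing = dict(p.modifications)
    new_mods = list(p.modifications)
    for label_name in flavor.fixed_labels:
        registry[label_name]  # fail fast on unknown label
        sites = [0] + [i + 1 for i, aa in enumerate(p.sequence) if aa == "K"]
        for pos in sites:
            have = existing.get(pos)
            if have is None:
                new_mods.append((pos, label_name))
                existing[pos] = label_name
            elif have != label_name:
                raise PeptideError(
                    f"cannot apply {label_name!r} at position {pos} of "
                    f"{p.sequence!r}: already modified with {have!r}"
                )
    return replace(p, modifications=tuple(new_mods))


def relabel_for_flavor(
    p: Peptide,
    flavor: ModelFlavor,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> Peptide:
    """Strip existing label modifications, then apply the flavor's own labels.

    Used for cross-flavor prediction (asking, e.g., a TMT-trained model about a
    peptide from an iTRAQ dataset): the model is shown the peptide in the label
    state it was trained on, while annotation of the observed spectrum keeps
    the peptide's true labels.
    """
    kept = tuple(
        (pos, name)
        for pos, name in p.modifications
        if not (name in registry and registry[name].is_label)
    )
    return apply_flavor_labels(replace(p, modifications=kept), flavor, registry)
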