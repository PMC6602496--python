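"""Turn (peptide, observed spectrum) pairs into per-fragment intensity targets.

The regression target for each fragment position is the log2 of its
TIC-normalized peak intensity, floored at ``log2(epsilon)``. TIC normalization
divides by the summed intensity of *all* observed peaks (matched or not), so
targets are comparable across spectra regardless of match rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import (
    DEFAULT_REGISTRY,
    FragmentConfig,
    FragmentIon,
    ModificationRegistry,
    Peptide,
    theoretical_fragments,
)
from .io import ObservedSpectrum, PeptideRecord

__all__ = [
    "AnnotationConfig",
    "IntensityTargetVector",
    "match_peaks",
    "tic_normalize",
    "log_transform",
    "extract_targets",
    "filter_unique_peptides",
]


@dataclass(frozen=True)
class AnnotationConfig:
    """Peak-matching and target-transform parameters.

    ``tolerance`` is interpreted in Da or ppm according to ``unit``. Defaults
    (0.02 Da) suit high-resolution analyzers (Orbitrap, QTOF); ion-trap CID
    spectra need ~0.5 Da. ``epsilon`` floors the normalized intensity before
    the log2 transform, bounding the target's dynamic range to about 10 log2
    units.
    """

    tolerance: float = 0.02
    unit: str = "Da"  # "Da" or "ppm"
    epsilon: float = 0.001
    fragments: FragmentConfig = field(default_factory=FragmentConfig)

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not (0 < self.epsilon < 1):
            raise ValueError("epsilon must be in (0, 1)")
        if self.unit not in ("Da", "ppm"):
            raise ValueError(f"tolerance unit must be Da or ppm, got {self.unit!r}")

    def tolerance_da(self, mz: float) -> float:
        return self.tolerance if self.unit == "Da" else self.tolerance * 1e-6 * mz

    @property
    def floor(self) -> float:
        return float(np.log2(self.epsilon))


@dataclass
class IntensityTargetVector:
    """Processed intensities for one ion series of one peptide.

    ``values[i]`` is the log2 TIC-normalized intensity of the (i+1)-th
    fragment of the series; unmatched positions hold exactly ``log2(epsilon)``
    and are flagged in ``matched_mask``.
    """

    series: str
    values: np.ndarray
    matched_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.matched_mask = np.asarray(self.matched_mask, dtype=bool)
        if self.values.shape != self.matched_mask.shape:
            raise ValueError("values and matched_mask must have equal shapes")


def match_peaks(
    spectrum: ObservedSpectrum,
    fragments: list[FragmentIon],
    cfg: AnnotationConfig = AnnotationConfig(),
) -> np.ndarray:
    """Raw intensity of the matched peak for each fragment (0 when unmatched).

    Each observed peak is assigned to at most one fragment: candidate
    (fragment, peak) pairs within tolerance are resolved greedily by m/z
    distance, ties broken toward the b series and then the lower fragment
    index.
    """
    mz = spectrum.mz
    out = np.zeros(len(fragments))
    if mz.size == 0 or not fragments:
        return out
    candidates = []  # (distance, series_rank, index, frag_pos, peak_idx)
    for fpos, frag in enumerate(fragments):
        tol = cfg.tolerance_da(frag.mz)
        lo = np.searchsorted(mz, frag.mz - tol, side="left")
        hi = np.searchsorted(mz, frag.mz + tol, side="right")
        for j in range(lo, hi):
            candidates.append(
                (abs(mz[j] - frag.mz), 0 if frag.series == "b" else 1, frag.index, fpos, j)
            )
    candidates.sort()
    used_frag: set[int] = set()
    used_peak: set[int] = set()
    for _, _, _, fpos, j in candidates:
        if fpos in used_frag or j in used_peak:
            continue
        used_frag.add(fpos)
        used_peak.add(j)
        out[fpos] = spectrum.intensity[j]
    return out


def tic_normalize(raw: np.ndarray, spectrum_tic: float) -> np.ndarray:
    """Divide matched intensities by the spectrum's total ion current."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw intensities must be non-negative")
    if spectrum_tic <= 0:
        raise ValueError("cannot TIC-normalize an empty spectrum (zero total ion current)")
    return raw / spectrum_tic


def log_transform(normalized: np.ndarray, epsilon: float = 0.001) -> np.ndarray:
    """log2 with a floor: ``log2(max(value, epsilon))``."""
    normalized = np.asarray(normalized, dtype=float)
    return np.log2(np.maximum(normalized, epsilon))


def extract_targets(
    p: Peptide,
    spectrum: ObservedSpectrum,
    cfg: AnnotationConfig = AnnotationConfig(),
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> tuple[IntensityTargetVector, IntensityTargetVector]:
    """Match, TIC-normalize and log-transform; returns (b, y) target vectors.

    Targets are defined on singly charged fragments, so each vector has length
    n − 1 regardless of the fragment-charge configuration used elsewhere.
    """
    fragments = theoretical_fragments(p, FragmentConfig(), registry=registry)
    raw = match_peaks(spectrum, fragments, cfg)
    normalized = tic_normalize(raw, spectrum.tic)
    values = log_transform(normalized, cfg.epsilon)
    n = len(p.sequence)
    out = []
    for series in ("b", "y"):
        idx = [i for i, f in enumerate(fragments) if f.series == series and f.charge == 1]
        assert len(idx) == n - 1
        out.append(
            IntensityTargetVector(
                series=series,
                values=values[idx],
                matched_mask=raw[idx] > 0,
            )
        )
    return out[0], out[1]


def filter_unique_peptides(
    pairs: list[tuple[PeptideRecord, ObservedSpectrum]],
) -> list[tuple[PeptideRecord, ObservedSpectrum]]:
    """Keep one spectrum per (sequence, modifications, charge) key.

    Among duplicates the spectrum with the highest total ion current is
    retained (a deterministic rule; earlier entry wins exact TIC ties).
    Output preserves the input order of the retained entries.
    """
    best: dict[tuple, tuple[int, float]] = {}
    for i, (record, spec) in enumerate(pairs):
        key = record.peptide.key
        tic = spec.tic
        if key not in best or tic > best[key][1]:
            best[key] = (i, tic)
    keep = sorted(i for i, _ in best.values())
    return [pairs[i] for i in keep]
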