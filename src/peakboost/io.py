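"""Readers and writers for every format the toolkit touches.

Supported formats:

* peptide request tables — CSV with columns ``spec_id, peptide, modifications,
  charge`` (PEPREC-style modification strings, see :mod:`peakboost.chem`);
* MGF (Mascot Generic Format) spectra, via pyteomics;
* NIST-style MSP spectral libraries (hand-written parser/writer; no installed
  library reads MSP);
* BiblioSpec / Skyline SSL + MS2 paired files;
* prediction CSV (one row per fragment ion).

All writers emit peaks in ascending m/z. Write→read round-trips preserve text
fields exactly and numerics to better than 1e-5 relative.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _ptmgf

from .chem import (
    DEFAULT_REGISTRY,
    FragmentIon,
    ModificationRegistry,
    Peptide,
    PeptideError,
    format_modification_string,
    parse_modification_string,
    peptide_neutral_mass,
    PROTON_MASS,
)

__all__ = [
    "ObservedSpectrum",
    "PeptideRecord",
    "PredictedPeaks",
    "read_peptide_table",
    "write_peptide_table",
    "read_mgf",
    "write_mgf",
    "read_msp",
    "read_msp_library",
    "write_msp",
    "read_ssl_ms2",
    "write_ssl_ms2",
    "write_predictions",
]

logger = logging.getLogger(__name__)

PREDICTION_SCALE = 10000.0  # linear predicted intensities rescaled to max peak


@dataclass
class ObservedSpectrum:
    """A centroided peak list with precursor information.

    Peaks are stored as parallel arrays sorted by ascending m/z; intensities
    are non-negative in arbitrary units.
    """

    identifier: str
    precursor_mz: float
    precursor_charge: int | None
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if np.any(self.intensity < 0):
            raise ValueError(f"negative peak intensity in spectrum {self.identifier!r}")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def tic(self) -> float:
        """Total ion current: sum of all peak intensities."""
        return float(self.intensity.sum())

    def __len__(self) -> int:
        return self.mz.size


@dataclass(frozen=True)
class PeptideRecord:
    """A peptide request row, optionally linked to an observed spectrum."""

    spec_id: str
    peptide: Peptide
    spectrum_id: str | None = None


@dataclass(frozen=True)
class PredictedPeaks:
    """Predicted fragment peaks for one peptide, in linear intensity space."""

    peptide: Peptide
    fragments: tuple[FragmentIon, ...]
    linear_intensity: np.ndarray  # aligned with fragments

    def sorted_peaks(self) -> tuple[np.ndarray, np.ndarray]:
        mz = np.array([f.mz for f in self.fragments])
        order = np.argsort(mz, kind="stable")
        return mz[order], np.asarray(self.linear_intensity)[order]


def precursor_mz_of(p: Peptide, registry: ModificationRegistry = DEFAULT_REGISTRY) -> float:
    return (peptide_neutral_mass(p, registry=registry) + p.charge * PROTON_MASS) / p.charge


# ---------------------------------------------------------------------------
# Peptide request CSV (PEPREC dialect)
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("spec_id", "peptide", "modifications", "charge")


def read_peptide_table(
    path, registry: ModificationRegistry = DEFAULT_REGISTRY
) -> tuple[list[PeptideRecord], list[tuple[int, str]]]:
    """Read a peptide request CSV.

    Returns ``(records, rejects)`` where rejects are ``(data_row_number,
    reason)`` pairs (1-based over data rows). A missing required column is
    fatal; per-row problems only reject that row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PeptideError(f"peptide table {path} missing required columns: {missing}")
    records: list[PeptideRecord] = []
    rejects: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            charge = int(getattr(row, "charge"))
            mods = parse_modification_string(getattr(row, "modifications"), registry)
            pep = Peptide(
                sequence=getattr(row, "peptide").strip(),
                modifications=tuple((pos, m.name) for pos, m in mods),
                charge=charge,
            )
            pep.validate_targets(registry)
            records.append(PeptideRecord(spec_id=getattr(row, "spec_id"), peptide=pep))
        except (PeptideError, ValueError) as exc:
            rejects.append((i, str(exc)))
    return records, rejects


def write_peptide_table(records: Iterable[PeptideRecord], path) -> None:
    rows = [
        {
            "spec_id": r.spec_id,
            "peptide": r.peptide.sequence,
            "modifications": format_modification_string(r.peptide),
            "charge": r.peptide.charge,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------


def read_mgf(path) -> Iterator[ObservedSpectrum]:
    """Stream spectra from an MGF file.

    Blocks without PEPMASS are skipped with a warning; a truncated final block
    (BEGIN IONS without END IONS) raises.
    """
    n_begin = n_end = 0
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s == "BEGIN IONS":
                n_begin += 1
            elif s == "END IONS":
                n_end += 1
    if n_begin != n_end:
        raise PeptideError(f"truncated MGF {path}: {n_begin} BEGIN IONS vs {n_end} END IONS")

    with _ptmgf.read(str(path), use_index=False, convert_arrays=1) as reader:
        for i, spec in enumerate(reader):
            params = spec.get("params", {})
            if "pepmass" not in params or params["pepmass"] is None:
                logger.warning("MGF block %d in %s has no PEPMASS; skipped", i + 1, path)
                continue
            pepmass = params["pepmass"]
            prec_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = params.get("charge")
            prec_z = int(charge[0]) if charge else None
            yield ObservedSpectrum(
                identifier=str(params.get("title", f"index={i}")),
                precursor_mz=prec_mz,
                precursor_charge=prec_z,
                mz=spec["m/z array"],
                intensity=spec["intensity array"],
            )


def write_mgf(spectra: Iterable[ObservedSpectrum], path) -> None:
    entries = []
    for s in spectra:
        params = {"title": s.identifier, "pepmass": s.precursor_mz}
        if s.precursor_charge is not None:
            params["charge"] = f"{s.precursor_charge}+"
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _ptmgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# MSP (NIST spectral library)
# ---------------------------------------------------------------------------

_MOD_TOKEN_RE = re.compile(r"\((-?\d+),([A-Z\-]),([^)]+)\)")


def _mods_comment_token(p: Peptide) -> str:
    """NIST-style ``Mods=k(pos,res,name)`` token.

    Residue modifications use 0-based residue positions with the residue
    letter; the N-terminus is written as ``(-1,-,Name)`` and the C-terminus as
    ``(n,-,Name)`` where n is the peptide length.
    """
    if not p.modifications:
        return "Mods=0"
    n = len(p.sequence)
    parts = []
    for pos, name in p.modifications:
        if pos == 0:
            parts.append(f"(-1,-,{name})")
        elif pos == n + 1:
            parts.append(f"({n},-,{name})")
        else:
            parts.append(f"({pos - 1},{p.sequence[pos - 1]},{name})")
    return f"Mods={len(parts)}" + "".join(parts)


def _parse_mods_token(token: str, sequence: str, registry: ModificationRegistry) -> tuple[tuple[int, str], ...]:
    if token.strip() in ("0", ""):
        return ()
    n = len(sequence)
    mods: list[tuple[int, str]] = []
    for pos_s, res, name in _MOD_TOKEN_RE.findall(token):
        pos = int(pos_s)
        if pos == -1:
            pep_pos = 0
        elif pos == n and res == "-":
            pep_pos = n + 1
        else:
            if not (0 <= pos < n):
                raise PeptideError(f"Mods position {pos} out of range for {sequence!r}")
            if res != "-" and sequence[pos] != res:
                raise PeptideError(
                    f"Mods residue mismatch at {pos}: sequence has "
                    f"{sequence[pos]!r}, Mods says {res!r}"
                )
            pep_pos = pos + 1
        if name not in registry:
            raise PeptideError(f"unknown modification {name!r} in Mods token")
        mods.append((pep_pos, name))
    return tuple(mods)


@dataclass
class MspEntry:
    """One parsed MSP entry: either a (record, spectrum) pair or a reject."""

    name: str
    record: PeptideRecord | None = None
    spectrum: ObservedSpectrum | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def read_msp(
    path, registry: ModificationRegistry = DEFAULT_REGISTRY
) -> Iterator[MspEntry]:
    """Stream entries from an MSP library.

    Entries whose modifications are unknown to the registry, or whose peak
    count disagrees with ``Num peaks``, are yielded with ``error`` set instead
    of raising, so batch layers can skip-and-log.
    """
    with open(path) as fh:
        block: list[str] = []
        for line in fh:
            if line.strip() == "" and block:
                yield _parse_msp_block(block, registry)
                block = []
            elif line.strip():
                block.append(line.rstrip("\n"))
        if block:
            yield _parse_msp_block(block, registry)


def _parse_msp_block(lines: list[str], registry: ModificationRegistry) -> MspEntry:
    name = ""
    comment = ""
    num_peaks: int | None = None
    peak_lines: list[str] = []
    in_peaks = False
    for line in lines:
        if in_peaks:
            peak_lines.append(line)
        elif line.startswith("Name:"):
            name = line.split(":", 1)[1].strip()
        elif line.startswith("Comment:"):
            comment = line.split(":", 1)[1].strip()
        elif line.lower().startswith("num peaks:"):
            num_peaks = int(line.split(":", 1)[1].strip())
            in_peaks = True
    try:
        if "/" not in name:
            raise PeptideError(f"MSP Name {name!r} lacks '/charge'")
        sequence, charge_s = name.rsplit("/", 1)
        charge = int(charge_s)
        fields = dict(
            kv.split("=", 1) for kv in comment.split() if "=" in kv
        )
        mods = _parse_mods_token(fields.get("Mods", "0"), sequence, registry)
        pep = Peptide(sequence=sequence, modifications=mods, charge=charge)
        pep.validate_targets(registry)
        mz, inten = [], []
        for pl in peak_lines:
            parts = pl.split()
            if len(parts) < 2:
                raise PeptideError(f"malformed peak line {pl!r}")
            mz.append(float(parts[0]))
            inten.append(float(parts[1]))
        if num_peaks is not None and num_peaks != len(mz):
            raise PeptideError(
                f"Num peaks mismatch in {name!r}: header {num_peaks}, found {len(mz)}"
            )
        parent = float(fields["Parent"]) if "Parent" in fields else precursor_mz_of(pep, registry)
        spec = ObservedSpectrum(
            identifier=name, precursor_mz=parent, precursor_charge=charge,
            mz=np.array(mz), intensity=np.array(inten),
        )
        return MspEntry(
            name=name,
            record=PeptideRecord(spec_id=name, peptide=pep, spectrum_id=name),
            spectrum=spec,
        )
    except (PeptideError, ValueError) as exc:
        return MspEntry(name=name, error=str(exc))


def read_msp_library(
    path, registry: ModificationRegistry = DEFAULT_REGISTRY
) -> tuple[list[tuple[PeptideRecord, ObservedSpectrum]], list[tuple[str, str]]]:
    """Convenience wrapper: full library as (pairs, rejects)."""
    pairs, rejects = [], []
    for entry in read_msp(path, registry):
        if entry.ok:
            pairs.append((entry.record, entry.spectrum))
        else:
            rejects.append((entry.name, entry.error))
    return pairs, rejects


def write_msp(
    pairs: Iterable[tuple[PeptideRecord, ObservedSpectrum]],
    path,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> None:
    with open(path, "w") as fh:
        for record, spec in pairs:
            p = record.peptide
            fh.write(f"Name: {p.sequence}/{p.charge}\n")
            fh.write(
                f"Comment: Parent={spec.precursor_mz:.6f} "
                f"{_mods_comment_token(p)}\n"
            )
            fh.write(f"Num peaks: {len(spec)}\n")
            for mz, inten in zip(spec.mz, spec.intensity):
                fh.write(f"{mz:.6f}\t{inten:.8g}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BiblioSpec / Skyline SSL + MS2
# ---------------------------------------------------------------------------


def _ssl_modified_sequence(p: Peptide, registry: ModificationRegistry) -> str:
    """Bracketed-mass modified sequence, e.g. ``[+229.162932]PEPTK[+229.162932]``.

    The N-terminal mod precedes the first residue; a C-terminal mod is written
    as a trailing ``-[+mass]``.
    """
    mods = dict(p.modifications)
    n = len(p.sequence)

    def tag(name: str) -> str:
        d = registry[name].delta_mass
        return f"[{d:+.6f}]"

    out = []
    if 0 in mods:
        out.append(tag(mods[0]))
    for i, aa in enumerate(p.sequence, start=1):
        out.append(aa)
        if i in mods:
            out.append(tag(mods[i]))
    if n + 1 in mods:
        out.append("-" + tag(mods[n + 1]))
    return "".join(out)


_SSL_TOKEN_RE = re.compile(r"(\[[+-][0-9.]+\])|(-\[[+-][0-9.]+\])|([A-Z])")


def _resolve_mod_by_mass(
    delta: float, site: str, registry: ModificationRegistry, tol: float = 0.01
) -> str:
    best_name, best_err = None, tol
    for mod in registry:
        if site in mod.targets and abs(mod.delta_mass - delta) <= best_err:
            best_name, best_err = mod.name, abs(mod.delta_mass - delta)
    if best_name is None:
        raise PeptideError(f"no registry modification with delta {delta:+.4f} at {site}")
    return best_name


def _parse_ssl_sequence(s: str, charge: int, registry: ModificationRegistry) -> Peptide:
    residues: list[str] = []
    mods: list[tuple[int, float]] = []
    pos = 0
    i = 0
    while i < len(s):
        m = _SSL_TOKEN_RE.match(s, i)
        if not m:
            raise PeptideError(f"cannot parse SSL sequence {s!r} at offset {i}")
        if m.group(3):  # residue
            residues.append(m.group(3))
            pos = len(residues)
        elif m.group(1):  # [+mass] at current position (0 = N-term)
            mods.append((pos, float(m.group(1)[1:-1])))
        else:  # trailing -[+mass] = C-term
            mods.append((len(s), float(m.group(2)[2:-1])))  # placeholder pos, fixed below
        i = m.end()
    seq = "".join(residues)
    n = len(seq)
    resolved = []
    for p_, delta in mods:
        if p_ == len(s):  # C-term placeholder
            p_ = n + 1
        if p_ == 0:
            site = "N-term"
        elif p_ == n + 1:
            site = "C-term"
        else:
            site = seq[p_ - 1]
        resolved.append((p_, _resolve_mod_by_mass(delta, site, registry)))
    return Peptide(sequence=seq, modifications=tuple(resolved), charge=charge)


def write_ssl_ms2(
    pairs: Iterable[tuple[PeptideRecord, ObservedSpectrum]],
    ssl_path,
    ms2_path,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> None:
    """Write paired SSL (peptide index) and MS2 (spectra) files.

    Scan numbers are assigned sequentially from 1; the SSL ``file`` column
    references the MS2 file name.
    """
    ms2_name = Path(ms2_path).name
    with open(ssl_path, "w") as ssl, open(ms2_path, "w") as ms2:
        ssl.write("file\tscan\tcharge\tsequence\n")
        ms2.write("H\tCreationTool\tpeakboost\n")
        for scan, (record, spec) in enumerate(pairs, start=1):
            p = record.peptide
            ssl.write(
                f"{ms2_name}\t{scan}\t{p.charge}\t"
                f"{_ssl_modified_sequence(p, registry)}\n"
            )
            mh = spec.precursor_mz * (p.charge) - (p.charge - 1) * PROTON_MASS
            ms2.write(f"S\t{scan}\t{scan}\t{spec.precursor_mz:.6f}\n")
            ms2.write(f"Z\t{p.charge}\t{mh:.6f}\n")
            for mz, inten in zip(spec.mz, spec.intensity):
                ms2.write(f"{mz:.6f} {inten:.8g}\n")


def read_ssl_ms2(
    ssl_path, ms2_path, registry: ModificationRegistry = DEFAULT_REGISTRY
) -> list[tuple[PeptideRecord, ObservedSpectrum]]:
    scans: dict[int, tuple[float, list[float], list[float]]] = {}
    cur = None
    with open(ms2_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("H\t"):
                continue
            if line.startswith("S\t"):
                _, scan_s, _, prec = line.split("\t")
                cur = (float(prec), [], [])
                scans[int(scan_s)] = cur
            elif line.startswith("Z\t"):
                continue
            else:
                mz_s, inten_s = line.split()
                cur[1].append(float(mz_s))
                cur[2].append(float(inten_s))
    out = []
    ssl_df = pd.read_csv(ssl_path, sep="\t", dtype=str)
    for _, row in ssl_df.iterrows():
        scan = int(row["scan"])
        charge = int(row["charge"])
        pep = _parse_ssl_sequence(row["sequence"], charge, registry)
        prec, mz, inten = scans[scan]
        spec_id = f"scan={scan}"
        spec = ObservedSpectrum(
            identifier=spec_id, precursor_mz=prec, precursor_charge=charge,
            mz=np.array(mz), intensity=np.array(inten),
        )
        out.append((PeptideRecord(spec_id=spec_id, peptide=pep, spectrum_id=spec_id), spec))
    return out


# ---------------------------------------------------------------------------
# Prediction output
# ---------------------------------------------------------------------------

PREDICTION_FORMATS = ("csv", "mgf", "msp", "ssl_ms2")


def _rescaled(linear: np.ndarray) -> np.ndarray:
    peak = float(np.max(linear)) if linear.size else 0.0
    if peak <= 0:
        return np.zeros_like(linear)
    return linear * (PREDICTION_SCALE / peak)


def write_predictions(
    records: Sequence[PeptideRecord],
    predictions: Mapping[str, PredictedPeaks],
    fmt: str,
    path,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> None:
    """Write predicted spectra in one of ``csv|mgf|msp|ssl_ms2``.

    Linear intensities are rescaled so the base peak of each spectrum is
    10000 (recorded in a header comment). For ``ssl_ms2``, ``path`` is a base
    prefix and ``<path>.ssl`` / ``<path>.ms2`` are written.
    """
    if fmt not in PREDICTION_FORMATS:
        raise PeptideError(
            f"unknown prediction format {fmt!r}; valid: {', '.join(PREDICTION_FORMATS)}"
        )
    ordered = [(r, predictions[r.spec_id]) for r in records if r.spec_id in predictions]

    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# predicted intensities rescaled to base peak = {PREDICTION_SCALE:g}\n")
            fh.write("spec_id,series,index,charge,mz,prediction\n")
            for record, pred in ordered:
                scaled = _rescaled(np.asarray(pred.linear_intensity))
                for frag, inten in zip(pred.fragments, scaled):
                    fh.write(
                        f"{record.spec_id},{frag.series},{frag.index},"
                        f"{frag.charge},{frag.mz:.6f},{inten:.6g}\n"
                    )
        return

    pairs = []
    for record, pred in ordered:
        mz, inten = pred.sorted_peaks()
        spec = ObservedSpectrum(
            identifier=record.spec_id,
            precursor_mz=precursor_mz_of(pred.peptide, registry),
            precursor_charge=pred.peptide.charge,
            mz=mz,
            intensity=_rescaled(inten),
        )
        pairs.append((PeptideRecord(record.spec_id, pred.peptide), spec))

    if fmt == "mgf":
        write_mgf((spec for _, spec in pairs), path)
    elif fmt == "msp":
        write_msp(pairs, path, registry)
    else:  # ssl_ms2
        base = Path(path)
        write_ssl_ms2(pairs, base.with_suffix(".ssl"), base.with_suffix(".ms2"), registry)
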