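"""On-disk data model: kinetics tables, posterior tracks and BED intervals.

The primary interchange format is a plain-text *kinetics table*: one row per
sequenced molecule carrying the base string and the per-base interpulse
durations (IPDs), tab-separated with the header

    molecule_id  ref_name  ref_start  ref_end  strand  bases  ipd

where ``ipd`` is a comma-separated list of non-negative reals, one per base,
with an empty field marking a missing observation.  All per-molecule vectors
are stored in molecule (read) orientation; conversion to reference
orientation happens only at export/overlap time.  Every coordinate emitted
on disk is 0-based half-open (BED convention).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KINETICS_COLUMNS = [
    "molecule_id",
    "ref_name",
    "ref_start",
    "ref_end",
    "strand",
    "bases",
    "ipd",
]

_VALID_BASES = frozenset("ACGTN")
_AT_CODES = (ord("A"), ord("T"))


class KineticsFormatError(ValueError):
    """Malformed kinetics/track data; the message names the offending row."""


class UnsupportedInputError(ValueError):
    """Input lacks the information this reader requires (e.g. kinetics tags)."""


@dataclass
class Molecule:
    """One sequenced fibre: base string plus per-base IPDs and placement.

    ``ipd`` is float per base, NaN where no IPD was observed.  ``ref_start``/
    ``ref_end`` are 0-based half-open on ``ref_name``; ``strand`` gives the
    alignment orientation of the read.
    """

    molecule_id: str
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str
    bases: str
    ipd: np.ndarray

    def __post_init__(self) -> None:
        self.ipd = np.asarray(self.ipd, dtype=float)
        if len(self.ipd) != len(self.bases):
            raise KineticsFormatError(
                f"molecule {self.molecule_id!r}: ipd length {len(self.ipd)} "
                f"!= bases length {len(self.bases)}"
            )
        if self.strand not in ("+", "-"):
            raise KineticsFormatError(
                f"molecule {self.molecule_id!r}: bad strand {self.strand!r}"
            )
        extra = set(self.bases) - _VALID_BASES
        if extra:
            raise KineticsFormatError(
                f"molecule {self.molecule_id!r}: invalid bases {sorted(extra)}"
            )
        finite = np.isfinite(self.ipd)
        if np.any(self.ipd[finite] < 0):
            raise KineticsFormatError(
                f"molecule {self.molecule_id!r}: negative IPD value"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def base_codes(self) -> np.ndarray:
        return np.frombuffer(self.bases.encode("ascii"), dtype=np.uint8)

    @property
    def at_mask(self) -> np.ndarray:
        """Boolean mask of A/T template positions."""
        codes = self.base_codes
        return (codes == _AT_CODES[0]) | (codes == _AT_CODES[1])

    def to_reference(self, pos: int) -> int:
        """Map a molecule coordinate to a reference coordinate (strand-aware)."""
        if not 0 <= pos < len(self):
            raise ValueError(f"position {pos} outside molecule of length {len(self)}")
        if self.strand == "+":
            return self.ref_start + pos
        return self.ref_start + (len(self) - 1 - pos)


@dataclass
class ModificationTrack:
    """Per-base posterior probability of adenine methylation for one molecule.

    Values are defined only at A/T positions with an observed IPD; everywhere
    else the track is NaN.
    """

    molecule_id: str
    prob: np.ndarray

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        finite = np.isfinite(self.prob)
        vals = self.prob[finite]
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise KineticsFormatError(
                f"track {self.molecule_id!r}: probability outside [0, 1]"
            )

    def __len__(self) -> int:
        return len(self.prob)


@dataclass
class FeatureSet:
    """BED-style intervals (chrom, start, end, name, score, strand)."""

    df: pd.DataFrame

    COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        for col, default in (("name", "."), ("score", 0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[self.COLUMNS]
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] >= df["end"]).any():
            bad = df.index[(df["start"] >= df["end"])][0]
            raise ValueError(f"interval {bad}: start >= end")
        if not df["strand"].isin(["+", "-", "."]).all():
            raise ValueError("strand must be one of +, -, .")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.df.itertuples(index=False))

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple]) -> "FeatureSet":
        defaults = (None, None, None, ".", 0, ".")
        rows = [tuple(r) + defaults[len(r):] for r in intervals]
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))


def _fmt(v: float) -> str:
    """Shortest round-trippable decimal for a float; empty string for NaN."""
    return "" if not np.isfinite(v) else repr(float(v))


def _parse_float_list(s: str) -> np.ndarray:
    toks = s.split(",")
    return np.array([float(t) if t else np.nan for t in toks], dtype=float)


def read_kinetics(path: str | Path) -> Iterator[Molecule]:
    """Stream validated :class:`Molecule` rows from a kinetics table.

    Malformed rows raise :class:`KineticsFormatError` naming the line; the
    total count read is logged so silent drops are impossible.
    """
    path = Path(path)
    n = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != KINETICS_COLUMNS:
            raise KineticsFormatError(
                f"{path}: bad header {header!r}, expected {KINETICS_COLUMNS}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(KINETICS_COLUMNS):
                raise KineticsFormatError(
                    f"{path}:{lineno}: expected {len(KINETICS_COLUMNS)} fields, "
                    f"got {len(row)}"
                )
            mol_id, ref_name, start, end, strand, bases, ipd_s = row
            try:
                mol = Molecule(
                    molecule_id=mol_id,
                    ref_name=ref_name,
                    ref_start=int(start),
                    ref_end=int(end),
                    strand=strand,
                    bases=bases,
                    ipd=_parse_float_list(ipd_s),
                )
            except (ValueError, KineticsFormatError) as exc:
                raise KineticsFormatError(f"{path}:{lineno}: {exc}") from exc
            n += 1
            yield mol
    logger.info("read %d molecules from %s", n, path)


def write_kinetics(molecules: Iterable[Molecule], path: str | Path) -> int:
    path = Path(path)
    n = 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(KINETICS_COLUMNS)
        for m in molecules:
            writer.writerow(
                [
                    m.molecule_id,
                    m.ref_name,
                    m.ref_start,
                    m.ref_end,
                    m.strand,
                    m.bases,
                    ",".join(_fmt(v) for v in m.ipd),
                ]
            )
            n += 1
    logger.info("wrote %d molecules to %s", n, path)
    return n


TRACK_COLUMNS = ["molecule_id", "prob"]


def write_tracks(tracks: Iterable[ModificationTrack], path: str | Path) -> int:
    """Write posterior tracks as TSV, 6-decimal fixed point (lossless to 1e-6)."""
    path = Path(path)
    n = 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRACK_COLUMNS)
        for t in tracks:
            vals = []
            for v in t.prob:
                if not np.isfinite(v):
                    vals.append("")
                else:
                    if v < 0.0 or v > 1.0:
                        raise KineticsFormatError(
                            f"track {t.molecule_id!r}: value {v} outside [0, 1]"
                        )
                    vals.append(f"{v:.6f}")
            writer.writerow([t.molecule_id, ",".join(vals)])
            n += 1
    logger.info("wrote %d tracks to %s", n, path)
    return n


def read_tracks(path: str | Path) -> Iterator[ModificationTrack]:
    path = Path(path)
    n = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != TRACK_COLUMNS:
            raise KineticsFormatError(
                f"{path}: bad header {header!r}, expected {TRACK_COLUMNS}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise KineticsFormatError(f"{path}:{lineno}: expected 2 fields")
            try:
                track = ModificationTrack(row[0], _parse_float_list(row[1]))
            except (ValueError, KineticsFormatError) as exc:
                raise KineticsFormatError(f"{path}:{lineno}: {exc}") from exc
            n += 1
            yield track
    logger.info("read %d tracks from %s", n, path)


def read_bed(path: str | Path) -> FeatureSet:
    """Read BED3 or BED6 into a :class:`FeatureSet`."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str, skip_blank_lines=True
    )
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :6]
    df.columns = FeatureSet.COLUMNS[: df.shape[1]]
    try:
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer coordinates ({exc})") from exc
    return FeatureSet(df)


def write_bed(features: FeatureSet, path: str | Path) -> None:
    features.df.to_csv(path, sep="\t", header=False, index=False)


def write_dyads(
    callsets: Iterable,
    molecules: Mapping[str, Molecule],
    path: str | Path,
) -> None:
    """Write dyad calls as 1-bp BED intervals on reference coordinates.

    Each dyad (a molecule coordinate) is mapped through the molecule's
    alignment: ``ref_start + p`` on the plus strand and
    ``ref_start + (L - 1 - p)`` on the minus strand.
    """
    rows = []
    for cs in callsets:
        mol = molecules[cs.molecule_id]
        for p in cs.dyads:
            start = mol.to_reference(int(p))
            rows.append((mol.ref_name, start, start + 1, cs.molecule_id, 0, mol.strand))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def bam_adapter(path: str | Path) -> Iterator[Molecule]:
    """Thin optional adapter from an aligned BAM with per-base kinetics tags.

    Accepts the forward-strand frame-count tag (``fi``, consensus reads) or
    the subread tag (``ip``); frame counts are passed through as IPD values
    since downstream normalization is per-molecule and scale-free.  Raises
    :class:`UnsupportedInputError` when a read carries no kinetics tag.
    """
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise UnsupportedInputError("pysam is required for BAM input") from exc

    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            if aln.has_tag("fi"):
                raw = aln.get_tag("fi")
            elif aln.has_tag("ip"):
                raw = aln.get_tag("ip")
            else:
                raise UnsupportedInputError(
                    f"read {aln.query_name}: no kinetics tag (fi/ip) present"
                )
            ipd = np.asarray(raw, dtype=float)
            if ipd.size != len(aln.query_sequence):
                raise KineticsFormatError(
                    f"read {aln.query_name}: kinetics tag length mismatch"
                )
            yield Molecule(
                molecule_id=aln.query_name,
                ref_name=aln.reference_name or ".",
                ref_start=int(aln.reference_start),
                ref_end=int(aln.reference_end or aln.reference_start + ipd.size),
                strand="-" if aln.is_reverse else "+",
                bases=aln.query_sequence.upper(),
                ipd=ipd,
            )
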