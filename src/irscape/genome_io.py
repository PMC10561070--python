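"""Masked-genome input/output, run segmentation and windowing.

Hard-masked assemblies code unknown bases and catalogued repeats as ``N``.
Every non-ACGT IUPAC symbol is treated as a separator that splits a
chromosome into maximal unambiguous runs; inverted-repeat pairs are later
only counted inside a single run.  Chromosomes are tiled into fixed-size,
non-overlapping windows (the trailing partial window is kept).

Coordinates are 0-based, half-open throughout; 1-based inclusive labels are
used only in human-readable region strings (:func:`region_label`).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: symbol codes: A, C, G, T, then everything ambiguous
A, C, G, T, AMBIG = 0, 1, 2, 3, 4

_IUPAC = set("ACGTRYSWKMBDHVN")

# byte -> code lookup; 255 marks characters outside the IUPAC alphabet
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _ch, _code in (("A", A), ("C", C), ("G", G), ("T", T)):
    _CODE_LUT[ord(_ch)] = _code
    _CODE_LUT[ord(_ch.lower())] = _code
for _ch in _IUPAC - set("ACGT"):
    _CODE_LUT[ord(_ch)] = AMBIG
    _CODE_LUT[ord(_ch.lower())] = AMBIG

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


@dataclass(frozen=True)
class UnambiguousRun:
    """Maximal stretch of unambiguous bases, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty run [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MaskedChromosome:
    """One named sequence with its ambiguity mask and derived runs.

    ``codes`` is a uint8 array over {0..4}; positions inside ``runs`` hold
    codes 0..3, every other position holds 4.
    """

    name: str
    codes: np.ndarray
    runs: list[UnambiguousRun] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if not self.runs:
            self.runs = segment_runs(self.codes)

    @property
    def length(self) -> int:
        return int(self.codes.size)

    def sequence(self) -> str:
        """Decode to an ACGTN string (all ambiguity collapses to N)."""
        return _BASES[np.minimum(self.codes, AMBIG)].tobytes().decode("ascii")


@dataclass(frozen=True)
class Window:
    """Fixed-size genome tile, 0-based half-open."""

    chrom: str
    index: int
    start: int
    end: int


def encode_sequence(seq: str, name: str = "?") -> np.ndarray:
    """Map a nucleotide string to symbol codes, upper-casing soft mask.

    Raises ``ValueError`` naming the first offending position for any
    character outside the IUPAC nucleotide alphabet.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[raw]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"non-IUPAC character {seq[pos]!r} at position {pos} in record {name!r}"
        )
    return codes


def segment_runs(codes: Sequence[int] | np.ndarray) -> list[UnambiguousRun]:
    """Maximal runs of unambiguous codes, sorted by start.

    Depends only on the ambiguity pattern: two code arrays with the same set
    of ambiguous positions yield identical runs.
    """
    codes = np.asarray(codes, dtype=np.uint8)
    clear = codes < AMBIG
    if not clear.any():
        return []
    # transitions of the 0/1 clear mask give run boundaries
    padded = np.diff(np.concatenate(([0], clear.view(np.uint8), [0])).astype(np.int8))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0]
    return [UnambiguousRun(int(s), int(e)) for s, e in zip(starts, ends)]


def read_masked_fasta(path: str | Path, hard_mask_lower: bool = False) -> list[MaskedChromosome]:
    """Read a (optionally gzip-compressed) hard-masked FASTA file.

    Lowercase (soft-masked) bases are upper-cased by default; with
    ``hard_mask_lower`` they are treated as ambiguous instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opener = gzip.open if path.suffix == ".gz" else open
    chroms: list[MaskedChromosome] = []
    seen: set[str] = set()
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate record name {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = str(rec.seq)
            if hard_mask_lower:
                seq = "".join(c if c.isupper() else "N" for c in seq)
            chroms.append(MaskedChromosome(rec.id, encode_sequence(seq, rec.id)))
    if not chroms:
        raise ValueError(f"no FASTA records in {path}")
    return chroms


def write_fasta(chroms: Iterable[MaskedChromosome], path: str | Path, width: int = 70) -> None:
    """Write chromosomes as ACGTN FASTA (gzip if the path ends in .gz)."""
    path = Path(path)
    records = [SeqRecord(Seq(ch.sequence()), id=ch.name, description="") for ch in chroms]
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def make_windows(chrom: MaskedChromosome, window_size: int) -> list[Window]:
    """Tile a chromosome into successive windows of ``window_size`` nt.

    The trailing partial window is included, so the count is
    ``ceil(length / window_size)`` and window spans sum to the length.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    L = chrom.length
    n = -(-L // window_size) if L else 0
    return [
        Window(chrom.name, i, i * window_size, min((i + 1) * window_size, L))
        for i in range(n)
    ]


def clip_runs(runs: Iterable[UnambiguousRun], start: int, end: int) -> list[UnambiguousRun]:
    """Intersect runs with [start, end), dropping empty intersections."""
    out = []
    for r in runs:
        s, e = max(r.start, start), min(r.end, end)
        if e > s:
            out.append(UnambiguousRun(s, e))
    return out


def region_label(chrom: str, start: int, end: int) -> str:
    """Human-readable 1-based inclusive label, e.g. ``chrX:53000001:53100000``."""
    return f"{chrom}:{start + 1}:{end}"


def write_window_bed(windows: Iterable[Window], path: str | Path) -> None:
    """BED3+1 window table (chrom, start, end, window index), tab-separated."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.index}\n")
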