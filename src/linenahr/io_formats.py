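"""Readers and writers for the standard formats the pipeline touches.

All intervals are 0-based, half-open, in base pairs — the UCSC table
convention shared by rmsk dumps and BED.  Converters to/from 1-based
coordinates are the only place the convention may change; no module below
this one re-interprets coordinates.  Chromosome names are taken verbatim
from the inputs (no ``chr`` normalization; callers are responsible for
consistent naming across inputs).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A malformed input file (carries the offending line number)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeAssembly:
    """A genome with its centromere and assembly-gap annotation.

    Parameters
    ----------
    sequences
        Per-chromosome uppercase DNA (alphabet ACGTN).
    centromeres, gaps
        Per-chromosome interval lists, 0-based half-open.  Chromosomes
        without an entry are treated as having none.
    """

    sequences: dict[str, str]
    centromeres: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    gaps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table, label in ((self.centromeres, "centromere"), (self.gaps, "gap")):
            for chrom, ivals in table.items():
                if chrom not in self.sequences:
                    raise ValueError(f"{label} interval on unknown chromosome {chrom!r}")
                n = len(self.sequences[chrom])
                for s, e in ivals:
                    if not (0 <= s < e <= n):
                        raise ValueError(
                            f"{label} interval [{s},{e}) outside {chrom!r} (length {n})"
                        )

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def non_gap_length(self) -> int:
        """Total length minus annotated assembly gaps (> 0 by construction)."""
        gap = sum(e - s for ivals in self.gaps.values() for s, e in ivals)
        n = self.total_length - gap
        if n <= 0:
            raise ValueError("non-gap genome length must be positive")
        return n


@dataclass(frozen=True)
class RepeatElement:
    """One annotated repeat copy (a LINE, for our purposes)."""

    id: str
    chromosome: str
    start: int
    end: int
    strand: str
    family: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"element {self.id}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"element {self.id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ProbeTrack:
    """Ordered aCGH probes for one sample: (chromosome, position, log2 ratio)."""

    sample: str
    chroms: list[str]
    positions: list[int]
    log2: list[float]

    def __post_init__(self) -> None:
        prev: dict[str, int] = {}
        for c, p in zip(self.chroms, self.positions):
            if c in prev and p <= prev[c]:
                raise ValueError(
                    f"probe positions not strictly increasing on {c!r} (at {p})"
                )
            prev[c] = p


@dataclass(frozen=True)
class SegDupPair:
    """A segmental-duplication (LCR) pair with relative orientation."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    orientation: str  # "direct" | "inverted"

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if (self.chrom_a, self.start_a, self.end_a) == (self.chrom_b, self.start_b, self.end_b):
            raise ValueError("segdup pair intervals coincide")


@dataclass(frozen=True)
class RawHsp:
    """One BLAST tabular (outfmt 6) row.

    Subject strand is encoded by coordinate order: ``sstart > send`` means a
    minus-strand HSP; the query is always forward.  Coordinates are kept
    1-based inclusive as BLAST prints them; ``q_interval``/``s_interval``
    expose the 0-based half-open equivalents.
    """

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    @property
    def minus_strand(self) -> bool:
        return self.sstart > self.send

    @property
    def q_interval(self) -> tuple[int, int]:
        return self.qstart - 1, self.qend

    @property
    def s_interval(self) -> tuple[int, int]:
        lo, hi = sorted((self.sstart, self.send))
        return lo - 1, hi


# ---------------------------------------------------------------------------
# repeat tables
# ---------------------------------------------------------------------------

#: rmsk table dump columns (UCSC database order, including the index `bin`)
_RMSK_MIN_COLS = 11


def read_repeat_table(path: str | Path, dialect: str = "bed6") -> list[RepeatElement]:
    """Parse a repeat annotation file into :class:`RepeatElement` records.

    ``dialect="ucsc_rmsk_tab"`` expects the UCSC RepeatMasker table dump
    (tab-separated, with the leading ``bin`` column: genoName at column 6,
    genoStart/genoEnd 0-based half-open, strand at column 10, repName at
    column 11).  ``dialect="bed6"`` expects chrom/start/end/name/score/strand.
    """
    if dialect not in ("ucsc_rmsk_tab", "bed6"):
        raise ValueError(f"unknown repeat-table dialect {dialect!r}")
    out: list[RepeatElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bed6":
                    if len(fields) < 6:
                        raise ValueError("expected >= 6 columns")
                    chrom, start, end, name, _score, strand = fields[:6]
                    fam = name
                else:
                    if len(fields) < _RMSK_MIN_COLS:
                        raise ValueError(
                            f"expected >= {_RMSK_MIN_COLS} columns, got {len(fields)}"
                        )
                    chrom = fields[5]
                    start, end = fields[6], fields[7]
                    strand = fields[9]
                    # rmsk encodes minus strand as 'C' in some dumps
                    strand = "-" if strand in ("-", "C") else "+"
                    fam = fields[10]
                    name = f"{fam}|{chrom}:{start}"
                out.append(
                    RepeatElement(
                        id=f"{name}@{chrom}:{start}-{end}",
                        chromosome=chrom,
                        start=int(start),
                        end=int(end),
                        strand=strand,
                        family=fam,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed line: {exc}") from exc
    return out


def write_repeat_bed6(elements: Iterable[RepeatElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for el in elements:
            fh.write(
                f"{el.chromosome}\t{el.start}\t{el.end}\t{el.family}\t0\t{el.strand}\n"
            )


# ---------------------------------------------------------------------------
# BED3 intervals (centromeres / gaps)
# ---------------------------------------------------------------------------

def read_bed3(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED3 file into a chromosome -> sorted interval-list mapping."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed line: {exc}") from exc
    for ivals in out.values():
        ivals.sort()
    return out


def write_bed3(intervals: dict[str, list[tuple[int, int]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in intervals:
            for s, e in intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

def read_blast_tabular(path: str | Path) -> list[RawHsp]:
    """Read a 12-column BLAST outfmt-6 file (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore)."""
    out: list[RawHsp] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                out.append(
                    RawHsp(
                        qseqid=fields[0],
                        sseqid=fields[1],
                        pident=float(fields[2]),
                        length=int(fields[3]),
                        mismatch=int(fields[4]),
                        gapopen=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed line: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_reads_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    """Read Sanger-encoded (PHRED+33) FASTQ into (id, sequence, qualities).

    Quality-list length equals sequence length for every record; violations
    (or non-+33 quality characters) raise :class:`FormatError`.
    """
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            out.append((rec.id, str(rec.seq).upper(), list(quals)))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return out


def write_fastq(records: Iterable[tuple[str, str, Sequence[int]]], path: str | Path) -> None:
    recs = []
    for name, seq, quals in records:
        if len(seq) != len(quals):
            raise ValueError(f"record {name}: sequence/quality length mismatch")
        r = SeqRecord(Seq(seq), id=name, description="")
        r.letter_annotations["phred_quality"] = list(quals)
        recs.append(r)
    SeqIO.write(recs, str(path), "fastq")


# ---------------------------------------------------------------------------
# probe tracks and segdup tables (TSV with header)
# ---------------------------------------------------------------------------

def read_probe_track(path: str | Path, sample: str | None = None) -> ProbeTrack:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "position", "log2"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: probe track needs columns {sorted(required)}")
    name = sample or (str(df["sample"].iloc[0]) if "sample" in df.columns and len(df) else "sample")
    return ProbeTrack(
        sample=name,
        chroms=[str(c) for c in df["chrom"]],
        positions=[int(p) for p in df["position"]],
        log2=[float(x) for x in df["log2"]],
    )


def write_probe_track(track: ProbeTrack, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample": track.sample,
            "chrom": track.chroms,
            "position": track.positions,
            "log2": track.log2,
        }
    ).to_csv(path, sep="\t", index=False)


def read_segdup_table(path: str | Path) -> list[SegDupPair]:
    """Read a genomicSuperDups-style TSV.

    Needs columns chrom/chromStart/chromEnd/otherChrom/otherStart/otherEnd/
    strand, where strand '+' means the two copies are directly oriented and
    '-' inverted (the UCSC convention for the `strand` field of that table).
    """
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "chromStart", "chromEnd", "otherChrom", "otherStart", "otherEnd", "strand"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: segdup table needs columns {sorted(need)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SegDupPair(
                chrom_a=str(row.chrom),
                start_a=int(row.chromStart),
                end_a=int(row.chromEnd),
                chrom_b=str(row.otherChrom),
                start_b=int(row.otherStart),
                end_b=int(row.otherEnd),
                orientation="direct" if str(row.strand) == "+" else "inverted",
            )
        )
    return out


def write_segdup_table(pairs: Iterable[SegDupPair], path: str | Path) -> None:
    rows = [
        {
            "chrom": p.chrom_a,
            "chromStart": p.start_a,
            "chromEnd": p.end_a,
            "otherChrom": p.chrom_b,
            "otherStart": p.start_b,
            "otherEnd": p.end_b,
            "strand": "+" if p.orientation == "direct" else "-",
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def dataclass_table(objs: Sequence, path: str | Path) -> None:
    """Write a homogeneous list of dataclass instances as a TSV with header."""
    pd.DataFrame([dataclasses.asdict(o) for o in objs]).to_csv(path, sep="\t", index=False)
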