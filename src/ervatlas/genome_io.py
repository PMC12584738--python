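"""Sequence and annotation I/O plus the coordinate algebra used pipeline-wide.

Internal coordinates are 0-based half-open throughout; every emitted file
(GFF3, TSV, BED) uses the 1-based inclusive convention of its format. DNA is
stored as uppercase strings over the alphabet {A, C, G, T, N}; IUPAC ambiguity
codes are collapsed to N on input and N never counts as a match downstream.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for empty FASTA input or duplicate record ids."""


class CoordinateError(ValueError):
    """Raised when a locus does not fit its contig."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Locus:
    """A stranded genomic interval: 0-based start (inclusive), end (exclusive)."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Locus") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "Locus") -> int:
        """Gap between two non-overlapping loci on one contig; 0 if they touch/overlap."""
        if self.contig != other.contig:
            raise CoordinateError("loci on different contigs have no distance")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


class ContigSet:
    """Named DNA sequences of one assembly plus a short species tag.

    The universe every :class:`Locus` in a run refers to. Contig ids are
    unique and non-empty, sequences non-empty and restricted to ACGTN.
    """

    def __init__(self, contigs: Mapping[str, str], species_tag: str = "") -> None:
        if not contigs:
            raise FastaFormatError("a ContigSet needs at least one contig")
        clean: dict[str, str] = {}
        for cid, seq in contigs.items():
            if not cid:
                raise FastaFormatError("empty contig id")
            if not seq:
                raise FastaFormatError(f"contig {cid!r} has an empty sequence")
            seq = seq.upper()
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise FastaFormatError(
                    f"contig {cid!r} contains letters outside ACGTN: {sorted(bad)}"
                )
            clean[cid] = seq
        self.contigs = clean
        self.species_tag = species_tag

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)

    def __getitem__(self, cid: str) -> str:
        return self.contigs[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self.contigs

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def length_of(self, cid: str) -> int:
        return len(self.contigs[cid])

    def validate(self, locus: Locus) -> None:
        if locus.contig not in self.contigs:
            raise CoordinateError(f"unknown contig {locus.contig!r}")
        if locus.end > len(self.contigs[locus.contig]):
            raise CoordinateError(
                f"locus [{locus.start}, {locus.end}) exceeds contig "
                f"{locus.contig!r} of length {len(self.contigs[locus.contig])}"
            )


def sanitize_dna(seq: str) -> tuple[str, int]:
    """Uppercase ``seq`` and collapse non-ACGTN letters to N.

    Returns the cleaned sequence and the number of substituted characters.
    """
    seq = seq.upper()
    out = []
    n_sub = 0
    for ch in seq:
        if ch in DNA_ALPHABET:
            out.append(ch)
        else:
            out.append("N")
            n_sub += 1
    return "".join(out), n_sub


def read_fasta(path: str | Path, species_tag: str = "") -> ContigSet:
    """Load a FASTA file into a :class:`ContigSet`.

    Lowercase letters are uppercased; anything outside ACGTN becomes N and the
    substitution count is logged. Empty files and duplicate ids are errors.
    """
    path = Path(path)
    contigs: dict[str, str] = {}
    n_sub_total = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FastaFormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq, n_sub = sanitize_dna(str(rec.seq))
        n_sub_total += n_sub
        contigs[rec.id] = seq
    if not contigs:
        raise FastaFormatError(f"no FASTA records in {path}")
    if n_sub_total:
        logger.info(
            "read_fasta(%s): %d non-ACGTN characters mapped to N", path, n_sub_total
        )
    return ContigSet(contigs, species_tag=species_tag)


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    if isinstance(records, Mapping):
        records = records.items()
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def extract(genome: ContigSet, locus: Locus, flank: int = 0) -> tuple[str, int, int]:
    """Extract ``locus`` with up to ``flank`` bp of context on each side.

    The window [start-flank, end+flank) is clipped at contig bounds; the
    achieved left/right flank lengths are returned alongside the sequence.
    Minus-strand loci are reverse-complemented (achieved flanks are reported
    in the returned sequence's orientation).
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    genome.validate(locus)
    seq = genome[locus.contig]
    lo = max(0, locus.start - flank)
    hi = min(len(seq), locus.end + flank)
    left = locus.start - lo
    right = hi - locus.end
    window = seq[lo:hi]
    if locus.strand == "-":
        return revcomp(window), right, left
    return window, left, right


@dataclass
class Feature:
    """An annotated locus destined for GFF3 output."""

    locus: Locus
    ftype: str
    source: str = "ervatlas"
    score: str = "."
    attributes: dict[str, str] = field(default_factory=dict)


def write_gff3(features: Iterable[Feature], path: str | Path) -> None:
    """Write features as GFF3 (1-based inclusive), sorted for stable output."""
    feats = sorted(
        features,
        key=lambda f: (f.locus.contig, f.locus.start, f.locus.end, f.ftype,
                       tuple(sorted(f.attributes.items()))),
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                "\t".join(
                    [
                        f.locus.contig,
                        f.source,
                        f.ftype,
                        str(f.locus.start + 1),
                        str(f.locus.end),
                        f.score,
                        f.locus.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            contig, source, ftype, start, end, score, strand = cols[:7]
            attrs: dict[str, str] = {}
            if len(cols) > 8 and cols[8] != ".":
                for kv in cols[8].split(";"):
                    if kv:
                        k, _, v = kv.partition("=")
                        attrs[k] = v
            feats.append(
                Feature(
                    locus=Locus(contig, int(start) - 1, int(end), strand),
                    ftype=ftype,
                    source=source,
                    score=score,
                    attributes=attrs,
                )
            )
    return feats


def write_tsv(records: Iterable[Mapping[str, object]], path: str | Path,
              columns: list[str] | None = None) -> None:
    """Write dict records as a headered TSV; header-only file for no records."""
    records = list(records)
    if columns is None:
        if records:
            columns = list(records[0].keys())
        else:
            columns = []
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t",
                                lineterminator="\n")
        if columns:
            writer.writeheader()
        for rec in records:
            writer.writerow(rec)


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
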