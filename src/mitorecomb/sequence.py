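"""Circular sequence containers and coordinate arithmetic.

Plant mitogenomes are commonly multipartite: one genome holds several
circular chromosomes, and features (repeat copies, flanks) may wrap the
arbitrary origin of the deposited sequence.  Everything downstream builds on
the two primitives here: a :class:`CircularChromosome` and wrap-aware slicing.

Coordinates in all public reports are 1-based inclusive, the convention of
BLAST tabular output.  Internal helpers that need 0-based half-open ranges
convert locally and never expose them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircularChromosome",
    "Genome",
    "Locus",
    "InputError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "extract_circular",
    "write_bed",
]

_VALID = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InputError(ValueError):
    """Raised for malformed user input (files, sequences, coordinates)."""


def _check_alphabet(seq: str, context: str) -> str:
    bad = set(seq) - _VALID
    if bad:
        raise InputError(
            f"illegal residue(s) {sorted(bad)} in {context}; expected A/C/G/T/N"
        )
    return seq


@dataclasses.dataclass(frozen=True)
class CircularChromosome:
    """One named circular DNA sequence.

    ``circular`` defaults to True: every chromosome of a multipartite
    mitogenome, and every predicted recombination product, is treated as a
    circle.  A linear flag exists for completeness but nothing in the
    pipeline sets it.
    """

    id: str
    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise InputError(f"chromosome {self.id!r} is empty")
        _check_alphabet(self.residues, f"chromosome {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclasses.dataclass(frozen=True)
class Genome:
    """An ordered collection of uniquely named circular chromosomes."""

    chromosomes: tuple[CircularChromosome, ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise InputError("genome has no chromosomes")
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate chromosome id(s): {dup}")

    def __iter__(self) -> Iterator[CircularChromosome]:
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __getitem__(self, chrom_id: str) -> CircularChromosome:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise KeyError(chrom_id)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "Genome":
        return cls(tuple(CircularChromosome(k, v) for k, v in seqs.items()))


@dataclasses.dataclass(frozen=True)
class Locus:
    """A 1-based inclusive interval on a named chromosome with a strand.

    HSP tables give minus-strand hits as start > end; use
    :meth:`from_hsp_coords` to normalise.  After construction start <= end
    always holds except for loci that wrap the circular origin, which are
    stored as (start > end) with strand kept explicit.
    """

    chrom_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"bad strand {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise InputError(f"coordinates must be >= 1, got {self}")

    @classmethod
    def from_hsp_coords(cls, chrom_id: str, start: int, end: int) -> "Locus":
        """Normalise BLAST-style coordinates (minus strand has start > end)."""
        if start > end:
            return cls(chrom_id, end, start, "-")
        return cls(chrom_id, start, end, "+")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Locus") -> bool:
        return (
            self.chrom_id == other.chrom_id
            and self.start <= other.end
            and other.start <= self.end
        )


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    _check_alphabet(seq, "sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def extract_circular(chrom: CircularChromosome, start: int, end: int) -> str:
    """Residues ``start..end`` (1-based, inclusive), wrapping the origin.

    When ``start > end`` the slice runs forward through the origin, so the
    result length is ``((end - start) mod length) + 1``.
    """
    n = chrom.length
    if not (1 <= start <= n) or not (1 <= end <= n):
        raise InputError(
            f"coordinates ({start}, {end}) out of range for "
            f"{chrom.id!r} of length {n}"
        )
    if start <= end:
        return chrom.residues[start - 1 : end]
    if not chrom.circular:
        raise InputError(f"wrap-around slice on linear chromosome {chrom.id!r}")
    return chrom.residues[start - 1 :] + chrom.residues[:end]


def extract_locus(genome: Genome, locus: Locus) -> str:
    """Sequence of a locus on its reported strand (minus => reverse complement)."""
    seq = extract_circular(genome[locus.chrom_id], locus.start, locus.end)
    return reverse_complement(seq) if locus.strand == "-" else seq


def read_fasta(path: str | Path) -> Genome:
    """Read a multi-FASTA into a Genome.

    Residues are uppercased and U is converted to T; anything outside
    {A,C,G,T,N} is rejected with the offending record named.
    """
    path = Path(path)
    chroms: list[CircularChromosome] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise InputError(f"empty record {rec.id!r} in {path}")
        bad = set(seq) - _VALID
        if bad:
            raise InputError(
                f"record {rec.id!r} in {path} has illegal residue(s) {sorted(bad)}"
            )
        chroms.append(CircularChromosome(rec.id, seq))
    if not chroms:
        raise InputError(f"no FASTA records in {path}")
    return Genome(tuple(chroms))


def write_fasta(
    records: Genome | Iterable[tuple[str, str]], path: str | Path, width: int = 70
) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    if isinstance(records, Genome):
        items = [(c.id, c.residues) for c in records]
    else:
        items = list(records)
    seqrecs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(seqrecs)


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read long reads from FASTA or FASTQ (qualities ignored)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        out.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write (chrom, start_1based, end_1based, name) as 0-based half-open BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
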