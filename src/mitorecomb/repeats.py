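"""Repeat-pair (HSP) discovery and ingestion.

A "repeat pair" is operationally one high-scoring segment pair between two
genomic loci.  Pairs can be discovered internally (:func:`find_repeats`,
a seed-and-extend scorer) or ingested from a BLAST tabular (outfmt 6) file
produced by an external search (:func:`parse_hsp_table`), which is the route
to reproduce a published repeat table bit-exactly.

Orientation follows the BLAST convention: a subject interval reported with
start > end means the second copy lies on the minus strand, i.e. the pair is
an inverted repeat; otherwise it is direct.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

from .alignment import RawHit, ScoringScheme, homology_search
from .sequence import Genome, InputError, Locus

__all__ = ["RepeatPair", "find_repeats", "parse_hsp_table", "write_repeat_table"]

DIRECT = "direct"
INVERTED = "inverted"


@dataclasses.dataclass(frozen=True)
class RepeatPair:
    """One HSP between two genomic loci with alignment statistics."""

    id: str
    copy1: Locus
    copy2: Locus
    orientation: str  # direct | inverted
    identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    evalue: float

    def __post_init__(self) -> None:
        if self.orientation not in (DIRECT, INVERTED):
            raise InputError(f"bad orientation {self.orientation!r}")
        if not (0 < self.identity <= 100):
            raise InputError(f"identity {self.identity} outside (0, 100]")
        if self.aln_length < 1:
            raise InputError("alignment length must be >= 1")

    @property
    def inter_molecular(self) -> bool:
        return self.copy1.chrom_id != self.copy2.chrom_id


def _hit_to_pair(hit: RawHit, pair_id: str) -> RepeatPair:
    orientation = INVERTED if hit.s_strand == "-" else DIRECT
    return RepeatPair(
        id=pair_id,
        copy1=Locus(hit.q_id, hit.q_start, hit.q_end, "+"),
        copy2=Locus(hit.s_id, hit.s_start, hit.s_end, hit.s_strand),
        orientation=orientation,
        identity=round(hit.identity, 3),
        aln_length=hit.aln_length,
        mismatches=hit.mismatches,
        gap_opens=hit.gap_opens,
        evalue=hit.evalue,
    )


def find_repeats(
    genome: Genome,
    min_word: int = 7,
    evalue_cutoff: float = 1e-6,
    min_length: int = 50,
    top_k: int | None = None,
    scoring: ScoringScheme | None = None,
) -> list[RepeatPair]:
    """Discover repeat pairs within a genome (both strands, all chromosome
    pairs including self).

    Trivial self-hits are removed, mirror duplicates collapsed with the
    positionally smaller locus as copy1, and HSPs subsumed by a longer HSP
    on the same diagonal dropped.  Pairs are labelled r01, r02, ... in order
    of decreasing alignment length; ``top_k`` keeps only the longest k -
    together with ``min_length`` this is the explicit candidate filter
    (there is no hidden heuristic between the raw HSP list and the
    reported table).
    """
    hits = homology_search(
        genome,
        None,
        word_size=min_word,
        evalue_cutoff=evalue_cutoff,
        min_length=min_length,
        scoring=scoring,
    )
    hits.sort(key=lambda h: (-h.aln_length, h.q_id, h.q_start))
    if top_k is not None:
        hits = hits[:top_k]
    return [_hit_to_pair(h, f"r{i + 1:02d}") for i, h in enumerate(hits)]


_OUTFMT6_MIN_COLS = 11  # bitscore column optional


def parse_hsp_table(path: str | Path) -> list[RepeatPair]:
    """Read repeat pairs from BLAST tabular output (outfmt 6).

    Expected columns: qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue [bitscore].  sstart > send marks an
    inverted pair.
    """
    pairs: list[RepeatPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _OUTFMT6_MIN_COLS:
                raise InputError(
                    f"{path}:{lineno}: expected >= {_OUTFMT6_MIN_COLS} "
                    f"tab-separated columns, got {len(fields)}"
                )
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                mismatch = int(fields[4])
                gapopen = int(fields[5])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: malformed row ({exc})") from exc
            copy1 = Locus.from_hsp_coords(qid, qstart, qend)
            copy2 = Locus.from_hsp_coords(sid, sstart, send)
            orientation = INVERTED if sstart > send else DIRECT
            pairs.append(
                RepeatPair(
                    id=f"r{len(pairs) + 1:02d}",
                    copy1=copy1,
                    copy2=copy2,
                    orientation=orientation,
                    identity=pident,
                    aln_length=length,
                    mismatches=mismatch,
                    gap_opens=gapopen,
                    evalue=evalue,
                )
            )
    return pairs


_TABLE_HEADER = [
    "repeat_id",
    "identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "copy1_chrom",
    "copy1_start",
    "copy1_end",
    "copy2_chrom",
    "copy2_start",
    "copy2_end",
    "evalue",
    "type",
]


def write_repeat_table(pairs: Iterable[RepeatPair], path: str | Path) -> None:
    """Write repeat pairs as a TSV mirroring the standard HSP-table columns."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_HEADER) + "\n")
        for p in pairs:
            c2s, c2e = p.copy2.start, p.copy2.end
            if p.orientation == INVERTED:
                c2s, c2e = c2e, c2s  # report minus strand as start > end
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        p.id,
                        p.identity,
                        p.aln_length,
                        p.mismatches,
                        p.gap_opens,
                        p.copy1.chrom_id,
                        p.copy1.start,
                        p.copy1.end,
                        p.copy2.chrom_id,
                        c2s,
                        c2e,
                        f"{p.evalue:.3g}",
                        p.orientation,
                    )
                )
                + "\n"
            )
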