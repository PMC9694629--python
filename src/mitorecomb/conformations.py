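"""Four-conformation reference sequences around a repeat pair.

Recombination between two repeat copies exchanges their flanking sequences.
Around each repeat we therefore build four references:

* C1 = U1-R1-D1 and C2 = U2-R2-D2 - the two arrangements present in the
  assembly (the major conformations, one per repeat copy);
* C3 = U1-R1-D2 and C4 = U2-R2-D1 - the flank-switched arrangements
  diagnostic of the recombined (minor) conformations.

For an inverted repeat, copy2's context is first rewritten in the
reverse-complement frame so both copies read the repeat on the same strand;
the same flank-switch rule then applies.  All four sequences are reported on
the frame of copy1's plus strand.  Flanks wrap the circular origin.

A long read that covers one of these references across the repeat with
anchors in both flanks identifies which conformation the source molecule
carried (see :mod:`mitorecomb.support`).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .repeats import INVERTED, RepeatPair
from .sequence import (
    CircularChromosome,
    Genome,
    InputError,
    extract_circular,
    reverse_complement,
    write_fasta,
)

__all__ = ["JunctionSet", "build_conformations", "write_conformation_fasta"]

LABELS = ("C1", "C2", "C3", "C4")
ROLES = {"C1": "Mac-copy1", "C2": "Mac-copy2", "C3": "Mic-1", "C4": "Mic-2"}


@dataclasses.dataclass(frozen=True)
class JunctionSet:
    """The four junction references around one repeat.

    ``upstream_lengths``/``repeat_lengths`` give, per label, the offset of
    the repeat body inside the reference and its length, so a classifier can
    cut anchor+repeat+anchor cores without re-deriving coordinates.
    """

    repeat_id: str
    flank: int
    C1: str
    C2: str
    C3: str
    C4: str
    upstream_lengths: dict[str, int]
    repeat_lengths: dict[str, int]
    warnings: tuple[str, ...] = ()
    roles: dict[str, str] = dataclasses.field(default_factory=lambda: dict(ROLES))

    def sequence(self, label: str) -> str:
        if label not in LABELS:
            raise InputError(f"unknown conformation label {label!r}")
        return getattr(self, label)

    def core(self, label: str, anchor: int) -> str:
        """Repeat body plus ``anchor`` bases of both flanks (clipped to ends)."""
        seq = self.sequence(label)
        u = self.upstream_lengths[label]
        r = self.repeat_lengths[label]
        return seq[max(0, u - anchor) : min(len(seq), u + r + anchor)]


def _mod_pos(pos: int, length: int) -> int:
    return (pos - 1) % length + 1


def _flank_upstream(chrom: CircularChromosome, start: int, flank: int) -> str:
    if flank == 0:
        return ""
    s = _mod_pos(start - flank, chrom.length)
    e = _mod_pos(start - 1, chrom.length)
    return extract_circular(chrom, s, e)


def _flank_downstream(chrom: CircularChromosome, end: int, flank: int) -> str:
    if flank == 0:
        return ""
    s = _mod_pos(end + 1, chrom.length)
    e = _mod_pos(end + flank, chrom.length)
    return extract_circular(chrom, s, e)


def _copy_positions(chrom: CircularChromosome, start: int, end: int, flank: int) -> set[int]:
    """Genomic positions (mod L) covered by window [start-flank, end+flank]."""
    span = (end - start) % chrom.length + 1
    first = start - flank
    return {_mod_pos(first + i, chrom.length) for i in range(span + 2 * flank)}


def build_conformations(
    genome: Genome, repeat: RepeatPair, flank: int = 500, max_span: int = 5000
) -> JunctionSet:
    """Build C1-C4 around ``repeat`` with ``flank`` bases of context.

    Each reference has length repeat-copy length + 2*flank, clipped only when
    a chromosome is too short for the requested window.  Warnings (not
    errors) are recorded when the two copies' windows overlap within one
    conformation - junction support becomes ambiguous - and when the repeat
    body exceeds ``max_span`` (few reads can span it).
    """
    if flank < 1:
        raise InputError("flank must be >= 1")
    chrom1 = genome[repeat.copy1.chrom_id]
    chrom2 = genome[repeat.copy2.chrom_id]

    span1 = (repeat.copy1.end - repeat.copy1.start) % chrom1.length + 1
    span2 = (repeat.copy2.end - repeat.copy2.start) % chrom2.length + 1
    flank1 = min(flank, max(0, (chrom1.length - span1) // 2))
    flank2 = min(flank, max(0, (chrom2.length - span2) // 2))

    warnings: list[str] = []
    if flank1 < flank or flank2 < flank:
        warnings.append(
            f"flank clipped to ({flank1}, {flank2}) bp: chromosome shorter "
            "than the requested window"
        )
    if max(span1, span2) > max_span:
        warnings.append(
            f"repeat body spans {max(span1, span2)} bp > max_span {max_span}; "
            "few reads will span it"
        )

    r1 = extract_circular(chrom1, repeat.copy1.start, repeat.copy1.end)
    u1 = _flank_upstream(chrom1, repeat.copy1.start, flank1)
    d1 = _flank_downstream(chrom1, repeat.copy1.end, flank1)

    r2_plus = extract_circular(chrom2, repeat.copy2.start, repeat.copy2.end)
    u2_plus = _flank_upstream(chrom2, repeat.copy2.start, flank2)
    d2_plus = _flank_downstream(chrom2, repeat.copy2.end, flank2)
    if repeat.orientation == INVERTED:
        # rewrite copy2's context on the strand where it reads like copy1
        r2 = reverse_complement(r2_plus)
        u2 = reverse_complement(d2_plus)
        d2 = reverse_complement(u2_plus)
    else:
        r2, u2, d2 = r2_plus, u2_plus, d2_plus

    if not repeat.inter_molecular:
        w1 = _copy_positions(chrom1, repeat.copy1.start, repeat.copy1.end, flank1)
        w2 = _copy_positions(chrom2, repeat.copy2.start, repeat.copy2.end, flank2)
        if w1 & w2:
            warnings.append(
                "the two repeat-copy windows overlap on the genome; "
                "junction support is ambiguous"
            )

    # recombinant references carry the repeat body of the copy contributing
    # the upstream flank (R1 for C3, R2 for C4)
    c1 = u1 + r1 + d1
    c2 = u2 + r2 + d2
    c3 = u1 + r1 + d2
    c4 = u2 + r2 + d1
    return JunctionSet(
        repeat_id=repeat.id,
        flank=flank,
        C1=c1,
        C2=c2,
        C3=c3,
        C4=c4,
        upstream_lengths={
            "C1": len(u1),
            "C2": len(u2),
            "C3": len(u1),
            "C4": len(u2),
        },
        repeat_lengths={
            "C1": len(r1),
            "C2": len(r2),
            "C3": len(r1),
            "C4": len(r2),
        },
        warnings=tuple(warnings),
    )


def write_conformation_fasta(junctions: JunctionSet, path: str | Path) -> None:
    """Write the four references as FASTA, headers ``<repeat_id>|C1|Mac-copy1``."""
    write_fasta(
        (
            (f"{junctions.repeat_id}|{lab}|{ROLES[lab]}", junctions.sequence(lab))
            for lab in LABELS
        ),
        path,
    )
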