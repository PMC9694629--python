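"""Circular-molecule rearrangement algebra for repeat-mediated recombination.

A genome is decomposed into circular molecules whose elements are repeat-copy
markers and the inter-repeat segments between them.  Reciprocal exchange at
the two copies of a repeat then has three outcomes, depending on where the
copies sit and how they read:

* both copies on one circle, same reading direction (direct): the circle
  **splits** into two circles, each carrying one copy;
* both copies on one circle, opposite directions (inverted): **one** circle
  with the segment between the copies reverse-complemented;
* copies on two circles: the circles **fuse** into one (a circle's reference
  frame is flipped first if needed so the copies read the same way).

Total length is conserved in every case, repeat copies are treated as atomic
blocks, and recombining twice at the same repeat is an involution (up to
rotation/strand choice of the circles).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

from .repeats import RepeatPair
from .sequence import Genome, InputError, Locus, extract_circular, reverse_complement

__all__ = [
    "Segment",
    "Molecule",
    "MoleculeSet",
    "genome_to_molecules",
    "recombine",
    "enumerate_conformation_space",
    "realize_sequence",
]


@dataclasses.dataclass(frozen=True)
class Segment:
    """A stretch of DNA in a molecule: an inter-repeat segment or, when
    ``repeat_id`` is set, one repeat-copy marker.

    ``sign`` is the reading direction of ``source`` (always a plus-strand
    genomic interval) within the molecule; ``copy_strand`` is the strand on
    which this repeat copy matches the repeat consensus (from the HSP).
    """

    id: str
    length: int
    sign: str = "+"
    source: Locus | None = None
    repeat_id: str | None = None
    copy_index: int | None = None
    copy_strand: str = "+"

    def __post_init__(self) -> None:
        if self.length < 0:
            raise InputError("segment length must be >= 0")
        if self.sign not in "+-":
            raise InputError(f"bad sign {self.sign!r}")

    @property
    def is_marker(self) -> bool:
        return self.repeat_id is not None

    @property
    def effective_strand(self) -> str:
        """Direction the repeat consensus reads in the molecule traversal."""
        return "+" if self.sign == self.copy_strand else "-"

    def flipped(self) -> "Segment":
        return dataclasses.replace(self, sign="-" if self.sign == "+" else "+")


@dataclasses.dataclass(frozen=True)
class Molecule:
    """A circular molecule as a cyclically ordered list of segments."""

    id: str
    segments: tuple[Segment, ...]

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    def rotated_to(self, index: int) -> "Molecule":
        segs = self.segments[index:] + self.segments[:index]
        return dataclasses.replace(self, segments=segs)

    def flipped(self) -> "Molecule":
        """The same circle read on the opposite strand."""
        return dataclasses.replace(
            self, segments=tuple(s.flipped() for s in reversed(self.segments))
        )

    def marker_index(self, repeat_id: str, copy_index: int) -> int | None:
        for i, s in enumerate(self.segments):
            if s.repeat_id == repeat_id and s.copy_index == copy_index:
                return i
        return None

    def canonical(self) -> tuple:
        """Rotation- and strand-invariant signature of the circle."""
        best = None
        for mol in (self, self.flipped()):
            n = len(mol.segments)
            for i in range(n):
                sig = tuple(
                    (s.id, s.sign, s.length)
                    for s in mol.segments[i:] + mol.segments[:i]
                )
                if best is None or sig < best:
                    best = sig
        return best if best is not None else ()


@dataclasses.dataclass(frozen=True)
class MoleculeSet:
    molecules: tuple[Molecule, ...]
    label: str = "Mac"  # Mac (assembly arrangement) or Mic (recombined)
    provenance: str = "assembly"

    @property
    def total_length(self) -> int:
        return sum(m.length for m in self.molecules)

    def canonical(self) -> tuple:
        """Multiset signature of the circles, invariant to rotation/strand."""
        return tuple(sorted(m.canonical() for m in self.molecules))

    def find_marker(self, repeat_id: str, copy_index: int) -> tuple[int, int]:
        for mi, mol in enumerate(self.molecules):
            si = mol.marker_index(repeat_id, copy_index)
            if si is not None:
                return mi, si
        raise InputError(
            f"repeat {repeat_id!r} copy {copy_index} absent from molecule set"
        )


def _copy_tuple(repeat: RepeatPair, copy_index: int) -> tuple[str, int, int, str]:
    locus = repeat.copy1 if copy_index == 1 else repeat.copy2
    return locus.chrom_id, locus.start, locus.end, locus.strand


def genome_to_molecules(genome: Genome, repeats: Sequence[RepeatPair]) -> MoleculeSet:
    """Decompose chromosomes into circles of repeat markers and segments.

    Repeat copies must not overlap one another (raises listing the clash).
    Zero-length gaps between adjacent copies are omitted.
    """
    placed: dict[str, list[tuple[int, int, Segment]]] = {c.id: [] for c in genome}
    for rep in repeats:
        for ci in (1, 2):
            chrom_id, start, end, strand = _copy_tuple(rep, ci)
            chrom = genome[chrom_id]
            span = (end - start) % chrom.length + 1
            marker = Segment(
                id=f"{rep.id}.{ci}",
                length=span,
                sign="+",
                source=Locus(chrom_id, start, end, "+"),
                repeat_id=rep.id,
                copy_index=ci,
                copy_strand=strand,
            )
            placed[chrom_id].append((start, end, marker))

    for chrom_id, items in placed.items():
        L = genome[chrom_id].length
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                if _circular_overlap(items[i][:2], items[j][:2], L):
                    raise InputError(
                        f"repeat copies {items[i][2].id} and {items[j][2].id} "
                        f"overlap on {chrom_id}"
                    )

    molecules = []
    seg_counter = 0
    for chrom in genome:
        items = sorted(placed[chrom.id], key=lambda t: t[0])
        if not items:
            seg_counter += 1
            molecules.append(
                Molecule(
                    chrom.id,
                    (
                        Segment(
                            id=f"s{seg_counter:02d}",
                            length=chrom.length,
                            source=Locus(chrom.id, 1, chrom.length, "+"),
                        ),
                    ),
                )
            )
            continue
        segs: list[Segment] = []
        L = chrom.length
        for k, (start, end, marker) in enumerate(items):
            segs.append(marker)
            nxt_start = items[(k + 1) % len(items)][0]
            gap = (nxt_start - end - 1) % L
            if gap:
                seg_counter += 1
                gs = (end % L) + 1
                ge = (nxt_start - 2) % L + 1
                segs.append(
                    Segment(
                        id=f"s{seg_counter:02d}",
                        length=gap,
                        source=Locus(chrom.id, gs, ge, "+"),
                    )
                )
        molecules.append(Molecule(chrom.id, tuple(segs)))
    return MoleculeSet(tuple(molecules), label="Mac", provenance="assembly")


def _circular_overlap(a: tuple[int, int], b: tuple[int, int], length: int) -> bool:
    def positions(iv: tuple[int, int]) -> set[int]:
        s, e = iv
        span = (e - s) % length + 1
        return {(s - 1 + i) % length for i in range(span)}

    return bool(positions(a) & positions(b))


def recombine(mols: MoleculeSet, repeat_id: str) -> MoleculeSet:
    """Reciprocal exchange at the two copies of ``repeat_id``.

    Returns a new MoleculeSet labelled ``Mic`` with provenance ``repeat_id``.
    Total length and the multiset of markers are conserved.
    """
    m1, s1 = mols.find_marker(repeat_id, 1)
    m2, s2 = mols.find_marker(repeat_id, 2)
    untouched = tuple(
        mol for i, mol in enumerate(mols.molecules) if i not in (m1, m2)
    )

    if m1 == m2:
        mol = mols.molecules[m1].rotated_to(s1)
        idx2 = mol.marker_index(repeat_id, 2)
        assert idx2 is not None
        head, between, after = mol.segments[0], mol.segments[1:idx2], mol.segments[idx2:]
        marker2, tail = after[0], after[1:]
        if head.effective_strand == marker2.effective_strand:
            # direct: split into two circles, one copy each
            out = (
                Molecule(f"{mol.id}:{repeat_id}:a", (head,) + between),
                Molecule(f"{mol.id}:{repeat_id}:b", (marker2,) + tail),
            )
        else:
            # inverted: reverse-complement the intervening segment
            inverted = tuple(s.flipped() for s in reversed(between))
            out = (
                Molecule(
                    f"{mol.id}:{repeat_id}:inv",
                    (head,) + inverted + (marker2,) + tail,
                ),
            )
    else:
        molA = mols.molecules[m1].rotated_to(s1)
        molB = mols.molecules[m2]
        idxB = molB.marker_index(repeat_id, 2)
        assert idxB is not None
        if molA.segments[0].effective_strand != molB.segments[idxB].effective_strand:
            molB = molB.flipped()
            idxB = molB.marker_index(repeat_id, 2)
            assert idxB is not None
        molB = molB.rotated_to(idxB)
        out = (
            Molecule(
                f"{molA.id}+{molB.id}:{repeat_id}",
                molA.segments + molB.segments,
            ),
        )

    result = MoleculeSet(untouched + out, label="Mic", provenance=repeat_id)
    assert result.total_length == mols.total_length
    return result


def enumerate_conformation_space(
    mols: MoleculeSet, active_repeats: Sequence[RepeatPair | str], depth: int = 1
) -> list[MoleculeSet]:
    """Single-event minor conformations, one per active repeat.

    ``depth > 1`` composes up to ``depth`` events breadth-first, returning
    every distinct product (canonical de-duplication over rotations and
    strand choices, compared as multisets of circles).
    """
    rep_ids = [r if isinstance(r, str) else r.id for r in active_repeats]
    products: list[MoleculeSet] = []
    seen = {mols.canonical()}
    frontier = [mols]
    for _ in range(max(depth, 0)):
        nxt = []
        for ms in frontier:
            for rid in rep_ids:
                try:
                    prod = recombine(ms, rid)
                except InputError:
                    continue
                key = prod.canonical()
                if key in seen:
                    continue
                seen.add(key)
                products.append(prod)
                nxt.append(prod)
        frontier = nxt
    return products


def realize_sequence(molecule: Molecule, genome: Genome) -> str:
    """Materialise a molecule as a DNA string from genome coordinates."""
    parts = []
    for seg in molecule.segments:
        if seg.source is None:
            raise InputError(f"segment {seg.id!r} has no genomic source")
        seq = extract_circular(genome[seg.source.chrom_id], seg.source.start, seg.source.end)
        parts.append(reverse_complement(seq) if seg.sign == "-" else seq)
    out = "".join(parts)
    assert len(out) == molecule.length
    return out


def write_structure_report(sets: Iterable[MoleculeSet], path: str | Path) -> None:
    """JSON report of molecules, segments, lengths and provenance."""
    payload = []
    for ms in sets:
        payload.append(
            {
                "label": ms.label,
                "provenance": ms.provenance,
                "total_length": ms.total_length,
                "molecules": [
                    {
                        "id": m.id,
                        "length": m.length,
                        "segments": [
                            {
                                "id": s.id,
                                "length": s.length,
                                "sign": s.sign,
                                "repeat_id": s.repeat_id,
                                "copy_index": s.copy_index,
                            }
                            for s in m.segments
                        ],
                    }
                    for m in ms.molecules
                ],
            }
        )
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
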