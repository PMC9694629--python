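"""Microsatellite (SSR) scanning with MISA-style copy-number thresholds.

An SSR is a maximal perfect tandem run of a 1-6 bp unit meeting a per-unit
copy threshold (defaults: mono >= 10 copies, di >= 5, tri >= 4,
tetra/penta/hexa >= 3).  Runs whose unit is itself a tandem of a shorter
unit (a non-primitive unit, e.g. "ATAT" as a tetramer) are reported once at
the shortest unit length.  Overlapping candidates are resolved in favour of
the longer run, ties to the smaller unit.

Unlike MISA, interrupted (compound) SSRs are not merged into single
records by default; :func:`group_compound` groups nearby records when
compound bookkeeping is wanted.  Chromosomes are scanned as deposited
(linear frame); a run split by the circular origin is reported as its two
arcs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .sequence import Genome, InputError, write_bed

__all__ = ["SSRRecord", "SSRThresholds", "scan_ssrs", "write_ssr_table", "group_compound"]

DEFAULT_MIN_COPIES: dict[int, int] = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclasses.dataclass(frozen=True)
class SSRThresholds:
    """Minimum perfect copy number per unit length (1..6 bp)."""

    min_copies: Mapping[int, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MIN_COPIES)
    )

    def __post_init__(self) -> None:
        for u in range(1, 7):
            if u not in self.min_copies:
                raise InputError(f"missing threshold for unit length {u}")
            if self.min_copies[u] < 2:
                raise InputError("copy thresholds must be >= 2")


@dataclasses.dataclass(frozen=True)
class SSRRecord:
    chrom_id: str
    motif: str  # canonical: lexicographically smallest rotation, reported strand
    unit_length: int
    copies: int
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.unit_length * self.copies:
            raise InputError("SSR span must equal unit_length * copies")


def _is_primitive(unit: str) -> bool:
    """True when the unit is not a whole number of copies of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit[:d] * (n // d) == unit:
            return False
    return True


def _canonical_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def scan_ssrs(
    genome: Genome, thresholds: SSRThresholds | None = None
) -> list[SSRRecord]:
    """Scan every chromosome for SSRs meeting the copy thresholds."""
    thresholds = thresholds or SSRThresholds()
    out: list[SSRRecord] = []
    for chrom in genome:
        out.extend(_scan_one(chrom.id, chrom.residues, thresholds))
    return out


def _candidates(seq: str, thresholds: SSRThresholds) -> list[tuple[int, int, int]]:
    """Maximal perfect runs as (start0, unit, copies) passing the thresholds."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    cands: list[tuple[int, int, int]] = []
    for u in range(1, 7):
        need = thresholds.min_copies[u]
        if n < u * need:
            continue
        eq = arr[: n - u] == arr[u:]
        # maximal runs of consecutive matches
        padded = np.concatenate(([False], eq, [False]))
        diffs = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diffs == 1)[0]
        ends = np.nonzero(diffs == -1)[0]  # exclusive in eq-space
        for s0, e0 in zip(starts, ends):
            span = (e0 - s0) + u  # periodic stretch length
            copies = span // u
            if copies < need:
                continue
            unit = seq[s0 : s0 + u]
            if "N" in unit or not _is_primitive(unit):
                continue
            cands.append((int(s0), u, int(copies)))
    return cands


def _scan_one(chrom_id: str, seq: str, thresholds: SSRThresholds) -> list[SSRRecord]:
    cands = _candidates(seq, thresholds)
    # longer run wins; ties to the smaller unit, then to the earlier start
    cands.sort(key=lambda c: (-(c[1] * c[2]), c[1], c[0]))
    accepted: list[tuple[int, int]] = []  # 0-based half-open
    records: list[SSRRecord] = []
    for s0, u, copies in cands:
        e0 = s0 + u * copies
        if any(s0 < be and bs < e0 for bs, be in accepted):
            continue
        accepted.append((s0, e0))
        records.append(
            SSRRecord(
                chrom_id=chrom_id,
                motif=_canonical_rotation(seq[s0 : s0 + u]),
                unit_length=u,
                copies=copies,
                start=s0 + 1,
                end=e0,
            )
        )
    records.sort(key=lambda r: r.start)
    return records


def group_compound(
    records: list[SSRRecord], max_distance: int = 100
) -> list[list[SSRRecord]]:
    """Group same-chromosome SSRs separated by <= max_distance bp.

    This mirrors MISA's compound-SSR bookkeeping without collapsing the
    member records; each group is returned in genomic order.
    """
    groups: list[list[SSRRecord]] = []
    for rec in sorted(records, key=lambda r: (r.chrom_id, r.start)):
        if (
            groups
            and groups[-1][-1].chrom_id == rec.chrom_id
            and rec.start - groups[-1][-1].end - 1 <= max_distance
        ):
            groups[-1].append(rec)
        else:
            groups.append([rec])
    return groups


def write_ssr_table(records: Iterable[SSRRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tmotif\tunit_length\tcopies\tstart\tend\n")
        for r in records:
            fh.write(
                f"{r.chrom_id}\t{r.motif}\t{r.unit_length}\t{r.copies}"
                f"\t{r.start}\t{r.end}\n"
            )


def write_ssr_bed(records: Iterable[SSRRecord], path: str | Path) -> None:
    write_bed(
        ((r.chrom_id, r.start, r.end, f"({r.motif}){r.copies}") for r in records),
        path,
    )
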