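"""Spanning-read classification and the recombination-frequency statistic.

A long read is informative about the arrangement at a repeat only if it
spans the repeat body with anchoring sequence in both flanks - otherwise it
aligns equally well to all four junction references.  Each read (and its
reverse complement) is aligned semi-globally against the
anchor+repeat+anchor core of each reference (edlib, infix mode); a
reference is a spanning candidate when the core is found within the read at
edit divergence <= ``max_divergence``.  The best candidate wins; exact ties
are ambiguous; no candidate means the read does not span the repeat.

The recombination frequency at a repeat is the fraction of confidently
assigned spanning reads that support the two minor (flank-switched)
references:

    f = 100 * (Mic1 + Mic2) / (Mac1 + Mac2 + Mic1 + Mic2)

Ambiguous reads are excluded from the denominator.
"""

from __future__ import annotations

import dataclasses
import warnings as _warnings
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import edlib

from .conformations import LABELS, JunctionSet
from .repeats import RepeatPair
from .sequence import reverse_complement

__all__ = [
    "SupportCounts",
    "RecombRecord",
    "classify_read",
    "count_support",
    "recombination_frequency",
    "call_active_repeats",
    "write_support_table",
]

AMBIGUOUS = "ambiguous"
UNSPANNING = "unspanning"


@dataclasses.dataclass(frozen=True)
class SupportCounts:
    """Per-conformation spanning-read tallies at one repeat."""

    repeat_id: str
    mac1: int = 0  # reads supporting C1
    mac2: int = 0  # C2
    mic1: int = 0  # C3
    mic2: int = 0  # C4
    ambiguous: int = 0
    unspanning: int = 0

    def __post_init__(self) -> None:
        for f in ("mac1", "mac2", "mic1", "mic2", "ambiguous", "unspanning"):
            if getattr(self, f) < 0:
                raise ValueError(f"count {f} is negative")

    @property
    def assigned(self) -> int:
        return self.mac1 + self.mac2 + self.mic1 + self.mic2


@dataclasses.dataclass
class RecombRecord:
    """A repeat with its read support, frequency, and activity call."""

    repeat: RepeatPair
    counts: SupportCounts
    frequency: float | None = None
    active: bool = False


def classify_read(
    read: str,
    junctions: JunctionSet,
    min_anchor: int = 100,
    max_divergence: float = 0.15,
) -> str:
    """Assign a read to C1/C2/C3/C4, or call it ambiguous/unspanning.

    The read must contain, as an infix, the full repeat body plus
    ``min_anchor`` bases of both flanks of the winning reference (clipped to
    the available flank), within edit divergence ``max_divergence``.
    """
    if not read:
        return UNSPANNING
    strands = (read, reverse_complement(read))
    max_div = Fraction(max_divergence).limit_denominator(10**6)
    best_label: str | None = None
    best_div: Fraction | None = None
    tie = False
    for label in LABELS:
        core = junctions.core(label, min_anchor)
        if not core:
            continue
        # distances above the divergence cutoff can never win or tie, so
        # let edlib bail out early via its k bound
        k = int(max_divergence * len(core))
        dists = [
            edlib.align(core, s, mode="HW", task="distance", k=k)["editDistance"]
            for s in strands
        ]
        dists = [d for d in dists if d >= 0]
        if not dists:
            continue
        div = Fraction(min(dists), len(core))
        if div > max_div:
            continue
        if best_div is None or div < best_div:
            best_label, best_div, tie = label, div, False
        elif div == best_div:
            tie = True
    if best_label is None:
        return UNSPANNING
    if tie:
        return AMBIGUOUS
    return best_label


def count_support(
    reads: Iterable[str | tuple[str, str]],
    junctions: JunctionSet,
    min_anchor: int = 100,
    max_divergence: float = 0.15,
) -> SupportCounts:
    """Tally :func:`classify_read` outcomes over a read collection.

    Reads may be plain sequences or (name, sequence) pairs.
    """
    tally = {lab: 0 for lab in LABELS}
    tally[AMBIGUOUS] = 0
    tally[UNSPANNING] = 0
    for read in reads:
        seq = read[1] if isinstance(read, tuple) else read
        tally[classify_read(seq, junctions, min_anchor, max_divergence)] += 1
    return SupportCounts(
        repeat_id=junctions.repeat_id,
        mac1=tally["C1"],
        mac2=tally["C2"],
        mic1=tally["C3"],
        mic2=tally["C4"],
        ambiguous=tally[AMBIGUOUS],
        unspanning=tally[UNSPANNING],
    )


def recombination_frequency(counts: SupportCounts) -> float | None:
    """Minor-conformation fraction as a percentage, rounded half-up to
    2 decimals; None (with a warning) when no read was assigned."""
    denom = counts.assigned
    if denom == 0:
        _warnings.warn(
            f"repeat {counts.repeat_id}: no assigned spanning reads; "
            "frequency undefined",
            stacklevel=2,
        )
        return None
    frac = Decimal(100 * (counts.mic1 + counts.mic2)) / Decimal(denom)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def call_active_repeats(
    records: Sequence[RecombRecord],
    min_each_mic: int = 1,
    min_total_mic: int = 2,
    max_repeat_span: int = 5000,
) -> list[RecombRecord]:
    """Flag repeats whose minor conformations are credibly read-supported.

    A repeat is called recombinationally active when both minor references
    have >= ``min_each_mic`` supporting reads, their sum is >=
    ``min_total_mic``, and the repeat body is <= ``max_repeat_span`` bp
    (reads spanning a very long repeat are too scarce for the call to be
    meaningful, and such products resist independent validation).
    """
    out = []
    for rec in records:
        c = rec.counts
        active = (
            c.mic1 >= min_each_mic
            and c.mic2 >= min_each_mic
            and c.mic1 + c.mic2 >= min_total_mic
            and rec.repeat.aln_length <= max_repeat_span
        )
        out.append(dataclasses.replace(rec, active=active))
    return out


_SUPPORT_HEADER = [
    "repeat_id",
    "identity",
    "aln_length",
    "type",
    "mac1",
    "mac2",
    "mic1",
    "mic2",
    "ambiguous",
    "unspanning",
    "recomb_frequency_pct",
    "active",
]


def write_support_table(records: Iterable[RecombRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SUPPORT_HEADER) + "\n")
        for r in records:
            freq = "NA" if r.frequency is None else f"{r.frequency:.2f}"
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.repeat.id,
                        r.repeat.identity,
                        r.repeat.aln_length,
                        r.repeat.orientation,
                        r.counts.mac1,
                        r.counts.mac2,
                        r.counts.mic1,
                        r.counts.mic2,
                        r.counts.ambiguous,
                        r.counts.unspanning,
                        freq,
                        "yes" if r.active else "no",
                    )
                )
                + "\n"
            )
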