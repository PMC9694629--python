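"""Published reference values for the *Salvia miltiorrhiza* mitogenome.

The deposited assembly (GenBank MN585275.1 / MN585276.1) comprises two
circular chromosomes, MC1 (328,915 bp) and MC2 (85,199 bp).  This module
records the published repeat (HSP) table with its PacBio spanning-read
counts, the MTPT footprint summary, and the genome-scale tallies, as plain
data: they are inputs for worked examples and cross-checks, not quantities
this package recomputes.  Recomputing the genome-scale tallies requires the
GenBank/SRA accessions themselves (see ``GENOME_SCALE_COUNTS``).
"""

from __future__ import annotations

from .repeats import RepeatPair
from .sequence import Locus
from .support import RecombRecord, SupportCounts

MC1 = "MC1"
MC2 = "MC2"
MC1_LENGTH = 328_915
MC2_LENGTH = 85_199
MITO_LENGTH = MC1_LENGTH + MC2_LENGTH  # 414,114 bp
PLASTOME_LENGTH = 151_394

MTPT_TOTAL_BP = 12_583  # non-redundant mitochondrial footprint of 16 MTPTs

#: Published tallies that derive from the full accessions (GenBank genomes
#: plus SRA long reads) and therefore cannot be recomputed from synthetic
#: desk-scale data.  Kept as reference constants only.
GENOME_SCALE_COUNTS = {
    "hsps": 72,  # self-BLASTN high-scoring pairs in MC1+MC2
    "mtpts": 16,  # plastid-derived fragments
    "ssrs": 112,  # microsatellites (99 on MC1, 13 on MC2)
}
GENOME_SCALE_COUNTS_REQUIRE_ACCESSION_DATA = True

# Candidate repeat table: id, identity %, alignment length, mismatches,
# gap opens, copy1 (chrom, start, end), copy2 (chrom, start, end as
# printed: start > end marks the minus strand), E-value, orientation,
# spanning-read counts (Mac1, Mac2, Mic1, Mic2), printed frequency %.
_ROWS = [
    ("r01", 100.000, 127, 1, 1, (MC1, 328831, 328915), (MC2, 85115, 85199), 3.51e-37, "direct", 70, 46, 5, 3, 6.45),
    ("r02", 99.853, 682, 1, 0, (MC1, 279954, 280635), (MC1, 235468, 234787), 0.0, "inverted", 31, 28, 5, 11, 21.33),
    ("r03", 100.000, 369, 0, 0, (MC1, 223308, 223676), (MC1, 27513, 27145), 0.0, "inverted", 28, 22, 5, 3, 13.79),
    ("r04", 95.312, 192, 5, 4, (MC1, 232877, 233068), (MC1, 78659, 78846), 1.53e-80, "direct", 24, 17, 1, 1, 4.65),
    ("r05", 100.000, 87, 0, 0, (MC1, 185367, 185453), (MC1, 1433, 1519), 2.72e-38, "direct", 65, 60, 2, 1, 2.34),
    ("r06", 95.139, 144, 5, 2, (MC1, 191145, 191287), (MC1, 141672, 141814), 9.49e-58, "direct", 46, 59, 6, 5, 9.48),
    ("r07", 91.176, 136, 11, 1, (MC1, 175216, 175351), (MC1, 209605, 209471), 5.80e-45, "inverted", 30, 37, 3, 2, 6.94),
    ("r08", 98.649, 74, 1, 0, (MC1, 300772, 300845), (MC1, 19641, 19714), 2.13e-29, "direct", 33, 29, 11, 3, 18.42),
    ("r09", 98.305, 59, 0, 1, (MC1, 311788, 311846), (MC1, 252783, 252840), 1.67e-20, "direct", 41, 48, 9, 3, 11.88),
    ("r10", 99.966, 5835, 1, 1, (MC1, 269937, 275770), (MC1, 42128, 36294), 0.0, "inverted", 15, 10, 15, 12, 51.92),
    # r11 is inter-molecular; the deposited table tags the wrong copy with
    # MC2 (326,567 exceeds MC2's 85,199 bp) - stored here coherently
    ("r11", 94.828, 116, 5, 1, (MC2, 27842, 27957), (MC1, 326567, 326681), 1.54e-44, "direct", 61, 65, 0, 1, 0.79),
]

#: Repeats whose minor conformations were independently validated by PCR.
VALIDATED_ACTIVE = (
    "r01", "r02", "r03", "r04", "r05", "r06", "r07", "r08", "r09",
)


def reference_repeats() -> list[RepeatPair]:
    """The eleven candidate repeat pairs as :class:`RepeatPair` objects."""
    out = []
    for rid, ident, length, mm, go, c1, c2, ev, orient, *_ in _ROWS:
        out.append(
            RepeatPair(
                id=rid,
                copy1=Locus.from_hsp_coords(*c1),
                copy2=Locus.from_hsp_coords(*c2),
                orientation=orient,
                identity=ident,
                aln_length=length,
                mismatches=mm,
                gap_opens=go,
                evalue=ev,
            )
        )
    return out


def reference_counts() -> dict[str, SupportCounts]:
    """Published spanning-read counts per repeat."""
    return {
        row[0]: SupportCounts(
            repeat_id=row[0], mac1=row[9], mac2=row[10], mic1=row[11], mic2=row[12]
        )
        for row in _ROWS
    }


def reference_frequencies() -> dict[str, float]:
    """Published recombination frequencies (percent) per repeat."""
    return {row[0]: row[13] for row in _ROWS}


def reference_records() -> list[RecombRecord]:
    """Repeat + counts bundles ready for frequency/activity analysis."""
    counts = reference_counts()
    return [
        RecombRecord(repeat=rep, counts=counts[rep.id])
        for rep in reference_repeats()
    ]
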