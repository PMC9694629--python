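"""Detection of plastid-derived insertions (MTPTs) in a mitogenome.

Plant mitogenomes routinely carry fragments of the co-resident plastome.
Candidates are found by homology search of the plastome against the
mitogenome (same seed-and-extend engine as repeat discovery), filtered
reciprocally - a hit is kept only when its mitochondrial and plastid
intervals are each other's best-scoring partners - and hits shorter than
``min_length`` (default 100 bp) are ignored.  Overlapping mitochondrial-side
hits that extend the same plastid region colinearly are merged (10 bp
tolerance by default; fragment counts are sensitive to this, so it is a
parameter).

Each accepted fragment can then be annotated with the plastome genes it
carries: genes fully contained in the plastid interval are listed as full
copies, genes only partially overlapped are flagged partial, and the genes
of one fragment form a cluster of contiguous plastome genes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .alignment import RawHit, homology_search
from .sequence import Genome, InputError, Locus, write_bed

__all__ = [
    "MTPTRecord",
    "GeneFeature",
    "GeneCluster",
    "find_mtpt",
    "summarize_mtpt",
    "group_gene_clusters",
    "read_annotation",
    "write_mtpt_table",
]


@dataclasses.dataclass(frozen=True)
class MTPTRecord:
    """One plastid-derived fragment in the mitogenome."""

    id: str
    mito_locus: Locus
    plastid_locus: Locus
    identity: float
    aln_length: int
    genes: tuple[tuple[str, bool], ...] = ()  # (gene name, is_full_copy)


@dataclasses.dataclass(frozen=True)
class GeneFeature:
    name: str
    chrom_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str


@dataclasses.dataclass(frozen=True)
class GeneCluster:
    mtpt_id: str
    genes: tuple[tuple[str, bool], ...]  # ordered along the plastome


def _interval(locus: Locus) -> tuple[int, int]:
    return (locus.start, locus.end) if locus.start <= locus.end else (locus.end, locus.start)


def _overlap(a: Locus, b: Locus) -> bool:
    if a.chrom_id != b.chrom_id:
        return False
    (s1, e1), (s2, e2) = _interval(a), _interval(b)
    return s1 <= e2 and s2 <= e1


def _reciprocal_best(hits: list[RawHit]) -> list[RawHit]:
    """Keep a hit iff no higher-scoring hit overlaps it on either side."""
    kept = []
    for h in hits:
        h_m = Locus(h.s_id, *sorted((h.s_start, h.s_end)), "+")
        h_p = Locus(h.q_id, *sorted((h.q_start, h.q_end)), "+")
        best = True
        for g in hits:
            if g is h or g.score <= h.score:
                continue
            g_m = Locus(g.s_id, *sorted((g.s_start, g.s_end)), "+")
            g_p = Locus(g.q_id, *sorted((g.q_start, g.q_end)), "+")
            if _overlap(h_m, g_m) or _overlap(h_p, g_p):
                best = False
                break
        if best:
            kept.append(h)
    return kept


def _mergeable(a: RawHit, b: RawHit, tol: int) -> bool:
    if a.s_id != b.s_id or a.q_id != b.q_id or a.s_strand != b.s_strand:
        return False
    am = sorted((a.s_start, a.s_end))
    bm = sorted((b.s_start, b.s_end))
    ap = sorted((a.q_start, a.q_end))
    bp = sorted((b.q_start, b.q_end))
    mito_close = am[0] - tol <= bm[1] and bm[0] - tol <= am[1]
    plast_close = ap[0] - tol <= bp[1] and bp[0] - tol <= ap[1]
    return mito_close and plast_close


def find_mtpt(
    mitogenome: Genome,
    plastome: Genome,
    evalue_cutoff: float = 1e-6,
    word_size: int = 7,
    min_length: int = 100,
    merge_tolerance: int = 10,
    id_prefix: str = "mtpt",
) -> list[MTPTRecord]:
    """Plastid-derived fragments in the mitogenome, reciprocally filtered."""
    hits = homology_search(
        plastome,
        mitogenome,
        word_size=word_size,
        evalue_cutoff=evalue_cutoff,
        min_length=min_length,
    )
    hits = _reciprocal_best(hits)

    # merge colinear mito-side fragments
    merged: list[list[RawHit]] = []
    for h in sorted(hits, key=lambda x: (x.s_id, min(x.s_start, x.s_end))):
        for group in merged:
            if any(_mergeable(h, g, merge_tolerance) for g in group):
                group.append(h)
                break
        else:
            merged.append([h])

    records = []
    for group in sorted(
        merged, key=lambda g: (g[0].s_id, min(min(h.s_start, h.s_end) for h in g))
    ):
        ms = min(min(h.s_start, h.s_end) for h in group)
        me = max(max(h.s_start, h.s_end) for h in group)
        ps = min(min(h.q_start, h.q_end) for h in group)
        pe = max(max(h.q_start, h.q_end) for h in group)
        total = sum(h.aln_length for h in group)
        identity = sum(h.identity * h.aln_length for h in group) / total
        records.append(
            MTPTRecord(
                id=f"{id_prefix}-{len(records) + 1:03d}",
                mito_locus=Locus(group[0].s_id, ms, me, "+"),
                plastid_locus=Locus(group[0].q_id, ps, pe, group[0].s_strand),
                identity=round(identity, 3),
                aln_length=me - ms + 1,
            )
        )
    return records


def summarize_mtpt(
    records: Sequence[MTPTRecord], mito_len: int, plastid_len: int
) -> dict:
    """Non-redundant mitochondrial footprint and its genome fractions.

    Overlapping mito-side intervals are unioned before summing, so no base
    is counted twice.  Percentages are rounded to 2 decimals.
    """
    if mito_len <= 0 or plastid_len <= 0:
        raise InputError("genome lengths must be positive")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in records:
        by_chrom.setdefault(r.mito_locus.chrom_id, []).append(_interval(r.mito_locus))
    total = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
    return {
        "n": len(records),
        "total_bp": total,
        "pct_of_mito": round(100.0 * total / mito_len, 2),
        "pct_of_plastome": round(100.0 * total / plastid_len, 2),
    }


def read_annotation(path: str | Path, fmt: str | None = None) -> list[GeneFeature]:
    """Read gene features from a GFF3 or GenBank annotation."""
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "gff3"
    if fmt == "genbank":
        feats = []
        for rec in SeqIO.parse(str(path), "genbank"):
            for f in rec.features:
                if f.type != "gene":
                    continue
                name = (
                    f.qualifiers.get("gene", f.qualifiers.get("locus_tag", ["?"]))
                )[0]
                feats.append(
                    GeneFeature(
                        name=name,
                        chrom_id=rec.id,
                        start=int(f.location.start) + 1,
                        end=int(f.location.end),
                        strand="-" if f.location.strand == -1 else "+",
                    )
                )
        return feats
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise InputError(f"{path}:{lineno}: GFF3 rows need 9 columns")
            if cols[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("gene") or attrs.get("ID", "?")
            feats.append(
                GeneFeature(
                    name=name,
                    chrom_id=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                )
            )
    return feats


def group_gene_clusters(
    records: Sequence[MTPTRecord], annotation: Sequence[GeneFeature]
) -> list[GeneCluster]:
    """Plastome genes carried by each MTPT, in plastome order.

    Genes fully inside the plastid interval are full copies; genes partially
    overlapped are flagged partial.  Raises when the annotation names no
    chromosome present in the records.
    """
    if records:
        plastid_ids = {r.plastid_locus.chrom_id for r in records}
        ann_ids = {g.chrom_id for g in annotation}
        if annotation and not (plastid_ids & ann_ids):
            raise InputError(
                f"annotation chromosomes {sorted(ann_ids)} do not match "
                f"plastid ids {sorted(plastid_ids)}"
            )
    genes_sorted = sorted(annotation, key=lambda g: (g.chrom_id, g.start))
    clusters = []
    for r in records:
        ps, pe = _interval(r.plastid_locus)
        members = []
        for g in genes_sorted:
            if g.chrom_id != r.plastid_locus.chrom_id:
                continue
            if g.start >= ps and g.end <= pe:
                members.append((g.name, True))
            elif g.start <= pe and g.end >= ps:
                members.append((g.name, False))
        clusters.append(GeneCluster(mtpt_id=r.id, genes=tuple(members)))
    return clusters


def annotate_records(
    records: Sequence[MTPTRecord], clusters: Sequence[GeneCluster]
) -> list[MTPTRecord]:
    by_id = {c.mtpt_id: c.genes for c in clusters}
    return [
        dataclasses.replace(r, genes=by_id.get(r.id, ())) for r in records
    ]


def confirm_mtpt_flanks(
    records: Sequence[MTPTRecord],
    mitogenome: Genome,
    reads: Sequence[str | tuple[str, str]],
    flank: int = 2000,
    max_divergence: float = 0.15,
) -> dict[str, int]:
    """Count long reads spanning each MTPT plus ``flank`` bases of both
    mitochondrial flanks.

    A read that covers the insertion together with genuine mitochondrial
    context on both sides shows the fragment is integrated in the
    mitogenome rather than being plastid carry-over.  This is a
    confirmation report, never a filter: records are returned unchanged
    elsewhere.
    """
    import edlib

    from .sequence import extract_circular, reverse_complement

    out: dict[str, int] = {}
    for rec in records:
        chrom = mitogenome[rec.mito_locus.chrom_id]
        lo, hi = _interval(rec.mito_locus)
        span = hi - lo + 1
        f = min(flank, max(0, (chrom.length - span) // 2))
        s = (lo - 1 - f) % chrom.length + 1
        e = (hi - 1 + f) % chrom.length + 1
        core = extract_circular(chrom, s, e)
        k = int(max_divergence * len(core))
        n = 0
        for read in reads:
            seq = read[1] if isinstance(read, tuple) else read
            if len(seq) < len(core):
                continue
            for probe in (seq, reverse_complement(seq)):
                d = edlib.align(core, probe, mode="HW", task="distance", k=k)[
                    "editDistance"
                ]
                if d >= 0:
                    n += 1
                    break
        out[rec.id] = n
    return out


def write_mtpt_table(records: Iterable[MTPTRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "mtpt_id\tmito_chrom\tmito_start\tmito_end\tplastid_chrom\t"
            "plastid_start\tplastid_end\tstrand\tidentity\taln_length\tgenes\n"
        )
        for r in records:
            genes = ",".join(
                name + ("" if full else "(partial)") for name, full in r.genes
            )
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.id,
                        r.mito_locus.chrom_id,
                        r.mito_locus.start,
                        r.mito_locus.end,
                        r.plastid_locus.chrom_id,
                        r.plastid_locus.start,
                        r.plastid_locus.end,
                        r.plastid_locus.strand,
                        r.identity,
                        r.aln_length,
                        genes,
                    )
                )
                + "\n"
            )


def write_mtpt_bed(records: Iterable[MTPTRecord], path: str | Path) -> None:
    write_bed(
        (
            (r.mito_locus.chrom_id, r.mito_locus.start, r.mito_locus.end, r.id)
            for r in records
        ),
        path,
    )


def write_link_table(records: Iterable[MTPTRecord], path: str | Path) -> None:
    """Mito interval <-> plastid interval link table for circular plots."""
    with open(path, "w") as fh:
        fh.write("mtpt_id\tmito_chrom\tmito_start\tmito_end\tplastid_chrom\tplastid_start\tplastid_end\n")
        for r in records:
            fh.write(
                f"{r.id}\t{r.mito_locus.chrom_id}\t{r.mito_locus.start}\t"
                f"{r.mito_locus.end}\t{r.plastid_locus.chrom_id}\t"
                f"{r.plastid_locus.start}\t{r.plastid_locus.end}\n"
            )
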