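"""Seed-and-extend local homology search on circular chromosomes.

This is the in-package analogue of a nucleotide BLAST search, used both for
repeat discovery within a genome and for plastid-vs-mitogenome homology.
Exact word seeds are located with a numpy k-mer join, clustered by diagonal,
and each cluster is extended with a score-based local alignment
(match +1, mismatch -2, gap open -5, gap extend -2 by default, mimicking
default blastn behaviour).  Significance is assessed with the Karlin-Altschul
formula, E = K m n exp(-lambda S), with lambda solved numerically for the
scoring matrix under uniform base composition and K fixed at 0.46 (the
tabulated ungapped value for +1/-2 scoring).

Circularity is handled by scanning doubled sequences and normalising hit
coordinates modulo the chromosome length; a hit is never reported twice and
never longer than the circle.

Exact score parity with NCBI BLAST is not promised; for bit-exact
reproduction of an external HSP table use
:func:`mitorecomb.repeats.parse_hsp_table`.
"""

from __future__ import annotations

import dataclasses
import numpy as np
from Bio import Align
from scipy.optimize import brentq

from .sequence import Genome, reverse_complement

__all__ = ["RawHit", "ScoringScheme", "homology_search"]

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


@dataclasses.dataclass(frozen=True)
class ScoringScheme:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2

    @property
    def karlin_lambda(self) -> float:
        """Ungapped lambda for uniform base composition."""
        m, x = float(self.match), float(self.mismatch)

        def f(lam: float) -> float:
            return 0.25 * np.exp(lam * m) + 0.75 * np.exp(lam * x) - 1.0

        return float(brentq(f, 1e-6, 10.0))

    karlin_k: float = 0.46


@dataclasses.dataclass
class RawHit:
    """One local alignment (HSP) between a query and subject locus.

    Coordinates are 1-based inclusive on the plus strand of each sequence;
    ``s_strand`` is '-' when the subject matched in reverse complement.
    An interval with ``start > end`` wraps the circular origin.
    """

    q_id: str
    s_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    s_strand: str
    score: int
    identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    evalue: float


def _kmer_starts(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (positions, codes) of all valid (N-free) k-mers."""
    codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    valid = codes != 255
    vals = np.where(valid, codes, 0).astype(np.int64)
    kmers = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for i in range(k):
        kmers = kmers * 4 + vals[i : n - k + 1 + i]
        ok &= valid[i : n - k + 1 + i]
    pos = np.nonzero(ok)[0]
    return pos, kmers[pos]


def _seed_matches(qseq: str, sseq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All (qpos, spos) 0-based pairs sharing an exact k-mer."""
    qpos, qk = _kmer_starts(qseq, k)
    spos, sk = _kmer_starts(sseq, k)
    if qpos.size == 0 or spos.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(sk, kind="stable")
    sk_sorted = sk[order]
    spos_sorted = spos[order]
    lo = np.searchsorted(sk_sorted, qk, side="left")
    hi = np.searchsorted(sk_sorted, qk, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    q_out = np.repeat(qpos, counts)
    idx = np.repeat(lo, counts) + (
        np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    )
    s_out = spos_sorted[idx]
    return q_out, s_out


def _max_exact_run(qp: np.ndarray, dg: np.ndarray, k: int) -> int:
    """Longest exact match implied by overlapping/adjacent same-diagonal seeds."""
    order = np.lexsort((qp, dg))
    qs, ds = qp[order], dg[order]
    best = run_start = 0
    for i in range(1, len(qs) + 1):
        if i == len(qs) or ds[i] != ds[i - 1] or qs[i] - qs[i - 1] > 1:
            best = max(best, int(qs[i - 1] - qs[run_start]) + k)
            run_start = i
    return best


def _cluster_seeds(
    qpos: np.ndarray,
    spos: np.ndarray,
    k: int,
    band: int = 24,
    max_gap: int = 120,
    min_exact: int | None = None,
) -> list[tuple[int, int, int, int]]:
    """Group co-diagonal seeds into candidate windows.

    Returns (qlo, qhi, slo, shi) 0-based seed-start extents per cluster.
    A cluster is kept only if its seeds imply an exact match of at least
    ``min_exact`` bases (default word size + 4): any real repeat of
    reportable length contains such a stretch even at 90% identity, while
    isolated random word hits do not.  Repeats with small indels stay within
    1-2 diagonal buckets; a candidate split across buckets yields two
    overlapping windows that the post-alignment subsumption filter collapses.
    """
    if qpos.size == 0:
        return []
    if min_exact is None:
        min_exact = k + 4
    diag = qpos - spos
    bucket = diag // band
    order = np.lexsort((qpos, bucket))
    qp, sp, dg, bk = qpos[order], spos[order], diag[order], bucket[order]
    clusters = []
    start = 0
    for i in range(1, len(qp) + 1):
        if (
            i == len(qp)
            or bk[i] != bk[i - 1]
            or int(qp[i]) - int(qp[i - 1]) > max_gap
        ):
            if (
                i - start >= 2
                and _max_exact_run(qp[start:i], dg[start:i], k) >= min_exact
            ):
                clusters.append(
                    (
                        int(qp[start:i].min()),
                        int(qp[start:i].max()),
                        int(sp[start:i].min()),
                        int(sp[start:i].max()),
                    )
                )
            start = i
    return clusters


def _make_aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # Biopython charges open_gap_score on the first gap column, so a gap of
    # length g costs open + (g-1)*extend here versus BLAST's open + g*extend.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _alignment_stats(
    aln: Align.Alignment, qwin: str, swin: str
) -> tuple[int, int, int, int, int, int, int, int]:
    """(qs, qe, ss, se, matches, mismatches, gap_opens, columns), 0-based half-open."""
    qblocks, sblocks = aln.aligned
    matches = mismatches = 0
    columns = 0
    for (qa, qb), (sa, sb) in zip(qblocks, sblocks):
        columns += qb - qa
        for cq, cs in zip(qwin[qa:qb], swin[sa:sb]):
            if cq == cs and cq != "N":
                matches += 1
            else:
                mismatches += 1
    gap_opens = 0
    for i in range(1, len(qblocks)):
        qgap = qblocks[i][0] - qblocks[i - 1][1]
        sgap = sblocks[i][0] - sblocks[i - 1][1]
        if qgap:
            gap_opens += 1
            columns += qgap
        if sgap:
            gap_opens += 1
            columns += sgap
    return (
        int(qblocks[0][0]),
        int(qblocks[-1][1]),
        int(sblocks[0][0]),
        int(sblocks[-1][1]),
        matches,
        mismatches,
        gap_opens,
        columns,
    )


def _norm_interval(start0: int, end0: int, length: int, circular: bool) -> tuple[int, int]:
    """0-based half-open on a doubled sequence -> 1-based inclusive mod length."""
    if circular:
        while start0 >= length:
            start0 -= length
            end0 -= length
    s1, e1 = start0 + 1, end0
    if circular and e1 > length:
        e1 -= length  # wraps the origin: start > end encodes the wrap
    return s1, e1


def homology_search(
    query: Genome,
    subject: Genome | None = None,
    word_size: int = 7,
    evalue_cutoff: float = 1e-6,
    min_length: int = 50,
    scoring: ScoringScheme | None = None,
    margin: int = 120,
) -> list[RawHit]:
    """Find local alignments between two genomes (or a genome and itself).

    With ``subject=None`` the search is the genome against itself: trivial
    self-hits (a locus aligned to itself, plus strand) are removed and
    mirror duplicates (A-B vs B-A) are collapsed with the positionally
    smaller locus as the query side.
    """
    scoring = scoring or ScoringScheme()
    aligner = _make_aligner(scoring)
    lam = scoring.karlin_lambda
    self_search = subject is None
    subj = query if self_search else subject
    m_len = query.total_length
    n_len = subj.total_length

    hits: list[RawHit] = []
    seen: set[tuple] = set()

    q_chroms = list(query)
    s_chroms = list(subj)
    for qi, qc in enumerate(q_chroms):
        for si, sc in enumerate(s_chroms):
            if self_search and si < qi:
                continue  # mirror chromosome pairs
            qseq2 = qc.residues * 2 if qc.circular else qc.residues
            for strand in "+-":
                s_plus = sc.residues * 2 if sc.circular else sc.residues
                sseq2 = s_plus if strand == "+" else reverse_complement(s_plus)
                qpos, spos = _seed_matches(qseq2, sseq2, word_size)
                if self_search and qc.id == sc.id and strand == "+":
                    # drop the identity diagonal (and its mod-L images)
                    diag = qpos - spos
                    keep = (diag % qc.length) != 0
                    # mirror within one chromosome: keep q before s only
                    keep &= qpos < spos
                    qpos, spos = qpos[keep], spos[keep]
                for qlo, qhi, slo, shi in _cluster_seeds(qpos, spos, word_size):
                    qa = max(0, qlo - margin)
                    qb = min(len(qseq2), qhi + word_size + margin)
                    sa = max(0, slo - margin)
                    sb = min(len(sseq2), shi + word_size + margin)
                    qwin, swin = qseq2[qa:qb], sseq2[sa:sb]
                    try:
                        aln = next(iter(aligner.align(qwin, swin)))
                    except StopIteration:  # pragma: no cover
                        continue
                    (
                        aqs,
                        aqe,
                        ass_,
                        ase,
                        nmatch,
                        nmm,
                        ngap,
                        columns,
                    ) = _alignment_stats(aln, qwin, swin)
                    if columns < min_length or columns > max(qc.length, sc.length):
                        continue
                    score = int(aln.score)
                    evalue = scoring.karlin_k * m_len * n_len * np.exp(-lam * score)
                    if evalue > evalue_cutoff:
                        continue
                    q0, q1 = qa + aqs, qa + aqe
                    s0, s1 = sa + ass_, sa + ase
                    if strand == "-":
                        s0, s1 = len(sseq2) - s1, len(sseq2) - s0
                    if q1 - q0 > qc.length or s1 - s0 > sc.length:
                        continue  # alignment longer than the circle itself
                    q_s, q_e = _norm_interval(q0, q1, qc.length, qc.circular)
                    s_s, s_e = _norm_interval(s0, s1, sc.length, sc.circular)
                    identity = 100.0 * nmatch / columns
                    hit = RawHit(
                        qc.id,
                        sc.id,
                        q_s,
                        q_e,
                        s_s,
                        s_e,
                        strand,
                        score,
                        identity,
                        columns,
                        nmm,
                        ngap,
                        float(evalue),
                    )
                    if self_search:
                        hit = _canonical_self(hit)
                        if hit is None:
                            continue
                    key = (
                        hit.q_id,
                        hit.s_id,
                        hit.q_start,
                        hit.q_end,
                        hit.s_start,
                        hit.s_end,
                        hit.s_strand,
                    )
                    if key in seen:
                        continue
                    seen.add(key)
                    hits.append(hit)
    return _drop_subsumed(hits)


def _canonical_self(hit: RawHit) -> RawHit | None:
    """Orient a self-search hit with the smaller locus first; drop self-identity."""
    a = (hit.q_id, hit.q_start, hit.q_end)
    b = (hit.s_id, hit.s_start, hit.s_end)
    if a == b and hit.s_strand == "+":
        return None
    if b < a:
        return dataclasses.replace(
            hit,
            q_id=hit.s_id,
            s_id=hit.q_id,
            q_start=hit.s_start,
            q_end=hit.s_end,
            s_start=hit.q_start,
            s_end=hit.q_end,
        )
    return hit


def _span_key(start: int, end: int) -> tuple[int, int]:
    # wrap-agnostic containment test key: sort handles the common linear case
    return (start, end) if start <= end else (end, start)


def _contains(outer: tuple[int, int], inner: tuple[int, int], slack: int = 0) -> bool:
    return outer[0] - slack <= inner[0] and inner[1] <= outer[1] + slack


def _drop_subsumed(hits: list[RawHit]) -> list[RawHit]:
    """Remove HSPs fully contained (both sides) in a longer HSP."""
    hits = sorted(hits, key=lambda h: -h.aln_length)
    kept: list[RawHit] = []
    for h in hits:
        hq, hs = _span_key(h.q_start, h.q_end), _span_key(h.s_start, h.s_end)
        subsumed = False
        for g in kept:
            if (
                g.q_id == h.q_id
                and g.s_id == h.s_id
                and g.s_strand == h.s_strand
                and _contains(_span_key(g.q_start, g.q_end), hq)
                and _contains(_span_key(g.s_start, g.s_end), hs)
            ):
                subsumed = True
                break
        if not subsumed:
            kept.append(h)
    kept.sort(key=lambda h: (h.q_id, h.q_start, h.s_id, h.s_start))
    return kept
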