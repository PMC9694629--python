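"""Independent oracles used to cross-check the implementation.

Each oracle is deliberately naive and shares no code with the library
path it checks: an O(nm) infix edit-distance DP (vs the edlib-based
classifier), a quadratic SSR enumerator (vs the run-length scanner), and
explicit cut-and-join string surgery (vs the segment-level topology
algebra).
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from numba import njit

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------- classify


@njit(cache=False)
def _infix_edit_distance(core: np.ndarray, read: np.ndarray) -> int:
    """min edit distance of `core` against any infix of `read` (full DP)."""
    m, n = len(core), len(read)
    prev = np.empty(n + 1, dtype=np.int32)
    cur = np.empty(n + 1, dtype=np.int32)
    for j in range(n + 1):
        prev[j] = 0
    for i in range(1, m + 1):
        cur[0] = i
        ci = core[i - 1]
        for j in range(1, n + 1):
            cost = 0 if ci == read[j - 1] else 1
            a = prev[j - 1] + cost
            b = prev[j] + 1
            c = cur[j - 1] + 1
            best = a if a < b else b
            if c < best:
                best = c
            cur[j] = best
        prev, cur = cur, prev
    best = prev[0]
    for j in range(1, n + 1):
        if prev[j] < best:
            best = prev[j]
    return int(best)


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8).astype(np.int32)


def oracle_classify(
    read: str, junctions, min_anchor: int = 100, max_divergence: float = 0.15
) -> str:
    """Exhaustive edit-distance classification against all four references,
    both strands, with the same decision contract as the library."""
    strands = (_encode(read), _encode(rc(read)))
    best_label, best_div, tie = None, None, False
    for label in ("C1", "C2", "C3", "C4"):
        core = junctions.core(label, min_anchor)
        if not core:
            continue
        enc = _encode(core)
        dist = min(_infix_edit_distance(enc, s) for s in strands)
        div = Fraction(dist, len(core))
        if div > Fraction(max_divergence).limit_denominator(10**6):
            continue
        if best_div is None or div < best_div:
            best_label, best_div, tie = label, div, False
        elif div == best_div:
            tie = True
    if best_label is None:
        return "unspanning"
    return "ambiguous" if tie else best_label


# --------------------------------------------------------------------- SSR


def _primitive(unit: str) -> bool:
    n = len(unit)
    return not any(
        n % d == 0 and unit[:d] * (n // d) == unit for d in range(1, n)
    )


def oracle_ssrs(seq: str, min_copies: dict[int, int]) -> list[tuple]:
    """Enumerate every start x unit length, extend perfect copies, then apply
    the documented resolution (longer run wins, ties to smaller unit)."""
    cands = []
    n = len(seq)
    for u in range(1, 7):
        for i in range(n - u + 1):
            unit = seq[i : i + u]
            if "N" in unit or not _primitive(unit):
                continue
            if i >= u and seq[i - u : i] == unit:
                continue  # not maximal: same run starts earlier
            c = 1
            while seq[i + c * u : i + (c + 1) * u] == unit:
                c += 1
            if c >= min_copies[u]:
                cands.append((i, u, c))
    cands.sort(key=lambda t: (-(t[1] * t[2]), t[1], t[0]))
    taken: list[tuple[int, int]] = []
    out = []
    for i, u, c in cands:
        e = i + u * c
        if any(i < te and ts < e for ts, te in taken):
            continue
        taken.append((i, e))
        motif = min(unit := seq[i : i + u], *(unit[j:] + unit[:j] for j in range(u)))
        out.append((motif, u, c, i + 1, e))
    out.sort(key=lambda t: t[3])
    return out


# ----------------------------------------------------------- string surgery


def surgery_split_direct(seq: str, c1: tuple[int, int], c2: tuple[int, int]):
    """Crossover between two direct copies on one circle (1-based inclusive
    loci, copy1 before copy2): returns the two product circles."""
    (s1, e1), (s2, e2) = c1, c2
    a = seq[e1 : s2 - 1]  # between copy1 and copy2
    b = seq[e2:] + seq[: s1 - 1]  # wrap-around remainder
    r1 = seq[s1 - 1 : e1]
    r2 = seq[s2 - 1 : e2]
    return r1 + a, r2 + b


def surgery_invert_intra(seq: str, c1: tuple[int, int], c2: tuple[int, int]) -> str:
    """Crossover between a plus-strand copy and its inverted mate: the
    segment between them is reverse-complemented."""
    (s1, e1), (s2, e2) = c1, c2
    return seq[: e1] + rc(seq[e1 : s2 - 1]) + seq[s2 - 1 :]


def surgery_fuse_direct(
    seq1: str, c1: tuple[int, int], seq2: str, c2: tuple[int, int]
) -> str:
    """Crossover between copies on two circles: one fused circle."""
    (s1, e1), (s2, e2) = c1, c2
    rot1 = seq1[s1 - 1 :] + seq1[: s1 - 1]  # starts with copy1
    rot2 = seq2[s2 - 1 :] + seq2[: s2 - 1]
    return rot1 + rot2


def circles_equal(a: str, b: str) -> bool:
    """Equality of circular sequences up to rotation and strand."""
    return len(a) == len(b) and (a in b + b or rc(a) in b + b)
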