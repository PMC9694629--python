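"""Synthetic genomes, conformation mixtures, and noisy long reads.

Every stage of the pipeline is testable without downloads: this module
generates circular chromosomes with planted direct/inverted,
intra-/inter-molecular repeat pairs and plastid-derived insertions, then
draws long reads from a Mac/Mic conformation mixture at a stated minor
fraction, with a lognormal read-length model and a PacBio-like error mix.

The generator is fully deterministic: one master seed derives all
per-stage generators by fixed offsets, and identical configurations yield
byte-identical FASTA/FASTQ output.

Defaults emulate an RSII-era long-read library over a plant mitogenome:
background GC 44.5%, read lengths lognormal with median 9 kb (truncated to
1-40 kb), per-base error 10% mixed sub:ins:del = 1:5:4.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.stats import beta as _beta

from .repeats import DIRECT, INVERTED, RepeatPair
from .sequence import CircularChromosome, Genome, InputError, Locus, reverse_complement
from .support import RecombRecord, SupportCounts
from .topology import genome_to_molecules, realize_sequence, recombine

__all__ = [
    "ReadModel",
    "PlantedRepeat",
    "SimulationConfig",
    "SimulationTruth",
    "ReadProvenance",
    "simulate_genome",
    "simulate_reads",
    "simulate_junction_reads",
    "evaluate_recovery",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

# fixed per-stage offsets from the master seed
_OFF_BACKGROUND = 0
_OFF_PLACEMENT = 1
_OFF_MUTATION = 2
_OFF_PLASTOME = 3
_OFF_READS = 4


@dataclasses.dataclass(frozen=True)
class ReadModel:
    """Long-read count, length distribution, and error model."""

    count: int = 500
    length_log_mean: float = math.log(9000.0)  # lognormal median 9 kb
    length_log_sd: float = 0.5
    min_length: int = 1000
    max_length: int = 40000
    error_rate: float = 0.10
    error_mix: tuple[float, float, float] = (0.1, 0.5, 0.4)  # sub, ins, del

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise InputError("error_rate must be in [0, 1)")
        if abs(sum(self.error_mix) - 1.0) > 1e-9:
            raise InputError("error_mix must sum to 1")


@dataclasses.dataclass(frozen=True)
class PlantedRepeat:
    """Specification of one repeat pair to plant."""

    length: int
    identity: float = 100.0
    orientation: str = DIRECT
    chrom1: int = 0  # chromosome indices; differ => inter-molecular
    chrom2: int = 0
    minor_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.orientation not in (DIRECT, INVERTED):
            raise InputError(f"bad orientation {self.orientation!r}")
        if not 0 <= self.minor_fraction <= 1:
            raise InputError("minor_fraction must be in [0, 1]")
        if not 60 <= self.length <= 6000:
            raise InputError("planted repeat length must be 60-6000 bp")
        if not 90 <= self.identity <= 100:
            raise InputError("planted repeat identity must be 90-100%")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (50_000,)
    gc: float = 0.445
    repeats: tuple[PlantedRepeat, ...] = ()
    mtpt_lengths: tuple[int, ...] = ()
    plastome_length: int = 30_000
    read_model: ReadModel = dataclasses.field(default_factory=ReadModel)


@dataclasses.dataclass(frozen=True)
class ReadProvenance:
    name: str
    molecule_id: str
    conformation: str  # C1..C4 for junction reads, "" for whole-molecule reads
    start: int  # 1-based on the source molecule
    strand: str
    length: int


@dataclasses.dataclass
class SimulationTruth:
    genome: Genome
    repeats: list[RepeatPair]
    minor_fractions: dict[str, float]
    plastome: Genome | None = None
    mtpts: list[tuple[Locus, Locus]] = dataclasses.field(default_factory=list)
    reads: list[ReadProvenance] = dataclasses.field(default_factory=list)
    expected_counts: dict[str, SupportCounts] = dataclasses.field(default_factory=dict)


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([seed, offset])


def _random_codes(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _place(
    occupied: dict[int, list[tuple[int, int]]],
    chrom_idx: int,
    length: int,
    chrom_len: int,
    rng: np.random.Generator,
    margin: int = 600,
    retries: int = 1000,
    lo: int | None = None,
    hi: int | None = None,
) -> int:
    """A 0-based start keeping >= margin bp clear of other planted features
    and of the origin (planted features never wrap); optionally confined to
    the window [lo, hi]."""
    lo = margin if lo is None else max(lo, margin)
    hi = chrom_len - length - margin if hi is None else min(hi, chrom_len - length - margin)
    if hi <= lo:
        raise InputError(
            f"no room for a {length} bp feature on chromosome {chrom_idx}"
        )
    for _ in range(retries):
        start = int(rng.integers(lo, hi))
        if all(
            start - margin >= e or start + length + margin <= s
            for s, e in occupied[chrom_idx]
        ):
            occupied[chrom_idx].append((start, start + length))
            return start
    raise InputError(
        f"could not place a {length} bp feature on chromosome {chrom_idx} "
        f"after {retries} tries; genome too small or too crowded"
    )


def simulate_genome(config: SimulationConfig) -> tuple[Genome, SimulationTruth]:
    """Random circular chromosomes with planted repeats and MTPTs.

    Repeats are planted by copy-paste with per-base substitution to hit the
    target identity (reverse-complemented when inverted); MTPTs are copied
    verbatim from a companion simulated plastome.
    """
    largest = max(
        [r.length for r in config.repeats] + list(config.mtpt_lengths) + [1]
    )
    if min(config.chromosome_lengths) < 10 * largest:
        raise InputError(
            "chromosome lengths must be >= 10x the largest planted feature"
        )
    bg = _rng(config.seed, _OFF_BACKGROUND)
    chroms = [
        _random_codes(n, config.gc, bg) for n in config.chromosome_lengths
    ]
    placer = _rng(config.seed, _OFF_PLACEMENT)
    mut = _rng(config.seed, _OFF_MUTATION)
    occupied: dict[int, list[tuple[int, int]]] = {
        i: [] for i in range(len(chroms))
    }

    truth_repeats: list[RepeatPair] = []
    minor: dict[str, float] = {}
    for idx, spec_rep in enumerate(config.repeats, start=1):
        L = spec_rep.length
        L1 = len(chroms[spec_rep.chrom1])
        L2 = len(chroms[spec_rep.chrom2])
        if spec_rep.chrom1 == spec_rep.chrom2:
            # the two copies of an intra-molecular repeat go to opposite
            # quadrants of the circle, as in real mitogenomes where active
            # repeat copies lie tens of kilobases apart: a read then spans
            # one junction at a time, keeping classification well-posed
            w = L1 // 32
            s1 = _place(
                occupied, spec_rep.chrom1, L, L1, placer,
                margin=300, lo=L1 // 4 - w, hi=L1 // 4 + w,
            )
            s2 = _place(
                occupied, spec_rep.chrom2, L, L2, placer,
                margin=300, lo=3 * L1 // 4 - w, hi=3 * L1 // 4 + w,
            )
        else:
            s1 = _place(occupied, spec_rep.chrom1, L, L1, placer)
            s2 = _place(occupied, spec_rep.chrom2, L, L2, placer)
        copy = chroms[spec_rep.chrom1][s1 : s1 + L].copy()
        n_mut = round((1 - spec_rep.identity / 100.0) * L)
        if n_mut:
            pos = placer.choice(L, size=n_mut, replace=False)
            copy[pos] = (copy[pos] + mut.integers(1, 4, size=n_mut)) % 4
        if spec_rep.orientation == INVERTED:
            copy = (3 - copy)[::-1]  # reverse complement in 2-bit coding
        chroms[spec_rep.chrom2][s2 : s2 + L] = copy
        rid = f"r{idx:02d}"
        c1 = Locus(f"chr{spec_rep.chrom1 + 1}", s1 + 1, s1 + L, "+")
        c2 = Locus(
            f"chr{spec_rep.chrom2 + 1}",
            s2 + 1,
            s2 + L,
            "-" if spec_rep.orientation == INVERTED else "+",
        )
        truth_repeats.append(
            RepeatPair(
                id=rid,
                copy1=c1,
                copy2=c2,
                orientation=spec_rep.orientation,
                identity=round(100.0 * (L - n_mut) / L, 3),
                aln_length=L,
                mismatches=n_mut,
                gap_opens=0,
                evalue=0.0,
            )
        )
        minor[rid] = spec_rep.minor_fraction

    plastome = None
    mtpts: list[tuple[Locus, Locus]] = []
    if config.mtpt_lengths:
        prng = _rng(config.seed, _OFF_PLASTOME)
        pt = _random_codes(config.plastome_length, 0.37, prng)
        p_occ: dict[int, list[tuple[int, int]]] = {0: []}
        for k, L in enumerate(config.mtpt_lengths, start=1):
            ps = _place(p_occ, 0, L, len(pt), prng, margin=200)
            ms = _place(occupied, 0, L, len(chroms[0]), placer, margin=200)
            chroms[0][ms : ms + L] = pt[ps : ps + L]
            mtpts.append(
                (
                    Locus("chr1", ms + 1, ms + L, "+"),
                    Locus("plastome", ps + 1, ps + L, "+"),
                )
            )
        plastome = Genome((CircularChromosome("plastome", _decode(pt)),))

    genome = Genome(
        tuple(
            CircularChromosome(f"chr{i + 1}", _decode(c))
            for i, c in enumerate(chroms)
        )
    )
    return genome, SimulationTruth(
        genome=genome,
        repeats=truth_repeats,
        minor_fractions=minor,
        plastome=plastome,
        mtpts=mtpts,
    )


def inject_errors(
    seq: str, rate: float, mix: tuple[float, float, float], rng: np.random.Generator
) -> str:
    """Per-base substitution/insertion/deletion noise (vectorised)."""
    if rate == 0 or not seq:
        return seq
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes)
    p_sub, p_ins, p_del = (rate * m for m in mix)
    r = rng.random(n)
    is_sub = r < p_sub
    is_ins = (r >= p_sub) & (r < p_sub + p_ins)
    is_del = (r >= p_sub + p_ins) & (r < p_sub + p_ins + p_del)
    out_codes = codes.copy()
    if is_sub.any():
        out_codes[is_sub] = (
            codes[is_sub] + rng.integers(1, 4, size=int(is_sub.sum()))
        ) % 4
    counts = np.ones(n, dtype=np.int64)
    counts[is_del] = 0
    counts[is_ins] = 2
    out = np.repeat(out_codes, counts)
    if is_ins.any():
        ins_pos = np.cumsum(counts)[is_ins] - 1  # the duplicated slot
        out[ins_pos] = rng.integers(0, 4, size=len(ins_pos))
    return _decode(out)


def _draw_length(model: ReadModel, rng: np.random.Generator) -> int:
    for _ in range(100):
        val = int(round(rng.lognormal(model.length_log_mean, model.length_log_sd)))
        if model.min_length <= val <= model.max_length:
            return val
    return int(np.clip(val, model.min_length, model.max_length))


def simulate_reads(
    molecules: Sequence[tuple[str, str, float]],
    model: ReadModel,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[ReadProvenance]]:
    """Draw reads from weighted circular molecules.

    ``molecules`` holds (id, sequence, weight) with weights summing to 1.
    Starts are uniform on the circle, strand random, lengths from the
    truncated lognormal model (clipped to the molecule length), errors from
    the configured mix.
    """
    weights = np.array([w for _, _, w in molecules], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-6:
        raise InputError("molecule weights must sum to 1")
    rng = _rng(seed, _OFF_READS)
    reads: list[tuple[str, str]] = []
    prov: list[ReadProvenance] = []
    for i in range(model.count):
        mi = int(rng.choice(len(molecules), p=weights))
        mol_id, seq, _ = molecules[mi]
        L = len(seq)
        length = min(_draw_length(model, rng), L)
        start = int(rng.integers(0, L))
        raw = (seq + seq)[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            raw = reverse_complement(raw)
        noisy = inject_errors(raw, model.error_rate, model.error_mix, rng)
        name = f"read{i + 1:05d}"
        reads.append((name, noisy))
        prov.append(ReadProvenance(name, mol_id, "", start + 1, strand, length))
    return reads, prov


def _marker_offset(molecule, repeat_id: str, copy_index: int) -> tuple[int, int]:
    off = 0
    for seg in molecule.segments:
        if seg.repeat_id == repeat_id and seg.copy_index == copy_index:
            return off, seg.length
        off += seg.length
    raise InputError(f"marker {repeat_id}.{copy_index} not in molecule")


def junction_sources(
    genome: Genome, repeat: RepeatPair
) -> dict[str, tuple[str, str, int, int]]:
    """Map each conformation label to (molecule id, sequence, junction
    offset, repeat length) in the realized Mac/Mic molecules.

    Splits and fusions swap the *upstream* partner of each copy, so the Mic
    junction at copy1 reads with copy2's upstream flank (reference C4) and
    vice versa (C3).  The one exception is the intra-molecular inversion,
    where reversing the intervening segment preserves each copy's upstream
    flank: there copy1 maps to C3 and copy2 to C4.  (Verified against
    error-free classification of the realized junctions.)
    """
    mac = genome_to_molecules(genome, [repeat])
    mic = recombine(mac, repeat.id)
    if repeat.orientation == INVERTED and not repeat.inter_molecular:
        mapping = {"C1": (mac, 1), "C2": (mac, 2), "C3": (mic, 1), "C4": (mic, 2)}
    else:
        mapping = {"C1": (mac, 1), "C2": (mac, 2), "C3": (mic, 2), "C4": (mic, 1)}
    out = {}
    for label, (ms, ci) in mapping.items():
        mi, _ = ms.find_marker(repeat.id, ci)
        mol = ms.molecules[mi]
        off, rlen = _marker_offset(mol, repeat.id, ci)
        out[label] = (mol.id, realize_sequence(mol, genome), off, rlen)
    return out


def simulate_junction_reads(
    genome: Genome,
    repeat: RepeatPair,
    minor_fraction: float,
    n_reads: int,
    model: ReadModel | None = None,
    seed: int = 0,
    anchor_pad: int = 150,
) -> tuple[list[tuple[str, str]], list[ReadProvenance], SupportCounts]:
    """Reads guaranteed to span the repeat junction, drawn from a Mac/Mic
    mixture at ``minor_fraction``.

    Each read covers the repeat body plus at least ``anchor_pad`` bases of
    both flanks of its source conformation.  Returns the reads, per-read
    provenance (conformation label recorded), and the expected support
    counts implied by the sampled labels.
    """
    model = model or ReadModel()
    rng = _rng(seed, _OFF_READS)
    sources = junction_sources(genome, repeat)
    p = minor_fraction
    labels = ("C1", "C2", "C3", "C4")
    probs = np.array([(1 - p) / 2, (1 - p) / 2, p / 2, p / 2])
    tally = {lab: 0 for lab in labels}
    reads: list[tuple[str, str]] = []
    prov: list[ReadProvenance] = []
    for i in range(n_reads):
        lab = labels[int(rng.choice(4, p=probs))]
        mol_id, seq, off, rlen = sources[lab]
        L = len(seq)
        need = rlen + 2 * anchor_pad
        length = max(min(_draw_length(model, rng), L), min(need, L))
        lo = off + rlen + anchor_pad - length
        hi = off - anchor_pad
        start = int(rng.integers(lo, hi + 1)) % L if hi >= lo else off % L
        raw = (seq + seq)[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            raw = reverse_complement(raw)
        noisy = inject_errors(raw, model.error_rate, model.error_mix, rng)
        name = f"span{i + 1:05d}"
        reads.append((name, noisy))
        prov.append(ReadProvenance(name, mol_id, lab, start % L + 1, strand, length))
        tally[lab] += 1
    expected = SupportCounts(
        repeat_id=repeat.id,
        mac1=tally["C1"],
        mac2=tally["C2"],
        mic1=tally["C3"],
        mic2=tally["C4"],
    )
    return reads, prov, expected


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes out of n."""
    if n == 0:
        return 0.0, 1.0
    alpha = 1 - conf
    lo = 0.0 if k == 0 else float(_beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(_beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def evaluate_recovery(
    truth: SimulationTruth, records: Sequence[RecombRecord]
) -> dict[str, dict]:
    """Compare estimated recombination frequencies to planted fractions.

    Per repeat: absolute error of the frequency estimate and whether the
    planted minor fraction lies inside the 95% Clopper-Pearson interval of
    the estimate.  Unmatched repeat ids raise.
    """
    report: dict[str, dict] = {}
    for rec in records:
        rid = rec.repeat.id
        if rid not in truth.minor_fractions:
            raise InputError(f"repeat {rid!r} not present in the simulation truth")
        p_true = truth.minor_fractions[rid]
        c = rec.counts
        n = c.assigned
        k = c.mic1 + c.mic2
        est = k / n if n else float("nan")
        lo, hi = clopper_pearson(k, n)
        report[rid] = {
            "planted_minor_fraction": p_true,
            "estimated_fraction": est,
            "abs_error": abs(est - p_true) if n else float("nan"),
            "ci_low": lo,
            "ci_high": hi,
            "covered": bool(lo <= p_true <= hi) if n else False,
            "n_assigned": n,
        }
    return report


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    """FASTQ with uniform placeholder qualities (quality is pass-through
    only; nothing downstream consumes it)."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
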