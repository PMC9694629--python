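# Methods

## The model

A genome is a set of circular chromosomes. A *repeat pair* is one local
alignment (HSP) between two loci, characterised by orientation (direct:
both copies on the same strand; inverted: the second copy reverse
complemented), identity, length, and whether the copies lie on one
chromosome or two. Homologous recombination between the two copies is
modelled as a single reciprocal exchange with the repeat body treated as an
atomic block. The outcome depends only on the copies' relative reading
direction and their molecular location:

| configuration | product |
|---|---|
| one circle, direct | two circles, one copy each |
| one circle, inverted | one circle, intervening segment reverse-complemented |
| two circles (frame fixed so copies read alike) | one fused circle |

Total length and the multiset of repeat copies are conserved; applying the
same exchange twice is an involution up to rotation and strand choice.
These invariants are enforced by assertions and property tests, and the
segment-level algebra is cross-checked character by character against
explicit cut-and-join string surgery on small circles.

## Junction references and read classification

For each repeat, four references are built: C1 = U1·R1·D1 and
C2 = U2·R2·D2 (the assembled arrangements at copy 1 and copy 2) and the
flank-switched C3 = U1·R1·D2, C4 = U2·R2·D1. For an inverted repeat,
copy 2's context is first rewritten in the reverse-complement frame so
both copies read the repeat on the same strand; all four references are
reported on copy 1's plus-strand frame. Flanks wrap the circular origin.
Where the two copies differ (identity < 100), the recombinant references
carry the repeat body of the copy contributing the upstream flank (R1 in
C3, R2 in C4); the choice is arbitrary but makes classification
insensitive to the repeat interior, which is what the flank anchors are
for.

A read supports a reference when the reference's *core*
(repeat body ± `min_anchor` flank bases) occurs as an infix of the read —
on either strand — within edit divergence `max_divergence`. Divergence is
compared exactly (as rationals); an exact tie between two references, or
no qualifying reference, yields `ambiguous` or `unspanning` respectively.
Ambiguous reads are excluded from the frequency denominator: they carry no
information that discriminates arrangements. One consequence worth knowing:
a read long enough to span *both* copies of an intra-molecular repeat
matches C1 and C2 equally and is scored ambiguous. This is correct
behaviour (such a read genuinely supports both Mac junctions at once), and
it is why the classifier is a per-junction instrument, not a per-molecule
one.

### Parameters

| parameter | default | rationale |
|---|---|---|
| `flank` | 500 bp | junction context written into each reference |
| `min_anchor` | 100 bp | flank coverage required on *both* sides; large enough that a chance match is implausible, small enough that ordinary long reads qualify |
| `max_divergence` | 0.15 | tolerant of RSII-era ~10–15% read error over the core |
| activity call | Mic1 ≥ 1, Mic2 ≥ 1, Mic1+Mic2 ≥ 2, span ≤ 5,000 bp | both minor junctions must be seen; very long repeats are rarely spanned and their products resist independent validation |

The frequency is reported as a percentage rounded half-up to two decimals.

## Repeat discovery

`find_repeats` is a self-contained seed-and-extend scorer: exact word seeds
(default length 7) located by a numpy k-mer join, clustered by diagonal
(band 24, gap 120), with clusters kept only when their seeds imply an exact
stretch of at least word+4 bases — any reportable repeat contains one even
at 90% identity, while isolated random word hits do not. Each candidate
window is extended by a local alignment at match +1, mismatch −2, gap open
−5, gap extend −2 (blastn-like), and significance is assessed with the
Karlin–Altschul formula E = K·m·n·e^(−λS), λ solved numerically for the
scoring matrix under uniform composition and K fixed at 0.46 (the
tabulated ungapped value for +1/−2). Circularity is handled by scanning
doubled sequences and normalising coordinates modulo the chromosome
length; self-hits, mirror duplicates and HSPs subsumed by a longer HSP are
removed. Exact parity with NCBI BLASTN is *not* promised — reported loci
may extend a few chance-matching bases beyond a planted repeat, exactly as
BLASTN's own local optimum does — and an external outfmt-6 table can be
substituted via `parse_hsp_table` at the same module surface.

MTPT detection reuses this engine (plastome as query), ignores hits
<100 bp, keeps a hit only when no higher-scoring hit overlaps it on either
genome (the reciprocal-best reading), and merges colinear mitochondrial
fragments within a 10 bp tolerance — fragment *counts* are sensitive to
that tolerance, so it is a parameter. Footprint percentages are computed
on the unioned mitochondrial intervals, never double-counting a base.

## SSR scanning

Maximal perfect tandem runs of 1–6 bp primitive units, with MISA's copy
thresholds (10/5/4/3/3/3). Non-primitive units are reported once at the
shortest period; overlapping candidates resolve to the longer run, ties to
the smaller unit; the motif is the lexicographically smallest rotation on
the reported strand (no strand collapsing, as in MISA). Two deliberate
departures from MISA: interrupted (compound) SSRs are not merged into
single records — `group_compound` provides the grouping separately — and
chromosomes are scanned in their deposited linear frame, so a run split by
the circular origin appears as its two arcs.

## The synthetic-data generator

`simulate_genome` draws i.i.d. background bases at a configurable GC
(default 44.5%, matching the organellar genomes this tool targets), then
plants features by copy-paste: repeat pairs (60–6,000 bp, 90–100%
identity, mutated by substitution to hit the target identity,
reverse-complemented when inverted) and plastome transfers copied verbatim
from a companion simulated plastome. Copies of an intra-molecular repeat
are placed in opposite quadrants of the circle, mirroring real
recombination-active repeats whose copies lie tens of kilobases apart;
this also keeps junction classification well-posed for full-length reads
(see above). Features never overlap and never wrap the origin.

`simulate_reads` draws reads from weighted circular molecules: uniform
start, random strand, lengths lognormal with median 9 kb and σ = 0.5
log-units truncated to [1, 40] kb (a desk-scale stand-in for a 12–50 kb
size-selected long-read library), and per-base errors at a configurable
rate (default 10%) mixed sub:ins:del = 1:5:4. `simulate_junction_reads`
additionally conditions read placement on covering a chosen junction, with
the conformation drawn as Mac (1−p, split evenly between C1/C2) or Mic
(p, split between C3/C4); the Mic sequences are realized through the
topology module itself (recombine + realize_sequence), not assembled ad
hoc. One master seed derives every per-stage generator through fixed
offsets; identical configurations give byte-identical outputs.

What the generator does **not** emulate: chimeric and adapter artefacts,
quality-score structure, coverage biases, heteroplasmy beyond a two-state
Mac/Mic mixture, and nuclear copies of organellar DNA. Passing tests on
synthetic data therefore demonstrate the correctness of the algorithms
under the stated read model, not robustness to every artefact of a real
sequencing run.

## Statistical evaluation

`evaluate_recovery` compares the estimated minor fraction k/n (k = minor
spanning reads, n = assigned spanning reads) with the planted fraction,
reporting the absolute error and whether the truth lies in the exact 95%
Clopper–Pearson interval. The acceptance suite sweeps
p ∈ {0.02, 0.05, 0.10, 0.20} with 20 seeded replicates of 1,000 spanning
reads at 10% error on 50 kb genomes and requires ≥90% CI coverage per
cell; a small upward bias (a few percent, from long Mac reads that span
both junctions and drop out as ambiguous) is visible but well inside the
interval width at these sample sizes.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive in every report (BLAST convention);
  internals use 0-based half-open ranges and never expose them. Minus
  strand intervals arrive as start > end and are normalised.
* An interval stored with start > end *and* an explicit strand denotes a
  wrap through the circular origin.
* `N` is legal in sequences, never counted as a match, and excluded from
  seed words.
* A zero frequency denominator yields `None` ("NA") with a warning, never
  a division error; an empty read set gives all-zero counts.
* Divergence ties in classification are compared as exact fractions, so a
  tie is a tie regardless of float rounding.
* De-duplication of predicted conformations uses a canonical form: each
  circle rotated to its lexicographically smallest signed-segment
  signature over both strands, sets compared as multisets.

## Reference data

`mitorecomb.reference` bundles the published *S. miltiorrhiza* mitogenome
repeat table (11 HSPs with per-conformation PacBio read counts), the
chromosome and plastome lengths, and the MTPT footprint, as *inputs* for
worked examples and cross-checks. The genome-scale tallies recorded there
(72 self-search HSPs, 16 MTPTs, 112 SSRs) derive from the deposited
accessions (MN585275.1/MN585276.1 and the companion SRA read sets) and are
not recomputable from synthetic data; they are flagged accordingly. Two
internal inconsistencies of the deposited table are preserved in the
ledgered form: row r01 prints identity 100/length 127 against an 85 bp
position span, and row r11 tags the wrong copy with MC2; the bundled table
stores the printed statistics verbatim and the coherent chromosome
assignment.

## Known limitations

* The scorer is blastn-*like*, not blastn: E-values and exact HSP
  boundaries can differ from NCBI BLAST. Feed a real outfmt-6 table for
  bit-exact reproduction of an external search.
* Classification treats each repeat independently; nested or overlapping
  repeat families produce per-repeat answers that are individually
  correct but not a joint genotype.
* The topology module predicts single- and few-event products; it makes
  no claim about the stoichiometry or replication dynamics of the
  conformation mixture.
* MTPT gene clustering requires a gene-level annotation (GFF3 `gene` rows
  or GenBank `gene` features); other feature types are ignored.
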