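"""Construction of the four junction references around a repeat."""

import pytest

import mitorecomb as mr
from mitorecomb.conformations import LABELS

from _oracles import rc, surgery_invert_intra


def make_repeat(rid, c1, c2, orientation, length, chrom1="c", chrom2="c"):
    return mr.RepeatPair(
        id=rid,
        copy1=mr.Locus(chrom1, *c1, "+"),
        copy2=mr.Locus(chrom2, *c2, "-" if orientation == "inverted" else "+"),
        orientation=orientation,
        identity=100.0,
        aln_length=length,
        mismatches=0,
        gap_opens=0,
        evalue=0.0,
    )


class TestToyCircle:
    # circle U1 R D1(=U2) R D2 with 4 bp blocks: flank switching is fully
    # forced, including the D1==U2 coincidence in C4
    SEQ = "CCCC" + "AAAA" + "GGGG" + "AAAA" + "TTTT"

    def test_direct_flank_switch(self):
        genome = mr.Genome.from_sequences({"c": self.SEQ})
        rep = make_repeat("r01", (5, 8), (13, 16), "direct", 4)
        js = mr.build_conformations(genome, rep, flank=4)
        assert js.C1 == "CCCCAAAAGGGG"
        assert js.C2 == "GGGGAAAATTTT"
        assert js.C3 == "CCCCAAAATTTT"
        assert js.C4 == "GGGGAAAAGGGG"

    def test_flank_multiset_conserved(self):
        genome = mr.Genome.from_sequences({"c": self.SEQ})
        rep = make_repeat("r01", (5, 8), (13, 16), "direct", 4)
        js = mr.build_conformations(genome, rep, flank=4)
        flanks = []
        for lab in LABELS:
            seq = js.sequence(lab)
            flanks += [seq[:4], seq[-4:]]
        # each of U1, D1, U2, D2 appears exactly twice across the four refs
        assert sorted(flanks) == sorted(
            ["CCCC", "GGGG", "GGGG", "TTTT"] * 2
        )


class TestGeometry:
    def test_lengths_are_repeat_plus_two_flanks(self):
        cfg = mr.SimulationConfig(
            seed=31,
            chromosome_lengths=(20_000,),
            repeats=(mr.PlantedRepeat(length=87, orientation="direct"),),
        )
        genome, truth = mr.simulate_genome(cfg)
        js = mr.build_conformations(genome, truth.repeats[0], flank=500)
        assert all(len(js.sequence(lab)) == 87 + 2 * 500 for lab in LABELS)

    def test_flank_wraps_origin(self):
        cfg = mr.SimulationConfig(seed=32, chromosome_lengths=(5_000,))
        genome, _ = mr.simulate_genome(cfg)
        seq = genome.chromosomes[0].residues
        # place a fake repeat right at the origin so flanks must wrap
        rep = make_repeat("r01", (1, 100), (2001, 2100), "direct", 100, "chr1", "chr1")
        js = mr.build_conformations(genome, rep, flank=200)
        assert js.C1 == seq[-200:] + seq[:300]

    def test_overlapping_windows_warn(self):
        cfg = mr.SimulationConfig(seed=33, chromosome_lengths=(5_000,))
        genome, _ = mr.simulate_genome(cfg)
        rep = make_repeat("r01", (1000, 1099), (1300, 1399), "direct", 100, "chr1", "chr1")
        js = mr.build_conformations(genome, rep, flank=400)
        assert any("overlap" in w for w in js.warnings)

    def test_long_repeat_warns(self, direct_sim):
        genome, truth = direct_sim
        js = mr.build_conformations(genome, truth.repeats[0], flank=100, max_span=200)
        assert any("max_span" in w for w in js.warnings)

    def test_flank_below_one_rejected(self, direct_sim):
        genome, truth = direct_sim
        with pytest.raises(mr.InputError):
            mr.build_conformations(genome, truth.repeats[0], flank=0)


class TestInvertedFrame:
    def test_exact_inverted_c1_c2_reverse_complementary(self, inverted_sim):
        """For an exact inverted repeat, C2 re-expressed on copy2's own
        strand is the reverse complement of a window that shares the repeat
        with C1 on the same strand."""
        genome, truth = inverted_sim
        rep = truth.repeats[0]
        js = mr.build_conformations(genome, rep, flank=120)
        body1 = js.C1[120:-120]
        body2 = js.C2[120:-120]
        assert body1 == body2  # both read the repeat on copy1's frame

    def test_recombinant_matches_sequence_surgery(self, inverted_sim):
        """The Mic references equal +/-flank windows cut from an explicitly
        inverted chromosome (brute-force surgery oracle)."""
        genome, truth = inverted_sim
        rep = truth.repeats[0]
        flank = 150
        js = mr.build_conformations(genome, rep, flank=flank)
        seq = genome.chromosomes[0].residues
        first, second = sorted(
            [(rep.copy1.start, rep.copy1.end), (rep.copy2.start, rep.copy2.end)]
        )
        recombined = surgery_invert_intra(seq, first, second)
        # junctions sit at the same coordinates in the recombined circle
        w1 = recombined[first[0] - 1 - flank : first[1] + flank]
        w2 = recombined[second[0] - 1 - flank : second[1] + flank]
        windows = {w1, rc(w1), w2, rc(w2)}
        assert js.C3 in windows
        assert js.C4 in windows

    def test_junction_set_frame_symmetry(self, inverted_sim):
        """Building from copy2's frame gives the same set up to reverse
        complement (exact repeat)."""
        genome, truth = inverted_sim
        rep = truth.repeats[0]
        swapped = mr.RepeatPair(
            id=rep.id,
            copy1=mr.Locus(rep.copy2.chrom_id, rep.copy2.start, rep.copy2.end, "+"),
            copy2=mr.Locus(rep.copy1.chrom_id, rep.copy1.start, rep.copy1.end, "-"),
            orientation="inverted",
            identity=rep.identity,
            aln_length=rep.aln_length,
            mismatches=0,
            gap_opens=0,
            evalue=0.0,
        )
        a = mr.build_conformations(genome, rep, flank=100)
        b = mr.build_conformations(genome, swapped, flank=100)
        set_a = {a.sequence(lab) for lab in LABELS}
        set_b = {rc(b.sequence(lab)) for lab in LABELS}
        assert set_a == set_b
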