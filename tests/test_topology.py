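"""Rearrangement algebra: split / inversion / fusion, and sequence parity."""

import pytest

import mitorecomb as mr
from test_conformations import make_repeat

from _oracles import (
    circles_equal,
    surgery_fuse_direct,
    surgery_invert_intra,
    surgery_split_direct,
)


class TestDecomposition:
    def test_no_repeats_single_segment(self):
        g = mr.Genome.from_sequences({"c": "ACGT" * 100})
        ms = mr.genome_to_molecules(g, [])
        assert len(ms.molecules) == 1
        assert ms.molecules[0].length == 400
        assert len(ms.molecules[0].segments) == 1

    def test_segment_lengths_from_circle_arithmetic(self):
        # MC1-scale coordinates: the two 87 bp copies cut the 328,915 bp
        # circle into arcs of 183,847 and 144,894 bp
        g = mr.Genome.from_sequences({"MC1": "A" * 328_915})
        rep = make_repeat(
            "r05", (185_367, 185_453), (1_433, 1_519), "direct", 87, "MC1", "MC1"
        )
        ms = mr.genome_to_molecules(g, [rep])
        (mol,) = ms.molecules
        seg_lengths = sorted(s.length for s in mol.segments if not s.is_marker)
        assert seg_lengths == [144_894, 183_847]
        assert sum(seg_lengths) + 87 + 87 == 328_915

    def test_inter_molecular_markers(self, inter_sim):
        genome, truth = inter_sim
        ms = mr.genome_to_molecules(genome, truth.repeats)
        markers_per_mol = [
            sum(s.is_marker for s in m.segments) for m in ms.molecules
        ]
        assert markers_per_mol == [1, 1]

    def test_overlapping_copies_rejected(self):
        g = mr.Genome.from_sequences({"c": "A" * 5000})
        r1 = make_repeat("r01", (100, 400), (2000, 2300), "direct", 301)
        r2 = make_repeat("r02", (300, 600), (3000, 3300), "direct", 301)
        with pytest.raises(mr.InputError, match="overlap"):
            mr.genome_to_molecules(g, [r1, r2])


class TestRecombine:
    def test_direct_intra_splits(self, direct_sim):
        genome, truth = direct_sim
        ms = mr.genome_to_molecules(genome, truth.repeats)
        mic = mr.recombine(ms, truth.repeats[0].id)
        assert len(mic.molecules) == 2
        assert mic.total_length == ms.total_length

    def test_inverted_intra_single_circle(self, inverted_sim):
        genome, truth = inverted_sim
        ms = mr.genome_to_molecules(genome, truth.repeats)
        mic = mr.recombine(ms, truth.repeats[0].id)
        assert len(mic.molecules) == 1
        assert mic.total_length == ms.total_length

    def test_inter_molecular_fuses(self, inter_sim):
        genome, truth = inter_sim
        ms = mr.genome_to_molecules(genome, truth.repeats)
        mic = mr.recombine(ms, truth.repeats[0].id)
        assert len(mic.molecules) == 1
        assert mic.total_length == 32_000

    @pytest.mark.parametrize("fixture", ["direct_sim", "inverted_sim", "inter_sim"])
    def test_involution_and_marker_conservation(self, fixture, request):
        genome, truth = request.getfixturevalue(fixture)
        ms = mr.genome_to_molecules(genome, truth.repeats)
        rid = truth.repeats[0].id

        def marker_multiset(mset):
            return sorted(
                s.id for m in mset.molecules for s in m.segments if s.is_marker
            )

        mic = mr.recombine(ms, rid)
        assert marker_multiset(mic) == marker_multiset(ms)
        back = mr.recombine(mic, rid)
        assert back.canonical() == ms.canonical()

    def test_missing_repeat_errors(self, direct_sim):
        genome, truth = direct_sim
        ms = mr.genome_to_molecules(genome, truth.repeats)
        with pytest.raises(mr.InputError):
            mr.recombine(ms, "r99")


class TestSequenceParity:
    """realize_sequence(recombine(.)) equals explicit string surgery."""

    def test_realize_mac_is_rotation(self, direct_sim):
        genome, truth = direct_sim
        ms = mr.genome_to_molecules(genome, truth.repeats)
        s = mr.realize_sequence(ms.molecules[0], genome)
        assert circles_equal(s, genome.chromosomes[0].residues)

    def test_split_matches_surgery(self, direct_sim):
        genome, truth = direct_sim
        rep = truth.repeats[0]
        seq = genome.chromosomes[0].residues
        ms = mr.genome_to_molecules(genome, [rep])
        mic = mr.recombine(ms, rep.id)
        got = [mr.realize_sequence(m, genome) for m in mic.molecules]
        first, second = sorted(
            [(rep.copy1.start, rep.copy1.end), (rep.copy2.start, rep.copy2.end)]
        )
        want = surgery_split_direct(seq, first, second)
        assert sorted(len(s) for s in got) == sorted(len(s) for s in want)
        match = {
            frozenset(
                i for i, w in enumerate(want) if circles_equal(g, w)
            )
            for g in got
        }
        assert match == {frozenset([0]), frozenset([1])} or match == {
            frozenset([1]),
            frozenset([0]),
        }

    def test_inversion_matches_surgery(self, inverted_sim):
        genome, truth = inverted_sim
        rep = truth.repeats[0]
        seq = genome.chromosomes[0].residues
        ms = mr.genome_to_molecules(genome, [rep])
        mic = mr.recombine(ms, rep.id)
        (got,) = [mr.realize_sequence(m, genome) for m in mic.molecules]
        first, second = sorted(
            [(rep.copy1.start, rep.copy1.end), (rep.copy2.start, rep.copy2.end)]
        )
        want = surgery_invert_intra(seq, first, second)
        assert circles_equal(got, want)

    def test_fusion_matches_surgery(self, inter_sim):
        genome, truth = inter_sim
        rep = truth.repeats[0]
        ms = mr.genome_to_molecules(genome, [rep])
        mic = mr.recombine(ms, rep.id)
        (got,) = [mr.realize_sequence(m, genome) for m in mic.molecules]
        want = surgery_fuse_direct(
            genome[rep.copy1.chrom_id].residues,
            (rep.copy1.start, rep.copy1.end),
            genome[rep.copy2.chrom_id].residues,
            (rep.copy2.start, rep.copy2.end),
        )
        assert circles_equal(got, want)


class TestEnumeration:
    def test_no_active_repeats(self, direct_sim):
        genome, truth = direct_sim
        ms = mr.genome_to_molecules(genome, truth.repeats)
        assert mr.enumerate_conformation_space(ms, []) == []

    def test_single_event_counts(self):
        cfg = mr.SimulationConfig(
            seed=51,
            chromosome_lengths=(30_000,),
            repeats=(
                mr.PlantedRepeat(length=200, orientation="direct"),
                mr.PlantedRepeat(length=200, orientation="inverted"),
            ),
        )
        genome, truth = mr.simulate_genome(cfg)
        ms = mr.genome_to_molecules(genome, truth.repeats)
        products = mr.enumerate_conformation_space(ms, truth.repeats)
        assert len(products) == 2
        by_prov = {p.provenance: len(p.molecules) for p in products}
        # direct intra adds a circle, inverted intra keeps the count
        assert by_prov[truth.repeats[0].id] == 2
        assert by_prov[truth.repeats[1].id] == 1

    def test_depth_two_matches_exhaustive_surgery(self):
        cfg = mr.SimulationConfig(
            seed=52,
            chromosome_lengths=(20_000,),
            repeats=(
                mr.PlantedRepeat(length=200, orientation="direct"),
                mr.PlantedRepeat(length=200, orientation="direct"),
            ),
        )
        genome, truth = mr.simulate_genome(cfg)
        ms = mr.genome_to_molecules(genome, truth.repeats)
        products = mr.enumerate_conformation_space(ms, truth.repeats, depth=2)
        got_sets = [
            sorted(mr.realize_sequence(m, genome) for m in p.molecules)
            for p in products
        ]
        # brute-force: apply surgeries in every order on the raw sequence
        seq = genome.chromosomes[0].residues

        def loci(rep):
            return tuple(
                sorted(
                    [
                        (rep.copy1.start, rep.copy1.end),
                        (rep.copy2.start, rep.copy2.end),
                    ]
                )
            )

        r1, r2 = truth.repeats
        a1, b1 = surgery_split_direct(seq, *loci(r1))
        a2, b2 = surgery_split_direct(seq, *loci(r2))
        # each single split, plus the double split (both repeats cut)
        for single in ([a1, b1], [a2, b2]):
            assert any(
                len(g) == 2
                and all(
                    any(circles_equal(x, y) for y in single) for x in g
                )
                for g in got_sets
            )
        assert len(products) >= 3  # two singles and at least one depth-2 product
        for p in products:
            assert p.total_length == ms.total_length
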