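"""Determinism and statistical sanity of the synthetic-data generator."""

import edlib
import numpy as np
import pytest

import mitorecomb as mr
from mitorecomb.simulate import clopper_pearson, inject_errors
from mitorecomb.support import SupportCounts


class TestSimulateGenome:
    def test_determinism(self):
        cfg = mr.SimulationConfig(
            seed=71,
            chromosome_lengths=(20_000,),
            repeats=(mr.PlantedRepeat(length=200),),
            mtpt_lengths=(300,),
        )
        g1, t1 = mr.simulate_genome(cfg)
        g2, t2 = mr.simulate_genome(cfg)
        assert [c.residues for c in g1] == [c.residues for c in g2]
        assert t1.repeats == t2.repeats
        assert [c.residues for c in t1.plastome] == [
            c.residues for c in t2.plastome
        ]

    def test_gc_content(self):
        cfg = mr.SimulationConfig(seed=72, chromosome_lengths=(100_000,), gc=0.445)
        genome, _ = mr.simulate_genome(cfg)
        seq = genome.chromosomes[0].residues
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.445) < 0.01

    def test_truth_table_lists_planted_pair(self):
        cfg = mr.SimulationConfig(
            seed=73,
            chromosome_lengths=(20_000,),
            repeats=(mr.PlantedRepeat(length=87),),
        )
        genome, truth = mr.simulate_genome(cfg)
        (rep,) = truth.repeats
        assert rep.identity == 100.0 and rep.aln_length == 87
        c1 = genome["chr1"].residues[rep.copy1.start - 1 : rep.copy1.end]
        c2 = genome["chr1"].residues[rep.copy2.start - 1 : rep.copy2.end]
        assert c1 == c2

    def test_too_small_genome_rejected(self):
        cfg = mr.SimulationConfig(
            seed=74,
            chromosome_lengths=(500,),
            repeats=(mr.PlantedRepeat(length=100),),
        )
        with pytest.raises(mr.InputError):
            mr.simulate_genome(cfg)


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self):
        cfg = mr.SimulationConfig(seed=75, chromosome_lengths=(10_000,))
        genome, _ = mr.simulate_genome(cfg)
        seq = genome.chromosomes[0].residues
        model = mr.ReadModel(count=50, error_rate=0.0, min_length=500)
        reads, prov = mr.simulate_reads([("chr1", seq, 1.0)], model, seed=75)
        doubled = seq + seq
        for (_, r), p in zip(reads, prov):
            probe = r if p.strand == "+" else mr.reverse_complement(r)
            assert probe in doubled

    def test_minor_fraction_binomial(self):
        cfg = mr.SimulationConfig(
            seed=76,
            chromosome_lengths=(30_000,),
            repeats=(mr.PlantedRepeat(length=300, minor_fraction=0.10),),
        )
        genome, truth = mr.simulate_genome(cfg)
        _, prov, expected = mr.simulate_junction_reads(
            genome, truth.repeats[0], 0.10, 2_000,
            model=mr.ReadModel(count=2_000, error_rate=0.0), seed=76,
        )
        minor = sum(1 for p in prov if p.conformation in ("C3", "C4"))
        assert minor == expected.mic1 + expected.mic2
        sigma = (2_000 * 0.1 * 0.9) ** 0.5
        assert abs(minor - 200) <= 3 * sigma

    def test_weights_must_sum_to_one(self):
        with pytest.raises(mr.InputError):
            mr.simulate_reads([("a", "ACGT" * 100, 0.5)], mr.ReadModel(count=1))

    def test_read_determinism(self):
        cfg = mr.SimulationConfig(seed=77, chromosome_lengths=(10_000,))
        genome, _ = mr.simulate_genome(cfg)
        seq = genome.chromosomes[0].residues
        model = mr.ReadModel(count=20, error_rate=0.1)
        r1, _ = mr.simulate_reads([("chr1", seq, 1.0)], model, seed=5)
        r2, _ = mr.simulate_reads([("chr1", seq, 1.0)], model, seed=5)
        assert r1 == r2


class TestInjectErrors:
    def test_zero_rate_identity(self, rng):
        seq = "ACGT" * 500
        assert inject_errors(seq, 0.0, (0.1, 0.5, 0.4), rng) == seq

    def test_edit_distance_tracks_rate(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        noisy = inject_errors(seq, 0.10, (0.1, 0.5, 0.4), rng)
        dist = edlib.align(seq, noisy, mode="NW", task="distance")["editDistance"]
        assert 0.07 < dist / len(seq) < 0.13


class TestEvaluateRecovery:
    def _records(self, genome, truth, counts):
        rep = truth.repeats[0]
        rec = mr.RecombRecord(repeat=rep, counts=counts)
        rec.frequency = mr.recombination_frequency(counts)
        return mr.call_active_repeats([rec])

    def test_zero_minor_fraction(self):
        cfg = mr.SimulationConfig(
            seed=78,
            chromosome_lengths=(20_000,),
            repeats=(mr.PlantedRepeat(length=300, minor_fraction=0.0),),
        )
        genome, truth = mr.simulate_genome(cfg)
        counts = SupportCounts(truth.repeats[0].id, mac1=52, mac2=48)
        recs = self._records(genome, truth, counts)
        assert recs[0].frequency == 0.0
        assert not recs[0].active
        report = mr.evaluate_recovery(truth, recs)
        assert report[truth.repeats[0].id]["covered"]

    def test_symmetric_mixture_covered(self):
        cfg = mr.SimulationConfig(
            seed=79,
            chromosome_lengths=(20_000,),
            repeats=(mr.PlantedRepeat(length=300, minor_fraction=0.5),),
        )
        genome, truth = mr.simulate_genome(cfg)
        counts = SupportCounts(truth.repeats[0].id, 26, 24, 25, 25)
        report = mr.evaluate_recovery(truth, self._records(genome, truth, counts))
        assert report[truth.repeats[0].id]["covered"]

    def test_unmatched_id_errors(self):
        cfg = mr.SimulationConfig(seed=80, chromosome_lengths=(20_000,))
        genome, truth = mr.simulate_genome(cfg)
        rep = mr.RepeatPair(
            id="rXX",
            copy1=mr.Locus("chr1", 1, 100, "+"),
            copy2=mr.Locus("chr1", 500, 599, "+"),
            orientation="direct",
            identity=100.0,
            aln_length=100,
            mismatches=0,
            gap_opens=0,
            evalue=0.0,
        )
        rec = mr.RecombRecord(repeat=rep, counts=SupportCounts("rXX", 1, 1, 1, 1))
        with pytest.raises(mr.InputError):
            mr.evaluate_recovery(truth, [rec])


class TestClopperPearson:
    def test_known_interval(self):
        lo, hi = clopper_pearson(5, 50)
        # exact interval for 5/50 at 95%
        assert lo == pytest.approx(0.0333, abs=2e-3)
        assert hi == pytest.approx(0.2181, abs=2e-3)

    def test_edge_cases(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0
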