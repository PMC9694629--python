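"""Plastid-transfer detection, footprint summary, and gene clustering."""

import pytest

import mitorecomb as mr
from mitorecomb import reference
from mitorecomb.mtpt import (
    GeneFeature,
    MTPTRecord,
    annotate_records,
    group_gene_clusters,
    read_annotation,
    summarize_mtpt,
)


@pytest.fixture(scope="module")
def transfer_sim():
    cfg = mr.SimulationConfig(
        seed=61,
        chromosome_lengths=(60_000,),
        mtpt_lengths=(1_000, 450, 250, 120, 80),
        plastome_length=25_000,
    )
    return mr.simulate_genome(cfg)


class TestFindMtpt:
    def test_planted_transfers_recovered(self, transfer_sim):
        genome, truth = transfer_sim
        records = mr.find_mtpt(genome, truth.plastome)
        # the 80 bp transfer is below min_length; the other four recovered
        assert len(records) == 4
        got = sorted((r.mito_locus.start, r.mito_locus.end) for r in records)
        want = sorted(
            (m.start, m.end) for m, _ in truth.mtpts if m.end - m.start + 1 >= 100
        )
        for (gs, ge), (ws, we) in zip(got, want):
            # each record covers its planted locus; local alignment may
            # extend a few chance-matching background bases past the edges
            assert gs <= ws and ge >= we
            assert ws - gs <= 5 and ge - we <= 5

    def test_below_min_length_dropped(self, transfer_sim):
        genome, truth = transfer_sim
        records = mr.find_mtpt(genome, truth.plastome, min_length=500)
        assert len(records) == 1
        assert records[0].aln_length >= 1000

    def test_no_false_records_without_transfers(self):
        cfg = mr.SimulationConfig(seed=62, chromosome_lengths=(50_000,))
        genome, _ = mr.simulate_genome(cfg)
        pcfg = mr.SimulationConfig(seed=63, chromosome_lengths=(25_000,), gc=0.37)
        plastome, _ = mr.simulate_genome(pcfg)
        assert mr.find_mtpt(genome, plastome) == []


class TestSummary:
    def _record(self, rid, start, end, chrom="MC1"):
        return MTPTRecord(
            id=rid,
            mito_locus=mr.Locus(chrom, start, end, "+"),
            plastid_locus=mr.Locus("pt", start, end, "+"),
            identity=100.0,
            aln_length=end - start + 1,
        )

    def test_published_footprint_fractions(self):
        recs = [self._record("m1", 1, reference.MTPT_TOTAL_BP)]
        s = summarize_mtpt(recs, reference.MITO_LENGTH, reference.PLASTOME_LENGTH)
        assert s["total_bp"] == 12_583
        assert s["pct_of_mito"] == 3.04
        assert s["pct_of_plastome"] == 8.31

    def test_overlaps_not_double_counted(self):
        recs = [self._record("a", 100, 599), self._record("b", 400, 899)]
        s = summarize_mtpt(recs, 10_000, 10_000)
        assert s["total_bp"] == 800

    def test_empty(self):
        s = summarize_mtpt([], 1000, 1000)
        assert s == {
            "n": 0,
            "total_bp": 0,
            "pct_of_mito": 0.0,
            "pct_of_plastome": 0.0,
        }


ANNOT = [
    GeneFeature("rbcL", "pt", 1_000, 2_400, "+"),
    GeneFeature("atpB", "pt", 2_600, 4_000, "-"),
    GeneFeature("atpE", "pt", 4_010, 4_400, "-"),
    GeneFeature("trnM-CAU", "pt", 4_500, 4_570, "+"),
    GeneFeature("psbB", "pt", 8_000, 9_500, "+"),
]


class TestGeneClusters:
    def _rec(self, rid, ps, pe):
        return MTPTRecord(
            id=rid,
            mito_locus=mr.Locus("MC1", 10, 10 + pe - ps, "+"),
            plastid_locus=mr.Locus("pt", ps, pe, "+"),
            identity=100.0,
            aln_length=pe - ps + 1,
        )

    def test_full_gene_cluster(self):
        (cl,) = group_gene_clusters([self._rec("m1", 900, 4_600)], ANNOT)
        assert cl.genes == (
            ("rbcL", True),
            ("atpB", True),
            ("atpE", True),
            ("trnM-CAU", True),
        )

    def test_partial_gene_flagged(self):
        (cl,) = group_gene_clusters([self._rec("m2", 8_700, 9_900)], ANNOT)
        assert cl.genes == (("psbB", False),)

    def test_intergenic_is_empty(self):
        (cl,) = group_gene_clusters([self._rec("m3", 5_000, 6_000)], ANNOT)
        assert cl.genes == ()

    def test_mismatched_annotation_rejected(self):
        bad = [GeneFeature("x", "other", 1, 10, "+")]
        with pytest.raises(mr.InputError):
            group_gene_clusters([self._rec("m1", 1, 100)], bad)

    def test_annotate_records(self):
        recs = [self._rec("m1", 900, 4_600)]
        out = annotate_records(recs, group_gene_clusters(recs, ANNOT))
        assert out[0].genes[0] == ("rbcL", True)


class TestAnnotationReaders:
    def test_gff3_gene_rows(self, tmp_path):
        gff = tmp_path / "pt.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "pt\tsrc\tgene\t1000\t2400\t.\t+\t.\tID=g1;Name=rbcL\n"
            "pt\tsrc\texon\t1000\t2400\t.\t+\t.\tParent=g1\n"
            "pt\tsrc\tgene\t2600\t4000\t.\t-\t.\tID=g2;gene=atpB\n"
        )
        feats = read_annotation(gff)
        assert [(f.name, f.start, f.end, f.strand) for f in feats] == [
            ("rbcL", 1000, 2400, "+"),
            ("atpB", 2600, 4000, "-"),
        ]

    def test_genbank_gene_features(self, tmp_path):
        gb = tmp_path / "pt.gb"
        gb.write_text(
            "LOCUS       pt                 100 bp    DNA     circular PLN 01-JAN-2000\n"
            "FEATURES             Location/Qualifiers\n"
            "     gene            10..50\n"
            '                     /gene="rbcL"\n'
            "ORIGIN\n"
            "        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac\n"
            "       51 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac\n"
            "//\n"
        )
        feats = read_annotation(gb)
        assert [(f.name, f.start, f.end) for f in feats] == [("rbcL", 10, 50)]


class TestFlankConfirmation:
    def test_spanning_reads_counted(self, transfer_sim):
        genome, truth = transfer_sim
        records = mr.find_mtpt(genome, truth.plastome, min_length=500)
        (rec,) = records
        from mitorecomb.mtpt import confirm_mtpt_flanks
        from mitorecomb.sequence import extract_circular

        chrom = genome[rec.mito_locus.chrom_id]
        lo, hi = rec.mito_locus.start, rec.mito_locus.end
        spanning = extract_circular(chrom, lo - 2500, hi + 2500)
        non_spanning = extract_circular(chrom, lo - 100, hi + 100)
        counts = confirm_mtpt_flanks(
            [rec], genome, [("a", spanning), ("b", non_spanning)], flank=2000
        )
        assert counts[rec.id] == 1
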