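"""Gene-model parsing, promoter construction and promoter filtering."""

import math
import random

import pytest

from pancscan.annotation import (
    CLEAN,
    CONTAMINATED,
    EXCLUDED,
    cpg_overlap_fraction,
    promoter_interval,
    read_gene_models,
    select_promoters,
)
from tests.conftest import make_gene

GTF = """\
chr1\tsrc\tgene\t5001\t8000\t.\t+\t.\tgene_id "gA";
chr1\tsrc\ttranscript\t5001\t8000\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";
chr1\tsrc\tCDS\t5101\t5400\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";
chr1\tsrc\ttranscript\t5501\t8000\t.\t+\t.\tgene_id "gA"; transcript_id "gA.2";
chr1\tsrc\tgene\t20001\t24000\t.\t-\t.\tgene_id "gB";
chr1\tsrc\ttranscript\t20001\t24000\t.\t-\t.\tgene_id "gB"; transcript_id "gB.1";
chr2\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "gC";
chr2\tsrc\ttranscript\t1001\t2000\t.\t+\t.\tgene_id "gC"; transcript_id "gC.1";
"""


class TestReadGeneModels:
    def test_gtf_groups_transcripts_by_gene(self, tmp_path):
        path = tmp_path / "toy.gtf"
        path.write_text(GTF)
        models = read_gene_models(str(path))
        assert [m.gene_id for m in models] == ["gA", "gB", "gC"]
        ga = models[0]
        # 1-based GTF 5001 -> 0-based 5000; two distinct starts, most
        # upstream first
        assert ga.tss == 5000
        assert ga.tss_alternatives == [5000, 5500]
        assert ga.cds_exons == [(5100, 5400)]
        gb = models[1]
        assert gb.strand == "-" and gb.tss == 23999

    def test_bed12_cds_from_blocks_intersect_thick(self, tmp_path):
        # - strand gene, two blocks, thick interval cuts into both; the
        # expected CDS comes from intersecting each block with the thick
        # interval by hand
        line = "chr1\t1000\t2000\tgX.1\t0\t-\t1100\t1900\t0\t2\t300,400\t0,600\n"
        path = tmp_path / "toy.bed"
        path.write_text(line)
        blocks = [(1000, 1300), (1600, 2000)]
        thick = (1100, 1900)
        expected = [(max(s, thick[0]), min(e, thick[1])) for s, e in blocks]
        (model,) = read_gene_models(str(path))
        assert model.strand == "-"
        assert model.tss == 1999
        assert model.cds_exons == expected

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.gtf"
        path.write_text("")
        assert read_gene_models(str(path)) == []

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(GTF + "chr1\tonly\tthree\n")
        with pytest.raises(ValueError, match="bad.gtf:9"):
            read_gene_models(str(path))


class TestPromoterInterval:
    @pytest.mark.parametrize("strand,tss,expected", [
        ("+", 10000, (8000, 10000)),   # -2000..-1 upstream window
        ("-", 10000, (10001, 12001)),  # mirror on the minus strand
        ("+", 500, (0, 500)),          # clipped at the chromosome start
    ])
    def test_window_placement(self, strand, tss, expected):
        g = make_gene(strand=strand, tss=tss)
        assert promoter_interval(g, 2000) == expected

    def test_no_upstream_room_is_empty(self):
        g = make_gene(strand="+", tss=0)
        iv = promoter_interval(g, 2000)
        assert iv[1] <= iv[0]

    def test_minus_strand_clipped_at_chrom_end(self):
        g = make_gene(strand="-", tss=10000)
        assert promoter_interval(g, 2000, chrom_length=10500) == (10001, 10500)

    @pytest.mark.parametrize("tss", [3000, 7777, 50000])
    def test_strand_symmetry_under_coordinate_mirror(self, tss):
        # mirroring the chromosome maps a + promoter onto the - promoter
        # of the mirrored gene
        L = 100000
        plus = make_gene(strand="+", tss=tss)
        minus = make_gene(strand="-", tss=L - 1 - tss, length=3000)
        a = promoter_interval(plus, 2000)
        b = promoter_interval(minus, 2000, chrom_length=L)
        assert (L - a[1], L - a[0]) == b


class TestSelectPromoters:
    def test_isolated_gene_is_clean(self):
        g = make_gene(tss=10000)
        (p,) = select_promoters([g])
        assert p.promoter_class == CLEAN
        assert p.interval == promoter_interval(g, 2000)
        assert p.panc_strand == "-"

    def test_promoter_into_neighbour_span_is_contaminated(self):
        a = make_gene("gA", tss=2000, length=5000, strand="+")     # span 2000-7000
        b = make_gene("gB", tss=8000, length=4000, strand="+")     # prom 6000-8000
        proms = {p.gene_id: p for p in select_promoters([a, b])}
        assert proms["gB"].promoter_class == CONTAMINATED
        assert proms["gA"].promoter_class == CLEAN

    def test_distal_tss_escapes_promoter_conflict(self):
        # gA's proximal promoter overlaps gB's promoter; its distal
        # alternative is free, so the distal one is selected
        a = make_gene("gA", strand="+", tss=21000, length=7000,
                      alts=[21000, 24000])
        b = make_gene("gB", strand="-", tss=21999, length=1000)  # prom 22000-24000
        proms = {p.gene_id: p for p in select_promoters([a, b])}
        assert proms["gA"].promoter_class == CLEAN
        assert proms["gA"].tss == 21000  # most upstream alternative
        assert proms["gA"].interval == (19000, 21000)
        # gB's own promoter sits inside gA's span
        assert proms["gB"].promoter_class == CONTAMINATED

    def test_close_promoters_resolved_to_one(self):
        # divergent pair with a 300 bp gap between promoters
        left = make_gene("gL", strand="-", tss=5000, length=3000)  # prom 5001-7001
        right = make_gene("gR", strand="+", tss=9301, length=3000)  # prom 7301-9301
        proms = {p.gene_id: p for p in select_promoters([left, right])}
        labels = sorted(p.promoter_class for p in proms.values())
        assert labels == [CLEAN, EXCLUDED]

    def test_partition_and_order_independence(self, small_sim):
        cfg, ann = small_sim
        genes = ann.genes_of("sp1")
        base = select_promoters(genes, chrom_lengths=ann.chrom_lengths["sp1"])
        assert len(base) == len(genes)
        labels = {p.gene_id: p.promoter_class for p in base}
        assert set(labels.values()) == {CLEAN, CONTAMINATED, EXCLUDED}
        shuffled = list(genes)
        random.Random(5).shuffle(shuffled)
        again = select_promoters(shuffled, chrom_lengths=ann.chrom_lengths["sp1"])
        assert {p.gene_id: (p.promoter_class, p.interval) for p in base} == \
               {p.gene_id: (p.promoter_class, p.interval) for p in again}

    def test_clean_promoters_respect_min_gap_and_no_overlap(self, small_sim):
        cfg, ann = small_sim
        genes = ann.genes_of("sp2")
        proms = select_promoters(genes, chrom_lengths=ann.chrom_lengths["sp2"])
        clean = sorted((p.interval for p in proms if p.promoter_class == CLEAN))
        spans = sorted(g.gene_span for g in genes)
        for (s1, e1), (s2, e2) in zip(clean, clean[1:]):
            assert s2 - e1 >= 500
        gid_span = {g.gene_id: g.gene_span for g in genes}
        for p in proms:
            if p.promoter_class != CLEAN:
                continue
            for gid, (s, e) in gid_span.items():
                if gid == p.gene_id:
                    continue
                assert not (p.interval[0] < e and s < p.interval[1])


class TestCpgOverlap:
    def test_fractions(self):
        proms = select_promoters([
            make_gene("g1", tss=10000),
            make_gene("g2", tss=50000),
            make_gene("g3", tss=90000),
            make_gene("g4", tss=130000),
        ])
        islands = {"chr1": [(9000, 9500), (48500, 48600), (89990, 90100)]}
        # brute force: g1 [8000,10000) hits (9000,9500); g2 [48000,50000)
        # hits (48500,48600); g3 [88000,90000) hits (89990,90100); g4 none
        out = cpg_overlap_fraction(proms, islands)
        assert out["total"] == 0.75
        assert cpg_overlap_fraction(proms, {"chr1": [(0, 10**6)]})["total"] == 1.0
        assert cpg_overlap_fraction(proms, {})["total"] == 0.0

    def test_empty_promoter_set_is_undefined(self):
        assert math.isnan(cpg_overlap_fraction([], {})["total"])
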