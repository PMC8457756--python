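"""Genome loading, annotation, operon inference, regulatory windows, background."""

from __future__ import annotations

import numpy as np
import pytest

from dapregulon.genome import (Gene, Genome, MarkovBackground, Operon,
                               extract_noncoding_regions, fit_markov_background,
                               infer_operons, read_annotation, read_genome,
                               regions_to_bed, write_annotation, write_genome)


def make_genome(length=5000, seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Genome(id="test", sequence=seq)


class TestReadGenome:
    def test_single_record_length(self, tmp_path):
        path = tmp_path / "g.fasta"
        path.write_text(">chr\n" + "ACGT" * 25 + "\n")
        g = read_genome(path)
        assert g.length == 100
        assert g.id == "chr"

    def test_lowercase_normalized(self, tmp_path):
        path = tmp_path / "g.fasta"
        path.write_text(">chr\nacgt\n")
        assert read_genome(path).sequence == "ACGT"

    def test_ambiguity_codes_become_n_and_roundtrip(self, tmp_path, caplog):
        path = tmp_path / "g.fasta"
        path.write_text(">chr\nACGRT\n")
        with caplog.at_level("WARNING"):
            g = read_genome(path)
        assert g.sequence == "ACGNT"
        assert any("mapped to N" in r.message for r in caplog.records)
        out = tmp_path / "out.fasta"
        write_genome(g, out)
        assert read_genome(out).sequence == g.sequence

    def test_empty_file_is_input_error(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            read_genome(path)

    def test_multiple_records_warns_and_uses_first(self, tmp_path, caplog):
        path = tmp_path / "g.fasta"
        path.write_text(">a\nAAAA\n>b\nCCCC\n")
        with caplog.at_level("WARNING"):
            g = read_genome(path)
        assert g.sequence == "AAAA"
        assert any("using the first" in r.message for r in caplog.records)


GFF_HEADER = "##gff-version 3\n"


def gff_line(start, end, strand="+", tag="g1", ftype="CDS"):
    return (f"test\tsrc\t{ftype}\t{start}\t{end}\t.\t{strand}\t0\t"
            f"ID=cds-{tag};locus_tag={tag};product=protein {tag}\n")


class TestReadAnnotation:
    def test_coordinate_convention(self, tmp_path):
        genome = make_genome(100)
        path = tmp_path / "a.gff3"
        path.write_text(GFF_HEADER + gff_line(11, 20))
        (gene,) = read_annotation(path, genome)
        assert (gene.start, gene.end, gene.strand) == (10, 20, "+")

    def test_duplicate_locus_tag_rejected(self, tmp_path):
        genome = make_genome(100)
        path = tmp_path / "a.gff3"
        path.write_text(GFF_HEADER + gff_line(1, 10, tag="dup")
                        + gff_line(21, 30, tag="dup"))
        with pytest.raises(ValueError, match="duplicate locus_tag"):
            read_annotation(path, genome)

    def test_three_features_sorted_by_start(self, tmp_path):
        genome = make_genome(200)
        path = tmp_path / "a.gff3"
        path.write_text(GFF_HEADER + gff_line(101, 150, tag="c")
                        + gff_line(1, 50, tag="a") + gff_line(51, 100, tag="b"))
        genes = read_annotation(path, genome)
        assert [g.locus_tag for g in genes] == ["a", "b", "c"]
        assert [(g.start, g.end) for g in genes] == [(0, 50), (50, 100), (100, 150)]

    def test_out_of_bounds_feature_named_in_error(self, tmp_path):
        genome = make_genome(50)
        path = tmp_path / "a.gff3"
        path.write_text(GFF_HEADER + gff_line(40, 90, tag="runaway"))
        with pytest.raises(ValueError, match="runaway"):
            read_annotation(path, genome)

    def test_write_read_roundtrip(self, tmp_path):
        genome = make_genome(300)
        genes = [Gene("x1", 10, 100, "+", "p1"), Gene("x2", 150, 290, "-", "p2")]
        path = tmp_path / "rt.gff3"
        write_annotation(genes, genome, path)
        back = read_annotation(path, genome)
        assert [(g.locus_tag, g.start, g.end, g.strand) for g in back] == \
               [(g.locus_tag, g.start, g.end, g.strand) for g in genes]


class TestInferOperons:
    def g(self, tag, start, end, strand="+"):
        return Gene(tag, start, end, strand)

    def test_small_gap_merges(self):
        ops = infer_operons([self.g("a", 0, 100), self.g("b", 150, 250)],
                            max_gap=150)
        assert len(ops) == 1 and ops[0].locus_tags == ["a", "b"]

    def test_large_gap_splits(self):
        ops = infer_operons([self.g("a", 0, 100), self.g("b", 600, 700)],
                            max_gap=150)
        assert len(ops) == 2

    def test_strand_switch_always_splits(self):
        genes = [self.g("a", 0, 100, "+"), self.g("b", 110, 200, "-"),
                 self.g("c", 210, 300, "+")]
        ops = infer_operons(genes, max_gap=1000)
        assert len(ops) == 3

    def test_minus_strand_transcription_order(self):
        genes = [self.g("a", 0, 100, "-"), self.g("b", 120, 220, "-")]
        (op,) = infer_operons(genes)
        # transcription runs right-to-left: the rightmost gene leads
        assert op.id == "b"
        assert op.locus_tags == ["b", "a"]

    def test_partition_and_idempotence(self):
        rng = np.random.default_rng(7)
        genes, pos = [], 0
        for i in range(40):
            pos += int(rng.integers(10, 400))
            length = int(rng.integers(50, 500))
            genes.append(self.g(f"g{i}", pos, pos + length,
                                "+" if rng.random() < 0.5 else "-"))
            pos += length
        ops = infer_operons(genes)
        tags = [t for op in ops for t in op.locus_tags]
        assert sorted(tags) == sorted(g.locus_tag for g in genes)
        ops2 = infer_operons(genes)
        assert [o.locus_tags for o in ops2] == [o.locus_tags for o in ops]


class TestNoncodingRegions:
    def test_full_window(self):
        genome = make_genome(3000)
        genes = [Gene("up", 200, 300, "+"), Gene("head", 1000, 2000, "+")]
        ops = infer_operons(genes, max_gap=150)
        regions = extract_noncoding_regions(genome, ops)
        region = [r for r in regions if "head" in r.downstream_operons][0]
        assert (region.start, region.end) == (600, 1040)
        assert region.upstream_extent == 400 and region.cds_overhang == 40

    def test_truncated_at_upstream_neighbor(self):
        genome = make_genome(3000)
        genes = [Gene("up", 200, 900, "+"), Gene("head", 1000, 2000, "+")]
        ops = infer_operons(genes, max_gap=50)
        regions = extract_noncoding_regions(genome, ops)
        region = [r for r in regions if "head" in r.downstream_operons][0]
        assert (region.start, region.end) == (900, 1040)

    def test_divergent_pair_shares_stretch(self):
        genome = make_genome(2000)
        genes = [Gene("left", 0, 500, "-"), Gene("right", 700, 1500, "+")]
        ops = infer_operons(genes)
        regions = extract_noncoding_regions(genome, ops)
        left = [r for r in regions if "left" in r.downstream_operons][0]
        right = [r for r in regions if "right" in r.downstream_operons][0]
        assert (left.start, left.end) == (460, 700)
        assert (right.start, right.end) == (500, 740)
        # a position in the shared stretch lies in both windows
        for pos in (500, 600, 699):
            assert pos in left and pos in right

    def test_never_overlaps_neighbor_cds(self, small_dataset):
        ds = small_dataset
        for region in ds.regions:
            for op in ds.operons:
                head = op.head
                for gene in op.genes:
                    if op.id in region.downstream_operons and gene is head:
                        continue
                    overlap = min(region.end, gene.end) - max(region.start, gene.start)
                    assert overlap <= 0, (region, gene)

    def test_short_head_gene_truncates_overhang(self, caplog):
        genome = make_genome(1000)
        genes = [Gene("tiny", 500, 525, "+")]
        ops = infer_operons(genes)
        with caplog.at_level("WARNING"):
            regions = extract_noncoding_regions(genome, ops)
        assert regions[0].cds_overhang == 25
        assert any("truncated" in r.message for r in caplog.records)

    def test_bed_export(self, tmp_path):
        genome = make_genome(2000)
        genes = [Gene("a", 1000, 1900, "+")]
        regions = extract_noncoding_regions(genome, infer_operons(genes))
        path = tmp_path / "regions.bed"
        regions_to_bed(regions, genome, path)
        fields = path.read_text().strip().split("\t")
        assert fields[:4] == ["test", "600", "1040", "a"]


class TestMarkovBackground:
    def test_uniform_composition(self):
        g = Genome(id="g", sequence="ACGT" * 100)
        bg = fit_markov_background(g, order=0)
        assert np.allclose(bg.probs[0], 0.25, atol=0.01)

    def test_pseudocount_hand_count_both_strands(self):
        # "AAAA" counted with its reverse complement "TTTT": 4 A and 4 T,
        # plus pseudocount 1 per base -> b(A) = b(T) = 5/12, b(C) = b(G) = 1/12
        g = Genome(id="g", sequence="AAAA")
        bg = fit_markov_background(g, order=0, pseudocount=1.0)
        assert bg.probs[0, 0] == pytest.approx(5 / 12)
        assert bg.probs[0, 3] == pytest.approx(5 / 12)
        assert bg.probs[0, 1] == pytest.approx(1 / 12)

    def test_contexts_normalized(self, small_dataset):
        bg = fit_markov_background(small_dataset.genome, order=2)
        assert np.allclose(bg.probs.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("order", [0, 1])
    def test_reverse_complement_symmetry(self, order):
        genome = make_genome(20000, seed=3)
        bg = fit_markov_background(genome, order=order)
        if order == 0:
            assert bg.probs[0, 0] == pytest.approx(bg.probs[0, 3], rel=1e-9)
            assert bg.probs[0, 1] == pytest.approx(bg.probs[0, 2], rel=1e-9)
        else:
            # joint P(c, x) must equal P(revcomp(x), revcomp(c))
            comp = [3, 2, 1, 0]
            counts = np.zeros((4, 4))
            # reconstruct pair frequencies from conditionals x marginals
            for c in range(4):
                for x in range(4):
                    counts[c, x] = bg.probs[c, x] * bg.base_freqs[c]
            for c in range(4):
                for x in range(4):
                    assert counts[c, x] == pytest.approx(
                        counts[comp[x], comp[c]], rel=0.05)

    def test_negative_order_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="order"):
            fit_markov_background(small_dataset.genome, order=-1)

    def test_position_log2_matches_marginal_for_order0(self):
        bg = MarkovBackground.uniform(0)
        from dapregulon._seq import encode

        vals = bg.position_log2(encode("ACGT"))
        assert np.allclose(vals, -2.0)
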