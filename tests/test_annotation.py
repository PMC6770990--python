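"""Tests of CDS extraction, the gene-model filter, and summaries."""
import pytest
from hypothesis import given
from hypothesis import strategies as st

from genoprof import (
    GeneModel,
    GenoprofError,
    classify_cds,
    completeness_percentages,
    extract_spliced_cds,
    filter_gene_models,
    parse_gff3,
    summarize_annotation,
    surviving_genes,
    write_gff3,
)
from genoprof.simulate import write_fasta
from genoprof.util import revcomp


def model(strand="+", exons=None, cds=None, seq_id="chr1", gid="g1", tid="t1"):
    return GeneModel(
        gene_id=gid,
        transcript_id=tid,
        sequence_id=seq_id,
        strand=strand,
        exons=exons or [(s, e) for s, e, _ in cds],
        cds_segments=cds,
    )


class TestExtractSplicedCds:
    def test_plus_strand_single_segment(self):
        genome = {"chr1": "ATGTAACCC"}
        assert extract_spliced_cds(model(cds=[(1, 6, 0)]), genome) == "ATGTAA"

    def test_minus_strand_reverse_complement(self):
        genome = {"chr1": "TTACAT"}
        assert extract_spliced_cds(model("-", cds=[(1, 6, 0)]), genome) == "ATGTAA"

    def test_two_plus_segments_spliced(self):
        genome = {"chr1": "ATGCCCTAA"}
        assert extract_spliced_cds(model(cds=[(1, 3, 0), (7, 9, 0)]), genome) == "ATGTAA"

    def test_phase_trims_leading_bases(self):
        genome = {"chr1": "CCATGTAA"}
        assert extract_spliced_cds(model(cds=[(1, 8, 2)]), genome) == "ATGTAA"

    def test_minus_strand_phase_on_transcription_first_segment(self):
        # transcription-first segment of a minus-strand model is the
        # genomic-last one; its phase trims the CDS 5' end
        cds = "ATGAAATAA"
        genome = {"chr1": revcomp("XX" + cds).replace("X", "G")}
        # genome = revcomp(GG + cds): segment covers everything; phase 2
        assert (
            extract_spliced_cds(model("-", cds=[(1, 11, 2)]), genome) == cds
        )

    def test_out_of_bounds_names_transcript(self):
        with pytest.raises(GenoprofError, match="t1"):
            extract_spliced_cds(model(cds=[(1, 99, 0)]), {"chr1": "ATG"})

    def test_strand_mirror_symmetry(self):
        # extracting on + equals extracting the mirrored model from the
        # reverse-complemented genome
        genome_seq = "ATGAAACCCGGGTTTTAA"
        n = len(genome_seq)
        plus = model(cds=[(1, 6, 0), (10, 18, 0)])
        minus_cds = sorted(
            ((n - e + 1, n - s + 1, p) for s, e, p in plus.cds_segments)
        )
        minus = model("-", cds=[(s, e, p) for s, e, p in minus_cds])
        assert extract_spliced_cds(plus, {"chr1": genome_seq}) == extract_spliced_cds(
            minus, {"chr1": revcomp(genome_seq)}
        )


class TestClassifyCds:
    def test_valid_cds_retained(self):
        cds = "ATG" + "AAA" * 48 + "TAA"  # 150 nt
        assert classify_cds(cds) == "retained"

    def test_rule_order_and_attribution(self):
        assert classify_cds("ATG" + "AAA" * 47 + "TAA") == "short"  # 147 nt
        assert classify_cds("ATG" + "A" * 148) == "bad_frame"  # 151 nt
        assert classify_cds("CTG" + "AAA" * 48 + "TAA") == "no_start"
        assert classify_cds("ATG" + "AAA" * 48 + "AAA") == "no_stop"
        assert classify_cds("ATG" + "TGA" + "AAA" * 47 + "TAA") == "internal_stop"

    def test_terminal_stop_is_not_internal(self):
        cds = "ATG" + "GGG" * 49 + "TGA"
        assert classify_cds(cds) == "retained"


class TestFilterGeneModels:
    def test_toy_set_attribution_and_conservation(self, toy_gene_set):
        genome_seq, models, truth = toy_gene_set
        genome = {"toy_contig": genome_seq}
        retained, rep = filter_gene_models(models, genome)
        expected = {cat: sum(1 for v in truth.values() if v == cat) for cat in set(truth.values())}
        assert rep.n_input == len(models) == 20
        assert rep.n_retained == expected["retained"]
        assert rep.n_removed_short_cds == expected["short"]
        assert rep.n_removed_bad_frame == expected["bad_frame"]
        assert rep.n_removed_no_start == expected["no_start"]
        assert rep.n_removed_no_stop == expected["no_stop"]
        assert rep.n_removed_internal_stop == expected["internal_stop"]
        assert rep.n_input == rep.n_retained + rep.n_removed
        assert {m.transcript_id for m in retained} == {
            t for t, v in truth.items() if v == "retained"
        }

    def test_filtering_is_idempotent(self, toy_gene_set):
        genome_seq, models, _ = toy_gene_set
        genome = {"toy_contig": genome_seq}
        retained, _ = filter_gene_models(models, genome)
        retained2, rep2 = filter_gene_models(retained, genome)
        assert rep2.n_removed == 0
        assert len(retained2) == len(retained)

    def test_gene_survives_if_any_transcript_survives(self):
        genome = {"chr1": "ATG" + "AAA" * 48 + "TAA"}
        good = model(cds=[(1, 150, 0)], gid="gA", tid="tGood")
        bad = model(cds=[(1, 147, 0)], gid="gA", tid="tBad")
        retained, _ = filter_gene_models([good, bad], genome)
        assert surviving_genes(retained) == {"gA"}


class TestSummarizeAnnotation:
    def test_gene_span_coverage_percent(self):
        m = model(exons=[(1, 1000)], cds=[(1, 999, 0)])
        s = summarize_annotation([m], genome_length=10_000)
        assert s.pct_genome_in_genes == 10.0

    def test_overlapping_spans_not_double_counted(self):
        m1 = model(exons=[(1, 1000)], cds=[(1, 999, 0)], gid="g1", tid="t1")
        m2 = model(exons=[(1, 1000)], cds=[(1, 999, 0)], gid="g2", tid="t2")
        one = summarize_annotation([m1], genome_length=10_000)
        two = summarize_annotation([m1, m2], genome_length=10_000)
        assert one.pct_genome_in_genes == two.pct_genome_in_genes

    def test_exon_and_intron_lengths(self):
        m = model(exons=[(1, 100), (201, 300)], cds=[(1, 100, 0), (201, 300, 2)])
        s = summarize_annotation([m], genome_length=1_000)
        assert s.mean_exon_length == 100.0
        assert s.mean_intron_length == 100.0
        assert s.mean_exons_per_cds == 2.0
        assert s.mean_gene_length == 300.0

    def test_zero_genome_length_rejected(self):
        with pytest.raises(ValueError):
            summarize_annotation([model(cds=[(1, 6, 0)])], genome_length=0)


class TestCompletenessPercentages:
    def test_printed_core_gene_percentages(self):
        # ray-finned fish core set: 4413 of 4584 complete single-copy
        acti = completeness_percentages({"complete_single": 4413}, 4584)
        assert acti.percentages["complete_single"] == 96.27
        # vertebrate core set: 2523 of 2586
        vert = completeness_percentages({"complete_single": 2523}, 2586)
        assert vert.percentages["complete_single"] == 97.56

    def test_zero_count_gives_zero_percent(self):
        s = completeness_percentages({"missing": 0}, 1000)
        assert s.percentages["missing"] == 0.0

    def test_non_reconciling_counts_flagged(self):
        s = completeness_percentages(
            {"complete_single": 4413, "complete_duplicated": 112,
             "fragmented": 89, "missing": 82},
            4584,
        )
        assert s.counts_sum == 4696
        assert not s.reconciles

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            completeness_percentages({"missing": -1}, 100)

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=10**6), min_size=1, max_size=6),
        total=st.integers(min_value=1, max_value=10**6),
    )
    def test_percentages_bounded_and_exact(self, counts, total):
        mapping = {f"c{i}": n for i, n in enumerate(counts)}
        s = completeness_percentages(mapping, total)
        for cat, n in mapping.items():
            assert s.percentages[cat] == pytest.approx(100 * n / total, abs=0.005)


class TestGff3RoundTrip:
    def test_write_parse_round_trip(self, toy_gene_set, tmp_path):
        genome_seq, models, _ = toy_gene_set
        gff = tmp_path / "toy.gff3"
        write_gff3(models, gff)
        parsed = parse_gff3(gff)
        assert parsed.n_unparseable == 0
        by_tid = {m.transcript_id: m for m in parsed.models}
        assert set(by_tid) == {m.transcript_id for m in models}
        for m in models:
            back = by_tid[m.transcript_id]
            assert back.cds_segments == m.cds_segments
            assert back.exons == m.exons
            assert back.strand == m.strand
            assert back.gene_id == m.gene_id

    def test_round_trip_preserves_filter_outcome(self, toy_gene_set, tmp_path):
        genome_seq, models, truth = toy_gene_set
        gff = tmp_path / "toy.gff3"
        fa = tmp_path / "toy.fa"
        write_gff3(models, gff)
        write_fasta([("toy_contig", genome_seq)], fa)
        import pyfaidx

        parsed = parse_gff3(gff)
        retained, rep = filter_gene_models(parsed.models, pyfaidx.Fasta(str(fa)))
        assert rep.n_retained == sum(1 for v in truth.values() if v == "retained")
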