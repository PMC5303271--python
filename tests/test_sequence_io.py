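import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sdscan.sequence_io import (ContigSet, CoverageTrack, EdgeExcludedError,
                                FormatError, GeneModel,
                                extract_initiation_region, extract_upstream,
                                read_annotation, read_fasta, read_wig,
                                reverse_complement, write_wig)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadFasta:
    def test_single_record(self, tmp_path):
        cs = read_fasta(_write(tmp_path, "a.fa", ">c1\nACGT\n"))
        assert cs["c1"] == "ACGT"

    def test_two_records_order_independent(self, tmp_path):
        cs = read_fasta(_write(tmp_path, "a.fa", ">c2\nGGGG\n>c1\nACGT\n"))
        assert cs["c1"] == "ACGT" and cs["c2"] == "GGGG"

    def test_lowercase_and_u_normalized(self, tmp_path):
        cs = read_fasta(_write(tmp_path, "a.fa", ">c1\nacgu\n"))
        assert cs["c1"] == "ACGT"

    @pytest.mark.parametrize("text", [
        "", ">c1\nACXT\n", ">c1\nACGT\n>c1\nACGT\n",
    ], ids=["empty", "illegal_char", "duplicate_id"])
    def test_format_errors(self, tmp_path, text):
        with pytest.raises(FormatError):
            read_fasta(_write(tmp_path, "bad.fa", text))

    def test_unknown_contig_lookup(self):
        with pytest.raises(KeyError):
            ContigSet({"c1": "ACGT"})["nope"]


GFF_HEADER = "##gff-version 3\n"


class TestReadAnnotation:
    def test_plus_strand_cds(self, tmp_path):
        gff = GFF_HEADER + "c1\t.\tCDS\t101\t400\t.\t+\t.\tID=g1\n"
        (gene,) = read_annotation(_write(tmp_path, "a.gff", gff))
        assert (gene.gene_id, gene.contig_id, gene.start, gene.end,
                gene.strand, gene.length_nt) == ("g1", "c1", 101, 400, "+", 300)

    def test_minus_strand_coordinates_unchanged(self, tmp_path):
        gff = GFF_HEADER + "c1\t.\tCDS\t101\t400\t.\t-\t.\tID=g1\n"
        (gene,) = read_annotation(_write(tmp_path, "a.gff", gff))
        assert gene.strand == "-" and (gene.start, gene.end) == (101, 400)

    def test_non_cds_features_ignored(self, tmp_path):
        gff = GFF_HEADER + ("c1\t.\tgene\t1\t400\t.\t+\t.\tID=g1\n"
                            "c1\t.\tmRNA\t1\t400\t.\t+\t.\tID=m1\n")
        assert read_annotation(_write(tmp_path, "a.gff", gff)) == []

    def test_locus_tag_fallback(self, tmp_path):
        gff = GFF_HEADER + "c1\t.\tCDS\t1\t9\t.\t+\t.\tlocus_tag=b0001\n"
        (gene,) = read_annotation(_write(tmp_path, "a.gff", gff))
        assert gene.gene_id == "b0001"

    @pytest.mark.parametrize("line", [
        "c1\t.\tCDS\t1\t9\t.\t+\t.\tNote=x",       # no usable identifier
        "c1\t.\tCDS\t9\t1\t.\t+\t.\tID=g1",        # start > end
        "c1\t.\tCDS\t1\t9\t.\t+\t.\tID=g1\nc1\t.\tCDS\t20\t28\t.\t+\t.\tID=g1",
    ], ids=["no_id", "reversed_coords", "multi_segment"])
    def test_errors(self, tmp_path, line):
        with pytest.raises(FormatError):
            read_annotation(_write(tmp_path, "bad.gff", GFF_HEADER + line + "\n"))


class TestReadWig:
    @pytest.fixture
    def contigs(self):
        return ContigSet({"c1": "A" * 10})

    def test_fixedstep(self, tmp_path, contigs):
        wig = "fixedStep chrom=c1 start=1 step=1\n1\n2\n3\n"
        track = read_wig(_write(tmp_path, "a.wig", wig), contigs)
        assert list(track.array("c1")) == [1, 2, 3, 0, 0, 0, 0, 0, 0, 0]
        assert track.total_signal == 6

    def test_variablestep(self, tmp_path, contigs):
        wig = "variableStep chrom=c1\n5 7\n"
        track = read_wig(_write(tmp_path, "a.wig", wig), contigs)
        arr = track.array("c1")
        assert arr[4] == 7 and arr.sum() == 7

    def test_span_repeats_value(self, tmp_path, contigs):
        wig = "variableStep chrom=c1 span=3\n2 4\n"
        track = read_wig(_write(tmp_path, "a.wig", wig), contigs)
        assert list(track.array("c1")[:5]) == [0, 4, 4, 4, 0]

    def test_track_line_ignored(self, tmp_path, contigs):
        wig = "track type=wiggle_0\nfixedStep chrom=c1 start=1 step=1\n2\n"
        assert read_wig(_write(tmp_path, "a.wig", wig), contigs).total_signal == 2

    @pytest.mark.parametrize("wig", [
        "fixedStep chrom=c1 start=9 step=1\n1\n2\n3\n",  # runs past contig
        "fixedStep chrom=c1 start=1 step=1\n-4\n",       # negative value
        "fixedStep chrom=cX start=1 step=1\n1\n",        # unknown chrom
    ], ids=["past_end", "negative", "unknown_chrom"])
    def test_errors(self, tmp_path, contigs, wig):
        with pytest.raises(FormatError):
            read_wig(_write(tmp_path, "bad.wig", wig), contigs)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=1,
                    max_size=40))
    def test_write_read_round_trip(self, tmp_path_factory, counts):
        contigs = ContigSet({"c1": "A" * len(counts)})
        track = CoverageTrack({"c1": np.array(counts, dtype=float)})
        path = tmp_path_factory.mktemp("wig") / "rt.wig"
        write_wig(track, path)
        again = read_wig(path, contigs)
        np.testing.assert_array_equal(track.array("c1"), again.array("c1"))


class TestUpstreamExtraction:
    @pytest.fixture
    def contigs(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        return ContigSet({"c1": seq})

    def test_plus_strand_window(self, contigs):
        gene = GeneModel("g", "c1", 101, 400, "+")
        expected = contigs["c1"][95:100].replace("T", "U")
        assert extract_upstream(gene, contigs, 5) == expected

    def test_minus_strand_window(self, contigs):
        gene = GeneModel("g", "c1", 101, 400, "-")
        expected = reverse_complement(contigs["c1"][400:405]).replace("T", "U")
        assert extract_upstream(gene, contigs, 5) == expected

    def test_edge_excluded_not_truncated(self, contigs):
        gene = GeneModel("g", "c1", 3, 302, "+")
        with pytest.raises(EdgeExcludedError):
            extract_upstream(gene, contigs, 5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=50, max_value=380),
           st.integers(min_value=1, max_value=20),
           st.sampled_from(["+", "-"]))
    def test_strand_symmetry(self, start, n, strand):
        """Flipping the contig and the strand yields the same upstream RNA."""
        rng = np.random.default_rng(start * 31 + n)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        contigs = ContigSet({"c1": seq})
        L = len(seq)
        gene = GeneModel("g", "c1", start, start + 89, strand)
        flipped = ContigSet({"c1": reverse_complement(seq)})
        flipped_gene = GeneModel("g", "c1", L - gene.end + 1,
                                 L - gene.start + 1,
                                 "-" if strand == "+" else "+")
        assert (extract_upstream(gene, contigs, n)
                == extract_upstream(flipped_gene, flipped, n))


class TestInitiationRegion:
    def test_reference_coordinates(self):
        seq = "".join(np.random.default_rng(0).choice(list("ACGT"), size=300))
        contigs = ContigSet({"c1": seq})
        gene = GeneModel("g", "c1", 101, 190, "+")  # exactly 30 codons
        region = extract_initiation_region(gene, contigs)
        assert region == seq[70:130].replace("T", "U")
        assert len(region) == 60

    def test_start_codon_occupies_center(self):
        seq = "T" * 100 + "ATGGCTGCTGCT" * 10 + "T" * 100
        contigs = ContigSet({"c1": seq})
        gene = GeneModel("g", "c1", 101, 101 + 119, "+")
        region = extract_initiation_region(gene, contigs)
        assert region[30:33] == "AUG"
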