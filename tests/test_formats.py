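import numpy as np
import pytest

from mugi.formats import (FormatError, IndexFormatError, load_index,
                          read_fasta, read_patterns, read_vcf_min, save_index,
                          write_matches)
from mugi.index import prepare_variants
from mugi.kmers import IndexParams
from mugi.reference import Chromosome, ChromosomeTable

from conftest import expand


@pytest.fixture
def toy_table():
    return ChromosomeTable([Chromosome("chr1", 0, 7)])


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">chr1\nACGT\n")
        ref, table = read_fasta(p)
        assert ref.length == 4
        assert [(c.name, c.global_start, c.length) for c in table] == \
            [("chr1", 0, 4)]

    def test_offsets_and_lowercase(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">a\nacgta\n>b\nGGT\n")
        ref, table = read_fasta(p)
        assert ref.to_string() == "ACGTAGGT"
        assert [c.global_start for c in table] == [0, 5]

    def test_bad_character_names_line(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">a\nACGT\nAXGT\n")
        with pytest.raises(FormatError, match="line 3"):
            read_fasta(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_duplicate_name(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">a\nAC\n>a\nGT\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(p)


VCF_HEADER = ("##fileformat=VCFv4.2\n"
              "##contig=<ID=chr1,length=7>\n"
              '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\n")


class TestVcf:
    def _write(self, tmp_path, lines):
        p = tmp_path / "v.vcf"
        p.write_text(VCF_HEADER + "".join(lines))
        return p

    def test_minimal_record(self, tmp_path, toy_table):
        p = self._write(tmp_path,
                        ["chr1\t4\t.\tT\tA\t.\t.\t.\tGT\t1|0\n"])
        vcf = read_vcf_min(p, toy_table)
        assert vcf.samples == ["S0"]
        (rec,) = vcf.records
        assert (rec.chrom, rec.pos, rec.ref_allele) == ("chr1", 4, "T")
        assert rec.alt_alleles == ("A",)
        assert rec.alleles_per_hap == (1, 0)

    def test_unphased_rejected(self, tmp_path, toy_table):
        p = self._write(tmp_path, ["chr1\t4\t.\tT\tA\t.\t.\t.\tGT\t0/1\n"])
        with pytest.raises(FormatError, match="unphased"):
            read_vcf_min(p, toy_table)

    def test_missing_genotype_rejected(self, tmp_path, toy_table):
        p = self._write(tmp_path, ["chr1\t4\t.\tT\tA\t.\t.\t.\tGT\t.|.\n"])
        with pytest.raises(FormatError, match="missing"):
            read_vcf_min(p, toy_table)

    def test_unknown_chromosome(self, tmp_path, toy_table):
        p = self._write(tmp_path, ["chr9\t4\t.\tT\tA\t.\t.\t.\tGT\t1|0\n"])
        with pytest.raises(FormatError, match="unknown chromosome"):
            read_vcf_min(p, toy_table)

    def test_unsorted_rejected(self, tmp_path, toy_table):
        p = self._write(tmp_path,
                        ["chr1\t5\t.\tA\tG\t.\t.\t.\tGT\t1|0\n",
                         "chr1\t4\t.\tT\tA\t.\t.\t.\tGT\t1|0\n"])
        with pytest.raises(FormatError, match="unsorted"):
            read_vcf_min(p, toy_table)

    def test_generator_output_reads_back_identically(self, tmp_path):
        from mugi.simulate import CollectionSpec, generate_collection
        spec = CollectionSpec(ref_len=1500, n_samples=3, rng_seed=42)
        coll = generate_collection(spec, tmp_path / "g.fa", tmp_path / "g.vcf")
        ref, table = read_fasta(tmp_path / "g.fa")
        assert ref.to_string() == "".join(coll.sequences.values())
        vcf = read_vcf_min(tmp_path / "g.vcf", table)
        assert vcf.samples == coll.samples
        assert len(vcf.records) == len(coll.records)
        for got, want in zip(vcf.records, coll.records):
            assert (got.chrom, got.pos, got.ref_allele) == \
                (want.chrom, want.pos, want.ref_allele)
            assert tuple(got.alt_alleles) == tuple(want.alt_alleles)
            assert got.alleles_per_hap == want.alleles_per_hap


class TestPatterns:
    def test_txt_ids_by_line(self, tmp_path):
        p = tmp_path / "q.txt"
        p.write_text("acgt\nGGTT\n")
        assert read_patterns(p, "txt") == [("1", "ACGT"), ("2", "GGTT")]

    def test_txt_empty_line_skipped_with_warning(self, tmp_path):
        p = tmp_path / "q.txt"
        p.write_text("ACGT\n\nGGTT\n")
        with pytest.warns(UserWarning):
            got = read_patterns(p, "txt")
        assert [g[0] for g in got] == ["1", "2"]

    def test_fasta_and_fastq(self, tmp_path):
        p = tmp_path / "q.fa"
        p.write_text(">r1\nACGT\n")
        assert read_patterns(p, "fasta") == [("r1", "ACGT")]
        p = tmp_path / "q.fq"
        p.write_text("@r1\nACGT\n+\nIIII\n")
        assert read_patterns(p, "fastq") == [("r1", "ACGT")]

    def test_malformed_fastq(self, tmp_path):
        p = tmp_path / "q.fq"
        p.write_text("@r1\nACGT\n+\nII\n")
        with pytest.raises(FormatError, match="malformed"):
            read_patterns(p, "fastq")


class TestMatchReport:
    def test_rows_and_haplotype_naming(self, tmp_path, toy_snp_index):
        recs = toy_snp_index.exact_search("GAA", min_seed_len=1)
        out = tmp_path / "m.tsv"
        write_matches([("1", recs)], out, toy_snp_index)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("pattern_id\tchrom")
        assert lines[1].split("\t") == ["1", "chr1", "2", "0", "0", "1",
                                        "S0_1"]

    def test_empty_results_header_only(self, tmp_path, toy_snp_index):
        out = tmp_path / "m.tsv"
        write_matches([("1", [])], out, toy_snp_index)
        assert len(out.read_text().splitlines()) == 1

    def test_same_position_different_sets_two_rows(self, tmp_path,
                                                   toy_snp_index):
        recs = toy_snp_index.approximate_search("GTA", 1, min_seed_len=1)
        out = tmp_path / "m.tsv"
        write_matches([("1", recs)], out, toy_snp_index)
        assert len(out.read_text().splitlines()) == 3


class TestIndexContainer:
    def test_roundtrip_preserves_all_answers(self, tmp_path, rich_index):
        path = tmp_path / "toy.mugi"
        save_index(rich_index, path)
        loaded = load_index(path)
        rng = np.random.default_rng(0)
        for _ in range(100):
            P = "".join(rng.choice(list("ACGT"), int(rng.integers(4, 12))))
            a = [(r.key(), r.mismatches, r.haplotypes.tobytes())
                 for r in rich_index.approximate_search(P, 1, min_seed_len=1)]
            b = [(r.key(), r.mismatches, r.haplotypes.tobytes())
                 for r in loaded.approximate_search(P, 1, min_seed_len=1)]
            assert a == b

    def test_wrong_magic(self, tmp_path):
        p = tmp_path / "x.mugi"
        p.write_bytes(b"NOTANIDX" + b"\x00" * 64)
        with pytest.raises(IndexFormatError, match="not a MuGI index"):
            load_index(p)

    def test_truncated(self, tmp_path, toy_snp_index):
        p = tmp_path / "t.mugi"
        save_index(toy_snp_index, p)
        blob = p.read_bytes()
        p.write_bytes(blob[:len(blob) // 2])
        with pytest.raises(IndexFormatError):
            load_index(p)

    def test_corrupted_checksum(self, tmp_path, toy_snp_index):
        p = tmp_path / "c.mugi"
        save_index(toy_snp_index, p)
        blob = bytearray(p.read_bytes())
        blob[-1] ^= 0xFF
        p.write_bytes(bytes(blob))
        with pytest.raises(IndexFormatError, match="checksum"):
            load_index(p)
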