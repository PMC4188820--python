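import numpy as np
import pytest

from mugi.index import prepare_variants
from mugi.oracle import (decode_all_haplotypes, decode_haplotype,
                         equivalence_check, generate_query_set, oracle_scan)
from mugi.simulate import CollectionSpec, generate_collection, synthesize
from mugi.variants import Variant, VariantDatabase
from mugi.reference import Chromosome, ChromosomeTable, PackedReference


def _setup(spec):
    coll = synthesize(spec)
    ref = coll.reference
    vd, matrix = prepare_variants(coll.records, coll.chrom_table, ref,
                                  coll.n_haplotypes)
    return coll, ref, vd, matrix


class TestGenerator:
    def test_zero_rates_give_empty_vcf(self):
        coll = synthesize(CollectionSpec(ref_len=500, n_samples=2,
                                         snp_rate=0, del_rate=0, ins_rate=0,
                                         sv_rate=0, rng_seed=1))
        assert coll.records == []

    def test_fixed_seed_reproduces_files(self, tmp_path):
        spec = CollectionSpec(ref_len=800, n_samples=2, rng_seed=3)
        generate_collection(spec, tmp_path / "a.fa", tmp_path / "a.vcf")
        generate_collection(spec, tmp_path / "b.fa", tmp_path / "b.vcf")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_snp_count_within_five_sigma(self):
        n, p = 10_000, 0.01
        coll = synthesize(CollectionSpec(ref_len=n, n_samples=2, snp_rate=p,
                                         del_rate=0, ins_rate=0, sv_rate=0,
                                         multiallelic_frac=0, rng_seed=4))
        mean, sigma = n * p, (n * p * (1 - p)) ** 0.5
        assert abs(len(coll.records) - mean) < 5 * sigma

    def test_no_carried_overlaps_per_haplotype(self):
        coll, ref, vd, matrix = _setup(
            CollectionSpec(ref_len=3000, n_samples=6, del_rate=0.004,
                           sv_rate=0.002, rng_seed=5))
        # decode_haplotype raises on overlapping carried variants
        for h in range(matrix.n_haplotypes):
            decode_haplotype(ref, coll.chrom_table, vd, matrix.rows[:, h], h)


class TestDecodeHaplotype:
    REF = PackedReference("ACGTACG")
    TABLE = ChromosomeTable([Chromosome("chr1", 0, 7)])

    def test_snp_application(self):
        vd = VariantDatabase([Variant("SNP", 3, alt_char="A")])
        carried = np.array([True])
        (ph,) = decode_haplotype(self.REF, self.TABLE, vd, carried, 0)
        assert ph.text == "ACGAACG"
        (ph,) = decode_haplotype(self.REF, self.TABLE, vd, ~carried, 1)
        assert ph.text == "ACGTACG"

    def test_deletion_length_conservation(self):
        vd = VariantDatabase([Variant("DEL", 2, del_len=3)])
        (ph,) = decode_haplotype(self.REF, self.TABLE, vd,
                                 np.array([True]), 0)
        assert len(ph.text) == 7 - 3

    def test_insertion_projection_offsets(self):
        vd = VariantDatabase([Variant("INS", 2, ins_seq="GG")])
        (ph,) = decode_haplotype(self.REF, self.TABLE, vd,
                                 np.array([True]), 0)
        assert ph.text == "ACGGGTACG"
        assert ph.pre[2:4].tolist() == [2, 2]
        assert ph.off[2:4].tolist() == [1, 2]
        assert ph.off[4] == 0 and ph.pre[4] == 2

    def test_length_balance_identity(self):
        coll, ref, vd, matrix = _setup(
            CollectionSpec(ref_len=1000, n_samples=4, rng_seed=6))
        for h in range(matrix.n_haplotypes):
            (ph,) = decode_haplotype(ref, coll.chrom_table, vd,
                                     matrix.rows[:, h], h)
            delta = sum(len(vd[i].ins_seq) - vd[i].del_len
                        for i in np.flatnonzero(matrix.rows[:, h]))
            assert len(ph.text) == 1000 + delta


class TestOracleScan:
    def test_toy_examples(self):
        vd = VariantDatabase([Variant("SNP", 3, alt_char="A")])
        ref = PackedReference("ACGTACG")
        table = ChromosomeTable([Chromosome("chr1", 0, 7)])
        h0 = decode_haplotype(ref, table, vd, np.array([True]), 0)
        h1 = decode_haplotype(ref, table, vd, np.array([False]), 1)
        haps = h0 + h1
        assert oracle_scan(haps, "ACGT", 0) == {("chr1", 0, 0, 1): 0}
        assert oracle_scan(haps, "ACGA", 0) == {("chr1", 0, 0, 0): 0}
        assert oracle_scan(haps, "ACGG", 1) == {("chr1", 0, 0, 0): 1,
                                                ("chr1", 0, 0, 1): 1}

    def test_pattern_n_matches_nothing(self):
        vd = VariantDatabase([])
        ref = PackedReference("ANGT")
        table = ChromosomeTable([Chromosome("chr1", 0, 4)])
        haps = decode_haplotype(ref, table, vd, np.zeros(0, bool), 0)
        assert oracle_scan(haps, "ANGT", 0) == {}
        # pattern N vs collection N still counts as one mismatch
        assert oracle_scan(haps, "ANGT", 1) == {("chr1", 0, 0, 0): 1}


class TestEquivalenceCheck:
    def test_identical_sets_pass(self):
        a = {("chr1", 3, 0, 1): 0}
        assert equivalence_check(dict(a), dict(a)).ok

    def test_missing_tuple_listed(self):
        rep = equivalence_check({}, {("chr1", 3, 0, 1): 0})
        assert not rep.ok and rep.missing == [("chr1", 3, 0, 1)]

    def test_extra_and_wrong_count_listed(self):
        rep = equivalence_check({("chr1", 1, 0, 0): 0, ("chr1", 2, 0, 0): 2},
                                {("chr1", 2, 0, 0): 1})
        assert not rep.ok
        assert rep.extra == [("chr1", 1, 0, 0)]
        assert rep.wrong_count == [(("chr1", 2, 0, 0), 2, 1)]


class TestQuerySet:
    def test_error_free_queries_found_exactly(self):
        from mugi.kmers import IndexParams
        from mugi.verify import build_from_collection
        coll, ref, vd, matrix = _setup(
            CollectionSpec(ref_len=2000, n_samples=3, rng_seed=9))
        haps = decode_all_haplotypes(ref, coll.chrom_table, vd, matrix)
        idx = build_from_collection(coll, IndexParams(k=20, lut_width=8))
        for _, P in generate_query_set(haps, 20, (100, 150), (0, 0),
                                       rng_seed=10):
            recs = idx.exact_search(P)
            assert recs and any(r.haplotypes.any() for r in recs)

    def test_fixed_seed_reproducible(self):
        coll, ref, vd, matrix = _setup(
            CollectionSpec(ref_len=2000, n_samples=2, rng_seed=11))
        haps = decode_all_haplotypes(ref, coll.chrom_table, vd, matrix)
        a = generate_query_set(haps, 15, rng_seed=12)
        b = generate_query_set(haps, 15, rng_seed=12)
        assert a == b

    def test_rejects_n_excerpts(self):
        coll, ref, vd, matrix = _setup(
            CollectionSpec(ref_len=2000, n_samples=2, n_run_rate=0.01,
                           rng_seed=13))
        haps = decode_all_haplotypes(ref, coll.chrom_table, vd, matrix)
        for _, P in generate_query_set(haps, 30, (50, 80), (0, 2),
                                       rng_seed=14):
            assert "N" not in P
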