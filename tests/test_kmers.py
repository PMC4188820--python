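import numpy as np
import pytest

from mugi.index import prepare_variants
from mugi.kmers import (IndexParams, categorize_entry, build_kmer_array,
                        enumerate_kmer_paths, replay_entry, sparsify)
from mugi.variants import Variant, VariantDatabase

from conftest import make_index


class TestEnumeration:
    def test_reference_only_counts(self):
        idx = make_index("ACGTACG", [], np.zeros((0, 2), dtype=bool))
        assert idx.subarray_sizes() == [5, 0, 0, 0]

    def test_snp_adds_three_kmers(self, toy_snp_index):
        idx = toy_snp_index
        assert idx.subarray_sizes() == [5, 3, 0, 0]
        texts = {t for t in idx.subarrays[1].texts}
        assert texts == {b"CGA", b"GAA", b"AAC"}
        starts = sorted(e.pos_ref for e in idx.subarrays[1].entries)
        assert starts == [1, 2, 3]

    def test_insertion_internal_offsets_are_category2(self):
        idx = make_index("AACGTT", [Variant("INS", 2, ins_seq="GG")],
                         [[1, 0]], k=3)
        offs = sorted((e.pos_ref, e.offset) for e in idx.subarrays[2].entries)
        assert offs == [(2, 1), (2, 2)]
        # the window starting at the first inserted character is GGC
        assert b"GGC" in idx.subarrays[2].texts

    def test_kmers_starting_with_n_dropped(self):
        idx = make_index("ANGTACG", [], np.zeros((0, 2), dtype=bool))
        assert all(not t.startswith(b"N") for t in idx.subarrays[0].texts)
        assert idx.subarray_sizes()[0] == 4  # start 1 removed

    def test_no_boundary_spanning_with_two_chromosomes(self):
        from mugi.bitvectors import OccurrenceMatrix
        from mugi.index import build_index
        from mugi.reference import Chromosome, ChromosomeTable, PackedReference
        ref = PackedReference("ACGTAAA")
        table = ChromosomeTable([Chromosome("c1", 0, 4), Chromosome("c2", 4, 3)])
        vd = VariantDatabase([])
        idx = build_index(ref, table, vd,
                          OccurrenceMatrix(np.zeros((0, 2), bool), 2),
                          IndexParams(k=3, lut_width=2))
        starts = sorted(e.pos_ref for e in idx.subarrays[0].entries)
        assert starts == [0, 1, 4]  # no window crosses position 4


class TestCategorize:
    @pytest.mark.parametrize("ev,offset,e_max,want", [
        ((), 0, 16, 0),
        (((5, 1), (6, 0), (7, 1)), 0, 16, 1),
        (((5, 1),), 1, 16, 2),
        (((5, 1), (9, 0)), 0, 16, 3),       # non-consecutive ids
        (((5, 1), (6, 1), (7, 1)), 0, 2, 3),  # more than e_max evidences
    ])
    def test_rules(self, ev, offset, e_max, want):
        assert categorize_entry(ev, offset, e_max) == want


class TestPresenceFilter:
    def test_universal_snp_drops_reference_path(self):
        idx = make_index("ACGTACG", [Variant("SNP", 3, alt_char="A")],
                         [[1, 1]])
        # occ=11: reference-path windows overlapping the SNP disappear
        assert b"GTA" not in idx.subarrays[0].texts
        assert b"GAA" in idx.subarrays[1].texts

    def test_uncarried_snp_drops_variant_path(self):
        idx = make_index("ACGTACG", [Variant("SNP", 3, alt_char="A")],
                         [[0, 0]])
        assert idx.subarray_sizes() == [5, 0, 0, 0]

    def test_every_entry_resolves_to_nonempty_haplotype_set(self, rich_index):
        from mugi.kmers import implied_evidence
        idx = rich_index
        for sub in idx.subarrays:
            for e in sub.entries:
                ev = implied_evidence(idx.vd, e.pos_ref, e.offset, e.first_vt)
                ev.update(dict(e.evidence))
                assert idx.store.resolve(ev).any()


class TestSortAndLookup:
    def test_sorted_and_reconstructible(self, rich_index):
        idx = rich_index
        for sub in idx.subarrays:
            assert sub.texts == sorted(sub.texts)
            for t, e in zip(sub.texts, sub.entries):
                chrom = idx.chrom_table.locate(e.pos_ref)
                text, _ = replay_entry(idx.ref, idx.vd, e, idx.params.k,
                                       chrom.global_start, chrom.global_end)
                assert text.encode() == t

    def test_interval_matches_linear_scan(self, rich_index):
        idx = rich_index
        for sub in idx.subarrays:
            for seed in (b"A", b"AC", b"GAA", b"TTTT", b"CG", b"G"):
                lo, hi = sub.interval(seed)
                brute = [i for i, t in enumerate(sub.texts)
                         if t[:len(seed)] == seed]
                assert list(range(lo, hi)) == brute

    def test_lut_narrows_same_interval(self, toy_snp_index):
        sub = toy_snp_index.subarrays[0]
        assert sub.lut_width == 2
        lo, hi = sub.interval(b"ACG")
        assert (lo, hi) == (0, 2)  # starts 0 and 4


class TestSparsify:
    def test_kma0_keeps_multiples(self, toy_snp_index):
        subs = sparsify(toy_snp_index.subarrays, 2, toy_snp_index.vd, 2)
        starts = sorted(e.pos_ref for e in subs[0].entries)
        assert starts == [0, 2, 4]

    def test_kma1_snp_initial_not_exempt(self, toy_snp_index):
        # kMA1 starts {1,2,3}; the SNP-initial window at 3 is not a
        # DEL/INS anchor, so only the even start survives
        subs = sparsify(toy_snp_index.subarrays, 2, toy_snp_index.vd, 2)
        assert sorted(e.pos_ref for e in subs[1].entries) == [2]

    def test_deletion_initial_windows_survive(self):
        idx = make_index("ACGTACGT", [Variant("DEL", 3, del_len=2)],
                         [[1, 0]], k=3)
        subs = sparsify(idx.subarrays, 16, idx.vd, 2)
        kept = [(e.pos_ref, e.evidence) for e in subs[1].entries]
        assert any(p == 3 and ev[0][1] == 1 for p, ev in kept)

    def test_identity_and_monotonicity(self, rich_index):
        idx = rich_index
        base = [len(s) for s in idx.subarrays]
        assert [len(s) for s in sparsify(idx.subarrays, 1, idx.vd, 2)] == base
        prev = base
        for d in (2, 3, 4, 8, 16):
            cur = [len(s) for s in sparsify(idx.subarrays, d, idx.vd, 2)]
            assert cur[2:] == base[2:]          # kMA2/kMA3 untouched
            assert cur[0] <= prev[0] or d < 3   # non-increasing overall trend
            assert cur[0] <= base[0] and cur[1] <= base[1]
            prev = cur


class TestCompleteness:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_subarrays_equal_brute_force_haplotype_kmers(self, seed):
        """Union of the four subarrays == all k-windows of all decoded
        haplotypes with their projections (dense index)."""
        from mugi.oracle import decode_all_haplotypes
        from mugi.simulate import CollectionSpec, synthesize
        from mugi.verify import build_from_collection

        k = 6
        coll = synthesize(CollectionSpec(ref_len=400, n_samples=2,
                                         snp_rate=0.03, del_rate=0.004,
                                         ins_rate=0.004, sv_rate=0.002,
                                         rng_seed=seed))
        ref = coll.reference
        vd, matrix = prepare_variants(coll.records, coll.chrom_table, ref,
                                      coll.n_haplotypes)
        haps = decode_all_haplotypes(ref, coll.chrom_table, vd, matrix)
        idx = build_from_collection(coll, IndexParams(k=k, lut_width=4))
        want = set()
        for ph in haps:
            for j in range(len(ph.text) - k + 1):
                t = ph.text[j:j + k]
                if not t.startswith("N"):
                    want.add((t, ph.chrom, int(ph.pre[j]), int(ph.off[j])))
        got = set()
        for sub in idx.subarrays:
            for t, e in zip(sub.texts, sub.entries):
                chrom = idx.chrom_table.locate(e.pos_ref)
                _, st = replay_entry(ref, vd, e, k, chrom.global_start,
                                     chrom.global_end)
                pos, off = st.start_proj
                got.add((t.decode(), chrom.name, pos - chrom.global_start, off))
        assert got == want
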