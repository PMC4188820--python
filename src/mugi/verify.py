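"""End-to-end verification harness: generate → build → query → compare with
the brute-force oracle.  Every routine is deterministic given its seed and
returns a stats dict whose ``failures`` entry is zero on success.

These routines are the package's own correctness evidence: the index answers
are compared, tuple by (chromosome, position, offset, haplotype) tuple,
against a naive sequential scan over every explicitly decoded haplotype.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .bitvectors import BitVectorStore, OccurrenceMatrix
from .index import MugiIndex, build_index, prepare_variants
from .kmers import IndexParams, replay_entry
from .oracle import (decode_all_haplotypes, equivalence_check, expand_records,
                     generate_query_set, oracle_scan)
from .search import pigeonhole_split
from .simulate import Collection, CollectionSpec, synthesize


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def build_from_collection(coll: Collection, params: IndexParams,
                          chunk_bits: int | None = None) -> MugiIndex:
    ref = coll.reference
    vd, matrix = prepare_variants(coll.records, coll.chrom_table, ref,
                                  coll.n_haplotypes)
    return build_index(ref, coll.chrom_table, vd, matrix, params,
                       sample_names=coll.samples, chunk_bits=chunk_bits)


def _setup(seed: int, ref_len, n_samples, **spec_kw):
    spec = CollectionSpec(ref_len=ref_len, n_samples=n_samples,
                          rng_seed=seed, **spec_kw)
    coll = synthesize(spec)
    ref = coll.reference
    vd, matrix = prepare_variants(coll.records, coll.chrom_table, ref,
                                  coll.n_haplotypes)
    haps = decode_all_haplotypes(ref, coll.chrom_table, vd, matrix)
    return coll, ref, vd, matrix, haps


def _find_exact(haplotypes, P: str) -> dict:
    """Fast exact-match oracle: sequential scan via str.find per sequence."""
    hits = {}
    for ph in haplotypes:
        i = ph.text.find(P)
        while i != -1:
            hits[(ph.chrom, int(ph.pre[i]), int(ph.off[i]), ph.hap)] = 0
            i = ph.text.find(P, i + 1)
    return hits


def run_exact_equivalence(n_collections: int = 50, n_queries: int = 200,
                          seed: int = 1, k: int = 25,
                          ref_len_range=(2000, 20000),
                          sample_range=(2, 32)) -> dict:
    """Exact-search answers vs the naive-scan oracle on random collections
    (SNPs ~1/100 bp, indels ~1/500, SVs ~1/2000)."""
    seeds = _child_seeds(seed, n_collections)
    rng = np.random.default_rng(seed + 1)
    stats = {"collections": n_collections, "queries": 0, "tuples": 0,
             "failures": 0, "discrepancies": []}
    for cs in seeds:
        ref_len = int(np.exp(rng.uniform(np.log(ref_len_range[0]),
                                         np.log(ref_len_range[1]))))
        n_samples = int(rng.integers(sample_range[0], sample_range[1] + 1))
        coll, ref, vd, matrix, haps = _setup(cs, ref_len, n_samples)
        index = build_from_collection(coll, IndexParams(k=k, lut_width=min(8, k)))
        queries = generate_query_set(haps, n_queries, (100, 200), (0, 2),
                                     rng_seed=cs + 1)
        for _pid, P in queries:
            got = expand_records(index.exact_search(P))
            want = _find_exact(haps, P)
            rep = equivalence_check(got, want)
            stats["queries"] += 1
            stats["tuples"] += len(want)
            if not rep.ok:
                stats["failures"] += 1
                if len(stats["discrepancies"]) < 10:
                    stats["discrepancies"].append((cs, P, str(rep)))
    return stats


def run_approx_equivalence(n_collections: int = 20, n_queries: int = 100,
                           q_values=(1, 2, 3, 4, 5), seed: int = 2,
                           k: int = 25, ref_len_range=(2000, 8000),
                           sample_range=(2, 16)) -> dict:
    """Approximate-search answers (positions, haplotypes and minimum
    mismatch counts) vs the Hamming-scan oracle for q in 1..5."""
    seeds = _child_seeds(seed, n_collections)
    rng = np.random.default_rng(seed + 1)
    q_max = max(q_values)
    stats = {"collections": n_collections, "queries": 0, "tuples": 0,
             "failures": 0, "discrepancies": []}
    for cs in seeds:
        ref_len = int(rng.integers(*ref_len_range))
        n_samples = int(rng.integers(sample_range[0], sample_range[1] + 1))
        coll, ref, vd, matrix, haps = _setup(cs, ref_len, n_samples)
        index = build_from_collection(coll, IndexParams(k=k, lut_width=min(8, k)))
        queries = generate_query_set(haps, n_queries, (100, 200), (0, q_max),
                                     rng_seed=cs + 1)
        for _pid, P in queries:
            full = oracle_scan(haps, P, q_max)
            for q in q_values:
                got = expand_records(index.approximate_search(P, q))
                want = {t: mm for t, mm in full.items() if mm <= q}
                rep = equivalence_check(got, want)
                stats["queries"] += 1
                stats["tuples"] += len(want)
                if not rep.ok:
                    stats["failures"] += 1
                    if len(stats["discrepancies"]) < 10:
                        stats["discrepancies"].append((cs, P, q, str(rep)))
    return stats


def run_sparse_dense(d_values=(2, 3, 4, 8, 16), k_values=(12, 25, 30),
                     n_collections: int = 3, n_queries: int = 40,
                     seed: int = 3, ref_len_range=(2000, 4000),
                     n_samples: int = 4, q_approx: int = 2) -> dict:
    """Sparse-index answers must equal the dense ones for every d and k."""
    seeds = _child_seeds(seed, n_collections)
    rng = np.random.default_rng(seed + 1)
    stats = {"comparisons": 0, "failures": 0, "discrepancies": []}
    for cs in seeds:
        ref_len = int(rng.integers(*ref_len_range))
        coll, ref, vd, matrix, haps = _setup(cs, ref_len, n_samples)
        queries = generate_query_set(haps, n_queries, (100, 200), (0, 2),
                                     rng_seed=cs + 1)
        for k in k_values:
            dense = build_from_collection(
                coll, IndexParams(k=k, lut_width=min(8, k)))
            answers = {}
            for pid, P in queries:
                answers[pid] = (expand_records(dense.exact_search(P)),
                                expand_records(dense.approximate_search(P, q_approx)))
            for d in d_values:
                sparse = build_from_collection(
                    coll, IndexParams(k=k, sparsity=d, lut_width=min(8, k)))
                for pid, P in queries:
                    got = (expand_records(sparse.exact_search(P)),
                           expand_records(sparse.approximate_search(P, q_approx)))
                    stats["comparisons"] += 1
                    if got != answers[pid]:
                        stats["failures"] += 1
                        if len(stats["discrepancies"]) < 10:
                            stats["discrepancies"].append((cs, k, d, P))
    return stats


def run_kmer_completeness(n_collections: int = 20, seed: int = 4, k: int = 8,
                          ref_len_range=(300, 800), n_samples: int = 2) -> dict:
    """The (k-mer text, projection) set reconstructed from the four
    subarrays equals brute-force enumeration over decoded haplotypes."""
    seeds = _child_seeds(seed, n_collections)
    rng = np.random.default_rng(seed + 1)
    stats = {"collections": n_collections, "kmers": 0, "failures": 0,
             "discrepancies": []}
    for i, cs in enumerate(seeds):
        ref_len = int(rng.integers(*ref_len_range))
        n_run = 0.005 if i % 4 == 0 else 0.0
        coll, ref, vd, matrix, haps = _setup(cs, ref_len, n_samples,
                                             n_run_rate=n_run)
        index = build_from_collection(coll, IndexParams(k=k, lut_width=4))
        want = set()
        for ph in haps:
            for j in range(len(ph.text) - k + 1):
                t = ph.text[j:j + k]
                if not t.startswith("N"):
                    want.add((t, ph.chrom, int(ph.pre[j]), int(ph.off[j])))
        got = set()
        for sub in index.subarrays:
            for text, e in zip(sub.texts, sub.entries):
                chrom = index.chrom_table.locate(e.pos_ref)
                _t, st = replay_entry(ref, vd, e, k, chrom.global_start,
                                      chrom.global_end)
                pos, off = st.start_proj
                got.add((text.decode("ascii"), chrom.name,
                         pos - chrom.global_start, off))
        stats["kmers"] += len(want)
        if got != want:
            stats["failures"] += 1
            if len(stats["discrepancies"]) < 5:
                stats["discrepancies"].append(
                    (cs, sorted(want - got)[:5], sorted(got - want)[:5]))
    return stats


def run_bitvector_roundtrip(seed: int = 5, chunk_widths=(8, 64, 192, 256),
                            n_variants: int = 10_000, n_haplotypes: int = 500,
                            n_resolve: int = 10_000) -> dict:
    """Lossless chunk-dictionary compression and evidence resolution against
    a per-haplotype brute-force check."""
    rng = np.random.default_rng(seed)
    stats = {"roundtrip_failures": 0, "resolve_failures": 0, "failures": 0,
             "checked": 0}
    for cb in chunk_widths:
        rows = rng.random((n_variants, n_haplotypes)) < 0.2
        m = OccurrenceMatrix(rows, n_haplotypes)
        store = BitVectorStore(m, cb)
        if not np.array_equal(store.decompress().rows, rows):
            stats["roundtrip_failures"] += 1
        stats["checked"] += n_variants
    rows = rng.random((2000, 32)) < 0.3
    m = OccurrenceMatrix(rows, 32)
    store = BitVectorStore(m, 64)
    for _ in range(n_resolve):
        n_ev = int(rng.integers(0, 7))
        ids = rng.choice(2000, size=n_ev, replace=False)
        flags = rng.integers(0, 2, size=n_ev)
        got = store.resolve_haplotypes(list(ids), list(flags))
        want = np.array([all(rows[v, h] == bool(f)
                             for v, f in zip(ids, flags))
                         for h in range(32)])
        if not np.array_equal(got, want):
            stats["resolve_failures"] += 1
        stats["checked"] += 1
    stats["failures"] = stats["roundtrip_failures"] + stats["resolve_failures"]
    return stats


def run_pigeonhole(n_patterns: int = 10_000, seed: int = 6) -> dict:
    """With exactly q planted substitutions, at least one of the q+1
    segments is error-free."""
    rng = np.random.default_rng(seed)
    stats = {"patterns": n_patterns, "failures": 0}
    for _ in range(n_patterns):
        q = int(rng.integers(1, 6))
        m = int(rng.integers(6 * (q + 1), 201))
        err = set(int(x) for x in rng.choice(m, size=q, replace=False))
        segments = pigeonhole_split(m, q)
        clean = any(not any(s <= e < s + ln for e in err)
                    for s, ln in segments)
        if not clean:
            stats["failures"] += 1
    return stats


def run_emax_invariance(e_values=(1, 4, 16), n_collections: int = 3,
                        n_queries: int = 40, seed: int = 7, k: int = 20,
                        ref_len_range=(2000, 4000), n_samples: int = 4) -> dict:
    """Categorization thresholds must not change query answers."""
    seeds = _child_seeds(seed, n_collections)
    rng = np.random.default_rng(seed + 1)
    stats = {"comparisons": 0, "failures": 0}
    for cs in seeds:
        ref_len = int(rng.integers(*ref_len_range))
        coll, ref, vd, matrix, haps = _setup(cs, ref_len, n_samples)
        queries = generate_query_set(haps, n_queries, (100, 200), (0, 2),
                                     rng_seed=cs + 1)
        baseline = None
        for e_max in e_values:
            index = build_from_collection(
                coll, IndexParams(k=k, e_max=e_max, lut_width=8))
            answers = {pid: (expand_records(index.exact_search(P)),
                             expand_records(index.approximate_search(P, 2)))
                       for pid, P in queries}
            if baseline is None:
                baseline = answers
            else:
                stats["comparisons"] += len(queries)
                if answers != baseline:
                    stats["failures"] += 1
    return stats


def run_serialization(tmpdir, n_collections: int = 2, n_queries: int = 100,
                      seed: int = 8, k: int = 20) -> dict:
    """Save/load round trip leaves every query answer unchanged."""
    import os
    seeds = _child_seeds(seed, n_collections)
    rng = np.random.default_rng(seed + 1)
    stats = {"queries": 0, "failures": 0}
    for i, cs in enumerate(seeds):
        ref_len = int(rng.integers(2000, 5000))
        coll, ref, vd, matrix, haps = _setup(cs, ref_len, 4)
        for d in (1, 3):
            index = build_from_collection(
                coll, IndexParams(k=k, sparsity=d, lut_width=8))
            from .formats import load_index, save_index
            path = os.path.join(str(tmpdir), f"idx_{i}_{d}.mugi")
            save_index(index, path)
            loaded = load_index(path)
            queries = generate_query_set(haps, n_queries, (100, 200), (0, 2),
                                         rng_seed=cs + 2)
            for _pid, P in queries:
                a = [(r.key(), r.mismatches, r.haplotypes.tobytes())
                     for r in index.approximate_search(P, 1)]
                b = [(r.key(), r.mismatches, r.haplotypes.tobytes())
                     for r in loaded.approximate_search(P, 1)]
                stats["queries"] += 1
                if a != b:
                    stats["failures"] += 1
    return stats


def run_determinism(tmpdir, seed: int = 9) -> dict:
    """Fixed seed reproduces collections, indexes and reports byte for
    byte."""
    import os

    from .formats import save_index, write_matches
    from .simulate import generate_collection, write_patterns_txt

    def one_round(tag):
        spec = CollectionSpec(ref_len=3000, n_samples=4, rng_seed=seed)
        fa = os.path.join(str(tmpdir), f"{tag}.fa")
        vcf = os.path.join(str(tmpdir), f"{tag}.vcf")
        coll = generate_collection(spec, fa, vcf)
        ref = coll.reference
        vd, matrix = prepare_variants(coll.records, coll.chrom_table, ref,
                                      coll.n_haplotypes)
        haps = decode_all_haplotypes(ref, coll.chrom_table, vd, matrix)
        index = build_from_collection(coll, IndexParams(k=20, lut_width=8))
        idx_path = os.path.join(str(tmpdir), f"{tag}.mugi")
        save_index(index, idx_path)
        queries = generate_query_set(haps, 50, (100, 200), (0, 2),
                                     rng_seed=seed + 1)
        qpath = os.path.join(str(tmpdir), f"{tag}.txt")
        write_patterns_txt(queries, qpath)
        rpath = os.path.join(str(tmpdir), f"{tag}.tsv")
        write_matches(((pid, index.approximate_search(P, 1))
                       for pid, P in queries), rpath, index)
        digests = []
        for p in (fa, vcf, idx_path, qpath, rpath):
            with open(p, "rb") as fh:
                digests.append(hashlib.sha256(fh.read()).hexdigest())
        return digests

    a = one_round("run1")
    b = one_round("run2")
    return {"files": len(a), "failures": sum(x != y for x, y in zip(a, b))}
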