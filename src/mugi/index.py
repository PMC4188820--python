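"""The assembled index: reference, variant database, haplotype bit vectors
and the four k-mer subarrays, plus the build pipeline."""

from __future__ import annotations

from dataclasses import dataclass

from .bitvectors import BitVectorStore, OccurrenceMatrix, build_occurrence_matrix
from .kmers import IndexParams, build_kmer_array, enumerate_kmer_paths, sparsify
from .reference import ChromosomeTable, PackedReference
from .variants import VariantDatabase, normalize_variant
from . import search as _search


def prepare_variants(records, chrom_table: ChromosomeTable,
                     ref: PackedReference, n_haplotypes: int | None = None
                     ) -> tuple[VariantDatabase, OccurrenceMatrix]:
    """Normalize VCF records (splitting multiallelic ones) into the variant
    database and fold the phased GT columns into the occurrence matrix."""
    all_variants = []
    per_record_input = []
    n_hap = n_haplotypes
    for rec in records:
        chrom = chrom_table.by_name(rec.chrom)
        vs = normalize_variant(chrom.global_start, rec.pos, rec.ref_allele,
                               rec.alt_alleles, reference=ref)
        per_record_input.append(list(range(len(all_variants),
                                           len(all_variants) + len(vs))))
        all_variants.extend(vs)
        if n_hap is None:
            n_hap = len(rec.alleles_per_hap)
    vd = VariantDatabase(all_variants)
    per_record_ids = [[int(vd.input_to_id[i]) for i in ids]
                      for ids in per_record_input]
    matrix = build_occurrence_matrix(
        (rec.alleles_per_hap for rec in records), per_record_ids,
        len(vd), n_hap or 0)
    return vd, matrix


@dataclass
class MugiIndex:
    ref: PackedReference
    chrom_table: ChromosomeTable
    vd: VariantDatabase
    store: BitVectorStore
    subarrays: list
    params: IndexParams
    sample_names: list[str]

    @property
    def n_haplotypes(self) -> int:
        return self.store.n_haplotypes

    def haplotype_name(self, h: int) -> str:
        return f"{self.sample_names[h // 2]}_{h % 2 + 1}"

    def exact_search(self, pattern: str, min_seed_len: int = 8):
        return _search.exact_search(self, pattern, min_seed_len)

    def approximate_search(self, pattern: str, q: int, min_seed_len: int = 8):
        return _search.approximate_search(self, pattern, q, min_seed_len)

    def subarray_sizes(self) -> list[int]:
        return [len(s) for s in self.subarrays]


def build_index(ref: PackedReference, chrom_table: ChromosomeTable,
                vd: VariantDatabase, matrix: OccurrenceMatrix,
                params: IndexParams, sample_names=None,
                chunk_bits: int | None = None) -> MugiIndex:
    """Build the full index from parsed inputs.

    The occurrence matrix is chunk-dictionary compressed; k-mer candidates
    are enumerated over all variant paths, presence-filtered against the bit
    vectors, categorized, sorted and (optionally) sparsified.
    """
    from .bitvectors import DEFAULT_CHUNK_BITS
    store = BitVectorStore(matrix, chunk_bits or DEFAULT_CHUNK_BITS)
    cands = enumerate_kmer_paths(ref, chrom_table, vd, params)
    subs = build_kmer_array(cands, params, store=store, vd=vd)
    lut_w = min(params.lut_width, params.k)
    subs = sparsify(subs, params.sparsity, vd, lut_w)
    if sample_names is None:
        sample_names = [f"S{i}" for i in range(store.n_haplotypes // 2)]
    return MugiIndex(ref, chrom_table, vd, store, subs, params,
                     list(sample_names))
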