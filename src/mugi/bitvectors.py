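"""Per-variant haplotype occurrence bit vectors with chunk-dictionary
compression, and folding of evidence lists into result haplotype sets.

One bit vector per variant, one bit per haploid genome (two per phased
diploid sample).  Spatially close variant configurations recur across
individuals, so rows are cut into fixed-width chunks and each distinct chunk
pattern is stored once in a vocabulary; a row is then a short sequence of
vocabulary tokens.
"""

from __future__ import annotations

import numpy as np

DEFAULT_CHUNK_BITS = 192


class OccurrenceMatrix:
    """Dense bool matrix, rows = variants, columns = haploid genomes."""

    def __init__(self, rows: np.ndarray, n_haplotypes: int):
        rows = np.asarray(rows, dtype=bool)
        if rows.ndim != 2 or rows.shape[1] != n_haplotypes:
            raise ValueError("occurrence matrix shape mismatch")
        self.rows = rows
        self.n_haplotypes = n_haplotypes

    @property
    def n_variants(self) -> int:
        return self.rows.shape[0]


def build_occurrence_matrix(gt_rows, per_alt_variant_ids, n_variants: int,
                            n_haplotypes: int) -> OccurrenceMatrix:
    """Fold phased GT columns into the occurrence matrix.

    ``gt_rows`` iterates, per VCF record, the flat per-haplotype allele
    indices (sample 0 left, sample 0 right, sample 1 left, ...);
    ``per_alt_variant_ids`` gives, per record, the VD id created for each ALT
    allele (index 0 -> allele value 1, etc.).
    """
    rows = np.zeros((n_variants, n_haplotypes), dtype=bool)
    for alleles, vids in zip(gt_rows, per_alt_variant_ids):
        if len(alleles) != n_haplotypes:
            raise ValueError("GT column count does not match haplotype count")
        for h, a in enumerate(alleles):
            if a == 0:
                continue
            if a < 0 or a > len(vids):
                raise ValueError(
                    f"GT allele index {a} exceeds ALT count {len(vids)}")
            rows[vids[a - 1], h] = True
    return OccurrenceMatrix(rows, n_haplotypes)


class BitVectorStore:
    """Chunk-dictionary compressed occurrence matrix (the BV structure)."""

    def __init__(self, matrix: OccurrenceMatrix,
                 chunk_bits: int = DEFAULT_CHUNK_BITS):
        if chunk_bits < 1:
            raise ValueError("chunk_bits must be >= 1")
        self.n_haplotypes = matrix.n_haplotypes
        self.n_variants = matrix.n_variants
        self.chunk_bits = chunk_bits
        n_chunks = -(-matrix.n_haplotypes // chunk_bits)
        if matrix.n_variants and n_chunks:
            padded = np.zeros((matrix.n_variants, n_chunks * chunk_bits), dtype=bool)
            padded[:, :matrix.n_haplotypes] = matrix.rows
            chunks = padded.reshape(matrix.n_variants * n_chunks, chunk_bits)
            packed = np.packbits(chunks, axis=1)
            vocab, tokens = np.unique(packed, axis=0, return_inverse=True)
            self.vocabulary = vocab  # (V, ceil(chunk_bits/8)) uint8
            self.tokens = tokens.reshape(matrix.n_variants, n_chunks).astype(np.uint32)
        else:
            self.vocabulary = np.zeros((0, -(-chunk_bits // 8)), dtype=np.uint8)
            self.tokens = np.zeros((matrix.n_variants, 0), dtype=np.uint32)
        self.n_chunks = n_chunks

    @classmethod
    def from_parts(cls, vocabulary, tokens, n_haplotypes, chunk_bits):
        obj = cls.__new__(cls)
        obj.vocabulary = np.asarray(vocabulary, dtype=np.uint8)
        obj.tokens = np.asarray(tokens, dtype=np.uint32)
        obj.n_haplotypes = int(n_haplotypes)
        obj.chunk_bits = int(chunk_bits)
        obj.n_variants = obj.tokens.shape[0]
        obj.n_chunks = obj.tokens.shape[1]
        return obj

    @property
    def vocabulary_size(self) -> int:
        return len(self.vocabulary)

    def variant_vector(self, variant_id: int) -> np.ndarray:
        """Decompress one row back to a bool vector of n_haplotypes bits."""
        if not 0 <= variant_id < self.n_variants:
            raise IndexError(f"variant id {variant_id} out of range")
        toks = self.tokens[variant_id]
        bits = np.unpackbits(self.vocabulary[toks], axis=1)[:, :self.chunk_bits]
        return bits.reshape(-1)[:self.n_haplotypes].astype(bool)

    def decompress(self) -> OccurrenceMatrix:
        rows = np.empty((self.n_variants, self.n_haplotypes), dtype=bool)
        for v in range(self.n_variants):
            rows[v] = self.variant_vector(v)
        return OccurrenceMatrix(rows, self.n_haplotypes)

    def resolve_haplotypes(self, vt_list, ev_list) -> np.ndarray:
        """Fold an evidence list into the R vector: start from all ones, AND
        each flagged variant's vector (complemented for flag 0).  Empty
        evidence means the sequence is present in every haploid genome."""
        r = np.ones(self.n_haplotypes, dtype=bool)
        seen: dict[int, int] = {}
        for vid, flag in zip(vt_list, ev_list):
            if vid in seen and seen[vid] != flag:
                return np.zeros(self.n_haplotypes, dtype=bool)
            seen[vid] = flag
            row = self.variant_vector(vid)
            r &= row if flag else ~row
            if not r.any():
                return r
        return r

    def resolve(self, evidence: dict[int, int]) -> np.ndarray:
        return self.resolve_haplotypes(list(evidence.keys()),
                                       list(evidence.values()))
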