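import numpy as np
import pytest

from mugi.bitvectors import OccurrenceMatrix
from mugi.index import build_index
from mugi.kmers import IndexParams
from mugi.reference import Chromosome, ChromosomeTable, PackedReference
from mugi.variants import Variant, VariantDatabase


def make_index(ref_seq, variants, occ_rows, k=3, sparsity=1, e_max=16,
               lut_width=2, chunk_bits=8, chrom_name="chr1"):
    """Build a toy single-chromosome index from explicit pieces."""
    ref = PackedReference(ref_seq)
    table = ChromosomeTable([Chromosome(chrom_name, 0, len(ref_seq))])
    vd = VariantDatabase(list(variants))
    occ = np.array(occ_rows, dtype=bool)
    if occ.size == 0:
        occ = occ.reshape(0, 2)
    matrix = OccurrenceMatrix(occ, occ.shape[1])
    params = IndexParams(k=k, sparsity=sparsity, e_max=e_max,
                         lut_width=lut_width)
    return build_index(ref, table, vd, matrix, params, chunk_bits=chunk_bits)


@pytest.fixture
def toy_snp_index():
    """Reference ACGTACG with one SNP T->A at position 3, carried by the
    first of two haplotypes (the running example: haplotypes ACGAACG and
    ACGTACG)."""
    return make_index("ACGTACG", [Variant("SNP", 3, alt_char="A")],
                      [[True, False]])


@pytest.fixture
def rich_index():
    """A small index exercising all four variant kinds."""
    #            0123456789012345678901234
    ref_seq = "ACGTACGTTAGCAGGATCCATTGCA"
    variants = [
        Variant("SNP", 3, alt_char="A"),
        Variant("DEL", 6, del_len=2),
        Variant("INS", 10, ins_seq="GG"),
        Variant("SV", 14, del_len=3, ins_seq="T"),
    ]
    occ = [[1, 0, 1, 0],
           [0, 1, 0, 0],
           [1, 1, 0, 0],
           [0, 0, 1, 1]]
    return make_index(ref_seq, variants, occ, k=4, lut_width=2)


def expand(records):
    out = {}
    for r in records:
        for h in np.flatnonzero(r.haplotypes):
            key = (r.chrom, r.pre, r.offset, int(h))
            if key not in out or r.mismatches < out[key]:
                out[key] = r.mismatches
    return out
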