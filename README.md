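# mugi — Multiple Genome Index

`mugi` indexes a *collection* of genomes represented the way variation
repositories actually store them: one reference genome (FASTA) plus a variant
database with phased genotypes (VCF).  A phased diploid sample contributes
two independent haploid genomes; the index answers **locate queries** over
all of them at once — every occurrence of a pattern, exact or with up to *q*
mismatches, reported as a reference position together with the exact set of
haploid genomes whose sequence contains that occurrence.

This matters when you want to align reads or probe oligos against *a
population*, not a single reference: a read spanning a SNP, indel or
structural variant matches some individuals and not others, and `mugi` tells
you which.

## The method

**Index.** The reference is stored 4 bits/base.  Variants (SNP, DEL, INS,
SV = deletion+insertion) are kept sorted by position with an inverse-deletion
list for leftward decoding.  Per-variant haplotype membership is a bit
vector, compressed through a dictionary of unique fixed-width bit chunks
(default 192 bits) — nearby variants share carrier patterns, so the
dictionary is small.  The core structure is the **k-mer array (kMA)**: every
k-length window occurring in *any* haplotype, enumerated by walking all
variant paths through the reference.  A window is stored not as text but as
a decoding recipe — reference start, optional offset inside an inserted
string, and an **evidence list** of (variant, present/absent) flags — and
kept only if at least one haploid genome carries exactly that combination.
Entries are split into four lexicographically sorted subarrays (reference-
only / consecutive evidence / insertion-internal / general) with a prefix
lookup table over the first 12 characters.

**Search.** Seed-and-extend: the pattern prefix of length min(|P|, k) is
binary-searched in all four subarrays; each hit is partially decoded and
extended right along every consistent variant path.  At the pattern end an
R vector is resolved: start from all-ones and AND each flagged variant's bit
vector (complemented for absent flags) — the surviving bits are the haploid
genomes containing the match.  With *q* mismatches the pattern is split into
q+1 disjoint segments (pigeonhole: one is error-free), each segment is
located exactly and extended bidirectionally under a shared mismatch budget.
A space-efficient mode keeps only kMA⁰/kMA¹ entries whose start is a
multiple of a sparsity *d* (plus every window beginning with a present
deletion/insertion), recovering the missed occurrences by searching *d*
shifted seeds and decoding leftward.

## Worked example

```bash
mugi simulate --ref-len 3000 --samples 4 --seed 5 --queries 10 --out-prefix demo
mugi build --ref demo.fa --vcf demo.vcf --k 20 --lut 8 --out demo.mugi
mugi query --index demo.mugi --patterns demo.patterns.txt -q 1 --out demo.tsv
```

The build step logs the index composition:

```
INFO kMA0 entries: 2981
INFO kMA1 entries: 651
INFO kMA2 entries: 8
INFO kMA3 entries: 0
INFO BV vocabulary size: 28
```

2981 windows equal the plain reference, 651 need a short run of variant
evidence, 8 start inside inserted sequence, and the 31 variant records'
carrier vectors compress to 28 dictionary chunks.  The report
(`demo.tsv`) has one row per matched path:

```
pattern_id  chrom  preceding_pos  insertion_offset  mismatches  haplotype_count  haplotype_ids
3           chr1   1781           0                 0           8                S0_1,S0_2,S1_1,S1_2,S2_1,S2_2,S3_1,S3_2
8           chr1   2501           0                 1           5                S0_1,S1_1,S1_2,S2_1,S3_2
```

Pattern 3 occurs exactly, 1781 reference characters into chr1, in all eight
haploid genomes (no variant touches it).  Pattern 8 matches with one
mismatch only in the five haplotypes carrying its particular variant
combination.  `preceding_pos` is the 1-based position of the last reference
character before the match (0 for a match at the chromosome start);
`insertion_offset` > 0 marks matches beginning inside an inserted string.

The same pipeline is available as a library:

```python
from mugi import IndexParams, build_index, prepare_variants
from mugi.formats import read_fasta, read_vcf_min

ref, table = read_fasta("demo.fa")
vcf = read_vcf_min("demo.vcf", table)
vd, occ = prepare_variants(vcf.records, table, ref, 2 * len(vcf.samples))
index = build_index(ref, table, vd, occ, IndexParams(k=20, lut_width=8),
                    sample_names=vcf.samples)
for rec in index.approximate_search("ACGT" * 30, q=2):
    print(rec.chrom, rec.pre, rec.mismatches, rec.haplotypes.sum())
```

`mugi selftest` runs the whole generate → build → query → naive-scan-oracle
loop and exits non-zero on any discrepancy.

## Limitations

- Mismatches only; edit-distance (indel) errors in the *pattern* are not
  supported (indels in the collection are, of course, part of the model).
- Patterns shorter than k cannot be located within the last k−1 positions
  of a chromosome (windows there are not enumerated).
- With sparsity d, approximate search needs pigeonhole segments of length
  ≥ d (i.e. |P| ≥ d·(q+1)); the library warns when this is violated.
- Genotypes must be phased and diploid; missing calls are rejected.

See `docs/methods.md` for the full model description and design rationale.
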