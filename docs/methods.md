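# Methods

## Data model

A collection of haploid genomes is represented as a reference sequence
(FASTA, one or more chromosomes, concatenated internally into a single
0-based global coordinate space) plus a variant database derived from a VCF
with phased diploid genotypes.  Only CHROM/POS/REF/ALT/GT are used; sample
*s* contributes haplotypes 2s (left allele) and 2s+1 (right allele).

Variants are normalized per ALT allele (multiallelic records are split) and
classified by their trimmed alleles:

| kind | meaning | effect_pos | fields |
|------|---------|-----------|--------|
| SNP | substitute one base | the substituted base | alt_char |
| DEL | delete `del_len` bases | first deleted base | del_len |
| INS | insert `ins_seq` | base *before which* insertion occurs | ins_seq |
| SV  | delete `del_len`, insert `ins_seq` | first deleted base | both |

`effect_pos` (the first affected character) is the internal coordinate;
reports convert to the VCF-style 1-based "preceding position", which equals
the 0-based local index of the match's first character.  Same-length
multi-base replacements (MNPs) are not one of the four classes and are
rejected; callers must pre-normalize.

A *path* is a choice of present/absent for each variant met while decoding
left to right, with the mechanics of the extension algorithm: a variant at
the cursor is introduced (emit its characters, advance the cursor) or
skipped; a variant inside an already-deleted region is silently irrelevant
unless it deletes beyond the previous deletion.  Variants are processed in
(effect_pos, input order) — this total order *defines* the decode semantics
for pathological overlaps, and the same order is used by the index, the
search and the oracle.

## Index construction

* **REF** — 4 bits per base (A,C,G,T,N), two bases per byte.
* **VD** — variants sorted by (effect_pos, id), with a coarse
  position→index lookup (bucket width 64) and **VD-invDel**, the list of
  DEL/SV entries sorted by resulting position (effect_pos + del_len), used
  to decode leftward and to find deletions spanning a given position (the
  scan window is bounded by the maximum deletion length).
* **BV** — one bit vector per variant over the haploid genomes, cut into
  fixed-width chunks (default 192 bits, configurable; tests exercise
  8–256).  Unique chunk patterns form a vocabulary; each row becomes
  ⌈n_hap/chunk_bits⌉ tokens.  Compression is exactly lossless; complements
  are computed on the fly during resolution.
* **kMA** — for every reference start, a depth-first walk enumerates every
  variant path over the next k characters, recording the evidence list
  (variant id, present flag).  Additional windows start at every internal
  offset of each insertion.  Windows never span chromosome boundaries;
  windows whose first character is N are dropped; a window is kept only if
  at least one haploid genome carries exactly its flagged combination
  (checked against BV, including the implied absent flags below).  Entries
  are deduplicated, sorted by window text, and split into kMA⁰ (no
  evidence), kMA¹ (≤ E_max consecutive evidences, on-reference start),
  kMA² (insertion-internal start) and kMA³ (everything else).  Each
  subarray gets a prefix lookup table (default width 12, A/C/G/T prefixes
  only; N-containing prefixes fall back to plain binary search).

Two kinds of evidence are *implied* by an entry's coordinates and therefore
recomputed at query time rather than stored: deletions spanning the window
start are necessarily absent, and for an insertion-internal window the
smaller-id consuming variants at the same anchor are necessarily absent.
The all-absent (pure reference) path is stored as a category-0 entry with
no evidence; its zero flags are reconstructed during decoding.  At a window
start, an insertion anchored exactly there is *not* flagged: its characters
precede the window, so both carriers and non-carriers contain the window.
(The flag appears as soon as left-adjacency is claimed — see leftward
extension.)  An SV or DEL anchored at the start deletes the start character
and is flagged absent on the reference path; the present-DEL branch yields
an entry whose first character sits at the deletion's resulting position,
which is also the position such a match reports.

**E_max** (default 16) only routes entries between kMA¹/kMA² and kMA³;
an invariance check (E_max ∈ {1,4,16}) confirms answers never change.

**Sparsification** (sparsity d): kMA⁰ and kMA¹ keep entries whose start is
a multiple of d; kMA¹ additionally keeps every window beginning with a
present DEL/INS/SV anchored at its start.  That exception is what makes
shifted-seed search complete across deletion jumps: within the first d
window starts of any occurrence there is either a multiple of d, an
insertion-internal start (kMA², never sparsified), or a deletion-anchored
window.  kMA²/kMA³ are never sparsified; d = 1 is the identity.

## Search

Exact: seed = first min(|P|, k) characters, binary search (narrowed by the
lookup table) in all four subarrays, partial decode of each hit (no
character comparisons — the seed is known to match), then recursive
rightward extension over all paths, comparing characters and collecting
evidence.  At the pattern end, R = all-ones ANDed with each flagged
variant's bit vector (complement for 0); R = 0 discards the path.  With a
sparse index, seeds P[j..] for j = 1..d−1 are also searched and each hit is
decoded *leftward* j characters.

The leftward walk mirrors the forward decode exactly (decreasing id order,
an id ceiling tracking which variants at the current boundary may still
contribute): insertions anchored at the boundary, then deletions ending at
it (jumping to their anchor, forcing absent flags for anything deleting
beyond the boundary from inside the jump and for smaller-id consuming
variants at the anchor), then the previous reference character or a SNP
alternative.  Decisions already recorded by the seed or rightward extension
are honoured, never re-branched, so a dense search and a shifted sparse
search of the same occurrence produce identical evidence — and therefore
identical reports.

Approximate (q mismatches): the pattern is split into q+1 disjoint segments
of length ⌊m/(q+1)⌋ (the remainder tail belongs to no segment but is still
checked during extension).  Each segment is located exactly — seeds never
extend beyond their segment, which is what the pigeonhole guarantee covers —
and extended both ways under a shared budget.  Substitutions only: a
pattern character mismatching a reference, alternative or inserted
character costs 1; path insertions/deletions are alternative exact paths,
not errors.  `N` (in pattern or collection) never matches anything.
Results from all segments and shifts are merged by the canonical key
(chromosome, preceding position, insertion offset, sorted evidence),
keeping the minimum mismatch count.

Guard rails: queries with seeds shorter than a configurable minimum
(default 8) are refused — short seeds hit huge subarray intervals; a
recursion-node cap (default 10⁴ per seed) aborts pathological extensions;
a path cap (default 2²⁰ per start) aborts pathological enumeration.

## Synthetic collections and the oracle

The generator draws a uniform A/C/G/T reference (optional short N runs),
then variant sites at user rates — defaults SNP 1/100 bp, DEL and INS
1/1000 bp each (indels 1/500 combined), SV 1/2000 bp, indel lengths ≤ 8,
SV lengths ≤ 12 — with unique effect positions (except multiallelic SNP
records, ~10%).  Carrier frequency per allele comes from a Beta(0.6, 3)
(most variants rare, exercising chunk sharing; a uniform option exists),
conditioned on at least one carrier.  A per-haplotype pass clears any
carried variant starting strictly inside another carried deletion, so each
haplotype is one unambiguous path; deletion spans still overlap other
variants' sites *across* haplotypes, which exercises evidence pruning.
Same seed, same bytes — FASTA and VCF output is reproducible.

Queries are mutated excerpts: uniform haplotype, start, and length
(default 100–200 bp), with e substitutions (e uniform in 0..5 by default,
each to a different base); N-containing excerpts are redrawn.

The oracle never touches the index machinery: each haplotype is built by
direct application of its carried variants, each character annotated with
its projection (reference position, insertion offset), and every window of
every sequence is scored by Hamming distance (plain `str.find` for the
exact case).  Equivalence is set equality of
(chromosome, position, offset, haplotype) → minimum-mismatch maps.

What passing does *not* show: the generator has no mutation spectrum, no
linkage structure, no sequencing-error profiles, and it forbids
same-position and nested-carried variants, so conflict handling for such
VCFs beyond the decode-order semantics above is untested against real data.

## Verification problem sizes

The shipped checks use: 50 collections (2–20 kb, 4–64 haplotypes) × 200
queries for exact equivalence; 20 collections (2–8 kb, 4–32 haplotypes) ×
100 queries × q ∈ {1..5} for approximate; d ∈ {2,3,4,8,16} × k ∈ {12,25,30}
for sparse/dense; 20 toy collections at k = 8 for completeness; a
10,000 × 500 matrix and 10,000 evidence lists for the bit-vector store;
10,000 planted-error patterns for pigeonhole soundness.  These sizes keep a
full verification run in the low minutes on one core while covering every
variant kind, chromosome edges, N handling and all four subarrays.

## Known limitations

- Patterns shorter than k are found via prefix intervals but cannot be
  located at the last k−1 positions of a chromosome (only full k-windows
  are enumerated; all verification queries use |P| ≥ k).
- Sparse approximate search requires segments of length ≥ d
  (|P| ≥ d·(q+1)); the library warns otherwise.
- Evidence semantics for co-carried overlapping variants follow the
  decode order strictly; genuinely contradictory VCFs resolve to R = 0
  rather than an error.
- The index container is versioned and checksummed but makes no attempt at
  byte-compatibility with any other tool's format; window texts are
  re-derived from the decoding recipes on load.
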