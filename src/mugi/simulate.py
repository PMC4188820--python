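"""Synthetic collections: random reference, random SNP/DEL/INS/SV variants
with phased occurrence matrices, written as standard FASTA + VCF.

The generator keeps every haplotype a single unambiguous variant path: no
two variants share an effect position (except the ALT alleles of one
multiallelic record, which a phased genotype can never co-carry), and no
haplotype carries a variant starting strictly inside another carried
deletion.  Deletion spans may still cover other variants' positions across
haplotypes, which exercises the index's evidence pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import RawVcfRecord
from .reference import Chromosome, ChromosomeTable, PackedReference
from .variants import DEL, INS, SNP, SV

_BASES = "ACGT"


@dataclass
class CollectionSpec:
    ref_len: int = 10_000
    n_chromosomes: int = 1
    n_samples: int = 8
    snp_rate: float = 0.01      # expected variants per base
    del_rate: float = 0.001
    ins_rate: float = 0.001
    sv_rate: float = 0.0005
    max_indel_len: int = 8
    max_sv_len: int = 12
    multiallelic_frac: float = 0.1
    allele_freq: tuple = ("beta", 0.6, 3.0)  # or ("uniform", lo, hi)
    n_run_rate: float = 0.0     # expected N runs per base
    rng_seed: int = 0

    def __post_init__(self):
        if self.ref_len < 1 or self.n_samples < 1 or self.n_chromosomes < 1:
            raise ValueError("lengths and counts must be positive")
        for r in (self.snp_rate, self.del_rate, self.ins_rate, self.sv_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")


@dataclass
class Collection:
    """In-memory synthetic collection (also writable as FASTA + VCF)."""
    spec: CollectionSpec
    sequences: dict            # chrom name -> str
    chrom_table: ChromosomeTable
    records: list              # RawVcfRecord, sorted
    samples: list

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.samples)

    @property
    def reference(self) -> PackedReference:
        return PackedReference("".join(self.sequences.values()))


def _random_seq(rng, n, n_run_rate=0.0):
    seq = rng.integers(0, 4, n)
    chars = np.frombuffer(b"ACGT", dtype=np.uint8)[seq]
    if n_run_rate > 0:
        n_runs = rng.binomial(n, n_run_rate)
        for _ in range(n_runs):
            start = int(rng.integers(0, n))
            length = int(rng.integers(1, 6))
            chars[start:start + length] = ord("N")
    return chars.tobytes().decode("ascii")


def _draw_freq(rng, how):
    if how[0] == "beta":
        return float(np.clip(rng.beta(how[1], how[2]), 0.02, 0.98))
    return float(rng.uniform(how[1], how[2]))


def synthesize(spec: CollectionSpec) -> Collection:
    """Deterministic in-memory collection for a given spec + seed."""
    rng = np.random.default_rng(spec.rng_seed)
    sequences = {}
    chroms = []
    offset = 0
    records = []
    samples = [f"S{i}" for i in range(spec.n_samples)]
    n_hap = 2 * spec.n_samples
    for ci in range(spec.n_chromosomes):
        name = f"chr{ci + 1}"
        L = spec.ref_len
        seq = _random_seq(rng, L, spec.n_run_rate)
        sequences[name] = seq
        chroms.append(Chromosome(name, offset, L))
        offset += L

        # --- draw variant sites with unique effect positions -----------
        taken = set()
        site_list = []  # (eff_local, kind, del_len, ins_len)

        def reserve(eff):
            if eff in taken:
                return False
            taken.add(eff)
            return True

        for kind, rate in ((SNP, spec.snp_rate), (DEL, spec.del_rate),
                           (INS, spec.ins_rate), (SV, spec.sv_rate)):
            count = rng.binomial(L, rate)
            tries = 0
            placed = 0
            while placed < count and tries < 20 * count + 100:
                tries += 1
                if kind == SNP:
                    eff = int(rng.integers(0, L))
                    dl, il = 0, 0
                elif kind == DEL:
                    dl = int(rng.integers(1, spec.max_indel_len + 1))
                    if L - dl < 1:
                        break
                    eff = int(rng.integers(1, L - dl + 1))
                    il = 0
                elif kind == INS:
                    dl = 0
                    il = int(rng.integers(1, spec.max_indel_len + 1))
                    eff = int(rng.integers(1, L))
                else:
                    dl = int(rng.integers(1, spec.max_sv_len + 1))
                    if L - dl < 1:
                        break
                    eff = int(rng.integers(1, L - dl + 1))
                    il = int(rng.integers(1, spec.max_sv_len + 1))
                    if il == dl:  # same-length replacement is not an SV
                        il = il + 1 if il < spec.max_sv_len else il - 1
                    if il < 1:
                        continue
                if reserve(eff):
                    site_list.append((eff, kind, dl, il))
                    placed += 1
            if placed < count:
                raise RuntimeError(
                    "variant placement failed: rates too high for the "
                    "reference length")
        site_list.sort()

        # --- materialize alleles and phased genotypes ------------------
        chrom_records = []
        for eff, kind, dl, il in site_list:
            if kind == SNP:
                ref_char = seq[eff]
                if ref_char == "N":
                    continue
                others = [b for b in _BASES if b != ref_char]
                n_alt = 2 if rng.random() < spec.multiallelic_frac else 1
                alts = list(rng.choice(others, size=n_alt, replace=False))
                pos1 = eff + 1
                ref_allele = ref_char
            else:
                anchor = seq[eff - 1]
                if anchor == "N" or "N" in seq[eff:eff + dl]:
                    continue
                pos1 = eff  # 1-based position of the anchor (0-based eff-1)
                if kind == DEL:
                    ref_allele, alts = anchor + seq[eff:eff + dl], [anchor]
                elif kind == INS:
                    ins = _random_seq(rng, il)
                    ref_allele, alts = anchor, [anchor + ins]
                else:
                    ins = _random_seq(rng, il)
                    if ins == seq[eff:eff + dl]:
                        continue
                    ref_allele, alts = anchor + seq[eff:eff + dl], [anchor + ins]
            gt = np.zeros(n_hap, dtype=np.int64)
            # condition on the site segregating: a record nobody carries
            # would not appear in a genotyped VCF
            for _attempt in range(50):
                for a in range(len(alts), 0, -1):
                    freq = _draw_freq(rng, spec.allele_freq)
                    carriers = rng.random(n_hap) < freq
                    gt[carriers] = a  # smaller allele index wins on overlap
                if gt.any():
                    break
            chrom_records.append((eff, dl,
                                  RawVcfRecord(name, pos1, ref_allele,
                                               tuple(alts), tuple(gt))))

        # --- per-haplotype conflict pass -------------------------------
        # forbid a carried variant starting strictly inside a carried
        # deletion (records are in effect-position order)
        final = []
        del_end = np.full(n_hap, -1, dtype=np.int64)
        for eff, dl, rec in chrom_records:
            gt = np.array(rec.alleles_per_hap, dtype=np.int64)
            inside = (gt > 0) & (eff < del_end)
            gt[inside] = 0
            if dl > 0:
                carried = gt > 0
                del_end[carried] = np.maximum(del_end[carried], eff + dl)
            if gt.any():
                final.append(RawVcfRecord(rec.chrom, rec.pos, rec.ref_allele,
                                          rec.alt_alleles, tuple(int(g) for g in gt)))
        final.sort(key=lambda r: r.pos)
        records.extend(final)

    return Collection(spec, sequences, ChromosomeTable(chroms), records,
                      samples)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_fasta(collection: Collection, path) -> None:
    with open(path, "w") as fh:
        for name, seq in collection.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_vcf(collection: Collection, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in collection.chrom_table:
            fh.write(f"##contig=<ID={c.name},length={c.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(collection.samples) + "\n")
        for r in collection.records:
            gts = "\t".join(
                f"{r.alleles_per_hap[2 * s]}|{r.alleles_per_hap[2 * s + 1]}"
                for s in range(len(collection.samples)))
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t"
                     f"{','.join(r.alt_alleles)}\t.\t.\t.\tGT\t{gts}\n")


def generate_collection(spec: CollectionSpec, fasta_path, vcf_path
                        ) -> Collection:
    """Generate and write a synthetic collection; same seed, same bytes."""
    coll = synthesize(spec)
    write_fasta(coll, fasta_path)
    write_vcf(coll, vcf_path)
    return coll


def write_patterns_txt(patterns, path) -> None:
    with open(path, "w") as fh:
        for _pid, seq in patterns:
            fh.write(seq + "\n")


def write_patterns_fasta(patterns, path) -> None:
    with open(path, "w") as fh:
        for pid, seq in patterns:
            fh.write(f">{pid}\n{seq}\n")


def write_patterns_fastq(patterns, path) -> None:
    with open(path, "w") as fh:
        for pid, seq in patterns:
            fh.write(f"@{pid}\n{seq}\n+\n{'I' * len(seq)}\n")
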