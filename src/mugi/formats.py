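"""External formats: FASTA references, minimal VCF (CHROM/POS/REF/ALT +
phased GT only), pattern files (plain text / FASTA / FASTQ), TSV match
reports, and the versioned binary index container."""

from __future__ import annotations

import io
import json
import struct
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
import pysam

from .bitvectors import BitVectorStore
from .index import MugiIndex
from .kmers import IndexParams, KmerEntry, KmerSubarray, replay_entry
from .reference import ALPHABET, Chromosome, ChromosomeTable, PackedReference
from .variants import Variant, VariantDatabase

MAGIC = b"MUGIIDX\x01"
FORMAT_VERSION = 1


class FormatError(ValueError):
    pass


class IndexFormatError(FormatError):
    pass


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _offending_line(path, bad_chars) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if any(c in bad_chars for c in line.strip().upper()):
                return lineno
    return -1


def read_fasta(path) -> tuple[PackedReference, ChromosomeTable]:
    """Read a (multi-record) FASTA into the concatenated packed reference.

    Lowercase is mapped to uppercase; any character outside A/C/G/T/N is a
    hard error naming the offending line.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not a FASTA file")
    names = set()
    chroms = []
    parts = []
    offset = 0
    for rec in records:
        if rec.id in names:
            raise FormatError(f"{path}: duplicate chromosome name {rec.id!r}")
        names.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise FormatError(
                f"{path}: non-nucleotide character(s) {sorted(bad)!r} in "
                f"record {rec.id!r} (line {_offending_line(path, bad)})")
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
        chroms.append(Chromosome(rec.id, offset, len(seq)))
        offset += len(seq)
        parts.append(seq)
    return PackedReference("".join(parts)), ChromosomeTable(chroms)


# ---------------------------------------------------------------------------
# VCF (minimal subset)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawVcfRecord:
    chrom: str
    pos: int                    # 1-based
    ref_allele: str
    alt_alleles: tuple
    alleles_per_hap: tuple      # flat: sample0 left, sample0 right, ...


@dataclass
class VcfMin:
    records: list[RawVcfRecord]
    samples: list[str]

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def read_vcf_min(path, chrom_table: ChromosomeTable) -> VcfMin:
    """Read CHROM/POS/REF/ALT/GT from a VCF with phased diploid genotypes.

    Unphased or missing genotypes, unknown chromosomes and unsorted input
    are hard errors; all other fields are ignored.
    """
    known = {c.name: c for c in chrom_table}
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vf = pysam.VariantFile(str(path))
        samples = list(vf.header.samples)
        last = None
        for rec in vf:
            if rec.chrom not in known:
                raise FormatError(
                    f"{path}: record on unknown chromosome {rec.chrom!r}")
            if rec.pos < 1 or rec.pos > known[rec.chrom].length:
                raise FormatError(
                    f"{path}: POS {rec.pos} outside chromosome {rec.chrom}")
            key = (known[rec.chrom].global_start, rec.pos)
            if last is not None and key < last:
                raise FormatError(
                    f"{path}: unsorted input at {rec.chrom}:{rec.pos}")
            last = key
            alts = tuple(rec.alts or ())
            if not alts:
                raise FormatError(f"{path}: record without ALT at "
                                  f"{rec.chrom}:{rec.pos}")
            flat = []
            for s in samples:
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None or len(gt) != 2 or None in gt:
                    raise FormatError(
                        f"{path}: missing genotype at {rec.chrom}:{rec.pos} "
                        f"sample {s}")
                if not call.phased:
                    raise FormatError(
                        f"{path}: unphased genotype at {rec.chrom}:{rec.pos} "
                        f"sample {s}")
                flat.extend(int(a) for a in gt)
            records.append(RawVcfRecord(rec.chrom, rec.pos,
                                        rec.ref.upper(), alts,
                                        tuple(flat)))
        vf.close()
    return VcfMin(records, samples)


# ---------------------------------------------------------------------------
# Pattern files
# ---------------------------------------------------------------------------

def read_patterns(path, fmt: str = "txt") -> list[tuple[str, str]]:
    """Query patterns as (id, sequence) pairs; qualities are discarded."""
    if fmt not in ("txt", "fasta", "fastq"):
        raise FormatError(f"unknown pattern format {fmt!r}")
    out = []
    if fmt == "txt":
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                seq = line.strip().upper()
                if not seq:
                    warnings.warn(f"{path}: skipping empty line {i}")
                    continue
                out.append((str(len(out) + 1), seq))
        return out
    try:
        for rec in SeqIO.parse(str(path), fmt):
            out.append((rec.id, str(rec.seq).upper()))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed {fmt.upper()}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Match report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ("pattern_id", "chrom", "preceding_pos", "insertion_offset",
                  "mismatches", "haplotype_count", "haplotype_ids")


def write_matches(results, path, index: MugiIndex) -> None:
    """TSV report: one row per (pattern, match record).

    ``results`` iterates (pattern_id, [MatchRecord, ...]).  Haplotypes are
    named ``<sample>_1`` / ``<sample>_2`` (left allele first).
    """
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for pid, records in results:
            for r in records:
                haps = np.flatnonzero(r.haplotypes)
                names = ",".join(index.haplotype_name(int(h)) for h in haps)
                fh.write(f"{pid}\t{r.chrom}\t{r.pre}\t{r.offset}\t"
                         f"{r.mismatches}\t{len(haps)}\t{names}\n")


# ---------------------------------------------------------------------------
# Index container
# ---------------------------------------------------------------------------

_KIND_CODE = {"SNP": 0, "DEL": 1, "INS": 2, "SV": 3}
_CODE_KIND = {v: k for k, v in _KIND_CODE.items()}


def _arrays_from_index(index: MugiIndex):
    vd = index.vd
    arrays = {}
    arrays["ref_packed"] = index.ref.packed
    kinds = np.array([_KIND_CODE[v.kind] for v in vd.variants], dtype=np.uint8)
    arrays["vt_kind"] = kinds
    arrays["vt_eff"] = np.array([v.effect_pos for v in vd.variants], dtype=np.int64)
    arrays["vt_del"] = np.array([v.del_len for v in vd.variants], dtype=np.int64)
    ins_blob = "".join(v.ins_seq for v in vd.variants)
    lens = np.array([len(v.ins_seq) for v in vd.variants], dtype=np.int64)
    arrays["vt_ins_off"] = np.concatenate([[0], np.cumsum(lens)]).astype(np.int64)
    arrays["vt_ins_blob"] = np.frombuffer(ins_blob.encode("ascii"), dtype=np.uint8)
    arrays["vt_alt"] = np.array(
        [ord(v.alt_char) if v.alt_char else 0 for v in vd.variants],
        dtype=np.uint8)
    arrays["bv_vocab"] = index.store.vocabulary
    arrays["bv_tokens"] = index.store.tokens
    for cat, sub in enumerate(index.subarrays):
        es = sub.entries
        arrays[f"ka{cat}_pos"] = np.array([e.pos_ref for e in es], dtype=np.int64)
        arrays[f"ka{cat}_off"] = np.array([e.offset for e in es], dtype=np.int64)
        arrays[f"ka{cat}_fvt"] = np.array([e.first_vt for e in es], dtype=np.int64)
        counts = np.array([len(e.evidence) for e in es], dtype=np.int64)
        arrays[f"ka{cat}_evptr"] = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        ids, flags = [], []
        for e in es:
            for vid, f in e.evidence:
                ids.append(vid)
                flags.append(f)
        arrays[f"ka{cat}_evid"] = np.array(ids, dtype=np.int64)
        arrays[f"ka{cat}_evfl"] = np.array(flags, dtype=np.uint8)
    return arrays


def save_index(index: MugiIndex, path) -> None:
    """Write the versioned binary container (sections for REF, chromosome
    table, VD, BV dictionary + tokens, the four subarrays and parameters,
    guarded by a CRC32 checksum)."""
    arrays = _arrays_from_index(index)
    header = {
        "version": FORMAT_VERSION,
        "ref_len": index.ref.length,
        "chromosomes": [[c.name, c.global_start, c.length]
                        for c in index.chrom_table],
        "samples": index.sample_names,
        "n_haplotypes": index.store.n_haplotypes,
        "chunk_bits": index.store.chunk_bits,
        "params": {"k": index.params.k, "sparsity": index.params.sparsity,
                   "e_max": index.params.e_max,
                   "lut_width": index.params.lut_width},
        "arrays": [[name, str(a.dtype), list(a.shape)]
                   for name, a in arrays.items()],
    }
    payload = io.BytesIO()
    hb = json.dumps(header).encode("utf-8")
    payload.write(struct.pack("<Q", len(hb)))
    payload.write(hb)
    for a in arrays.values():
        payload.write(np.ascontiguousarray(a).tobytes())
    body = payload.getvalue()
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<I", zlib.crc32(body)))
        fh.write(body)


def load_index(path) -> MugiIndex:
    with open(path, "rb") as fh:
        blob = fh.read()
    if blob[:len(MAGIC)] != MAGIC:
        raise IndexFormatError(f"{path}: not a MuGI index")
    try:
        (crc,) = struct.unpack_from("<I", blob, len(MAGIC))
        body = blob[len(MAGIC) + 4:]
        if zlib.crc32(body) != crc:
            raise IndexFormatError(f"{path}: checksum failure (truncated or "
                                   "corrupt index)")
        (hlen,) = struct.unpack_from("<Q", body, 0)
        header = json.loads(body[8:8 + hlen].decode("utf-8"))
        if header["version"] != FORMAT_VERSION:
            raise IndexFormatError(
                f"{path}: unsupported index version {header['version']}")
        arrays = {}
        off = 8 + hlen
        for name, dtype, shape in header["arrays"]:
            a = np.frombuffer(blob, dtype=np.dtype(dtype),
                              count=int(np.prod(shape)) if shape else 1,
                              offset=len(MAGIC) + 4 + off)
            nbytes = a.nbytes
            arrays[name] = a.reshape(shape)
            off += nbytes
        if off != len(body):
            raise IndexFormatError(f"{path}: trailing or missing data")
    except (struct.error, ValueError, KeyError) as exc:
        raise IndexFormatError(f"{path}: corrupt index: {exc}") from exc

    ref = PackedReference.from_packed(arrays["ref_packed"],
                                      header["ref_len"])
    table = ChromosomeTable([Chromosome(n, s, l)
                             for n, s, l in header["chromosomes"]])
    ins_blob = arrays["vt_ins_blob"].tobytes().decode("ascii")
    ins_off = arrays["vt_ins_off"]
    variants = []
    for i in range(len(arrays["vt_kind"])):
        kind = _CODE_KIND[int(arrays["vt_kind"][i])]
        alt = chr(arrays["vt_alt"][i]) if arrays["vt_alt"][i] else ""
        variants.append(Variant(
            kind, int(arrays["vt_eff"][i]), int(arrays["vt_del"][i]),
            ins_blob[int(ins_off[i]):int(ins_off[i + 1])], alt))
    vd = VariantDatabase(variants)
    store = BitVectorStore.from_parts(arrays["bv_vocab"], arrays["bv_tokens"],
                                      header["n_haplotypes"],
                                      header["chunk_bits"])
    p = header["params"]
    params = IndexParams(k=p["k"], sparsity=p["sparsity"], e_max=p["e_max"],
                         lut_width=p["lut_width"])
    lut_w = min(params.lut_width, params.k)
    subs = []
    for cat in range(4):
        pos = arrays[f"ka{cat}_pos"]
        offs = arrays[f"ka{cat}_off"]
        fvt = arrays[f"ka{cat}_fvt"]
        ptr = arrays[f"ka{cat}_evptr"]
        evid = arrays[f"ka{cat}_evid"]
        evfl = arrays[f"ka{cat}_evfl"]
        entries, texts = [], []
        for i in range(len(pos)):
            ev = tuple((int(evid[j]), int(evfl[j]))
                       for j in range(int(ptr[i]), int(ptr[i + 1])))
            e = KmerEntry(cat, int(pos[i]), int(offs[i]), int(fvt[i]), ev)
            chrom = table.locate(e.pos_ref)
            text, _ = replay_entry(ref, vd, e, params.k,
                                   chrom.global_start, chrom.global_end)
            entries.append(e)
            texts.append(text.encode("ascii"))
        subs.append(KmerSubarray(texts, entries, lut_w))
    return MugiIndex(ref, table, vd, store, subs, params,
                     list(header["samples"]))
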