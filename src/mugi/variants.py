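"""Variant database: typed variant records over the reference, ordered by
effect position, with an inverse-deletion list for leftward decoding.

Coordinate convention
---------------------
All positions are 0-based global indices into the concatenated reference.
``effect_pos`` is the first affected reference character:

* SNP  — the substituted character itself,
* DEL  — the first deleted character (one past the VCF anchor base),
* INS  — the reference character *before which* the insertion occurs,
* SV   — the first deleted character; the inserted string replaces the
  deleted block at the same point.

Reports convert back to a 1-based "preceding position", which numerically
equals the 0-based local position of the first matched character.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SNP, DEL, INS, SV = "SNP", "DEL", "INS", "SV"


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class Variant:
    kind: str
    effect_pos: int
    del_len: int = 0
    ins_seq: str = ""
    alt_char: str = ""
    id: int = -1

    def __post_init__(self):
        if self.kind == SNP:
            ok = self.del_len == 0 and len(self.alt_char) == 1 and not self.ins_seq
        elif self.kind == DEL:
            ok = self.del_len >= 1 and not self.ins_seq and not self.alt_char
        elif self.kind == INS:
            ok = self.del_len == 0 and len(self.ins_seq) >= 1 and not self.alt_char
        elif self.kind == SV:
            ok = self.del_len >= 1 and len(self.ins_seq) >= 1 and not self.alt_char
        else:
            raise VariantError(f"unknown variant kind {self.kind!r}")
        if not ok:
            raise VariantError(f"inconsistent fields for {self.kind} variant: {self}")

    # --- decoding attributes (Algorithm-2 style mechanics) -------------
    @property
    def adv(self) -> int:
        """Reference positions consumed when the variant is introduced."""
        if self.kind == SNP:
            return 1
        if self.kind == INS:
            return 0
        return self.del_len

    @property
    def emit(self) -> str:
        """Characters emitted when the variant is introduced."""
        if self.kind == SNP:
            return self.alt_char
        return self.ins_seq

    @property
    def deletes(self) -> bool:
        return self.kind in (DEL, SV)

    @property
    def inserts(self) -> bool:
        return self.kind in (INS, SV)


def normalize_variant(chrom_offset: int, pos1: int, ref_allele: str,
                      alt_alleles, reference=None) -> list[Variant]:
    """Split a (possibly multiallelic) VCF record into typed variants.

    ``pos1`` is the 1-based VCF POS; ``chrom_offset`` the chromosome's global
    start.  When ``reference`` is given the REF allele is checked against it.
    """
    ref_allele = ref_allele.upper()
    start0 = chrom_offset + pos1 - 1
    if reference is not None:
        actual = reference.slice(start0, start0 + len(ref_allele)).decode("ascii")
        if actual != ref_allele:
            raise VariantError(
                f"REF allele {ref_allele!r} does not match reference "
                f"({actual!r}) at POS {pos1}")
    out = []
    for alt in alt_alleles:
        alt = alt.upper()
        if not alt or any(c not in "ACGTN" for c in alt):
            raise VariantError(f"unsupported ALT allele {alt!r} at POS {pos1}")
        if len(ref_allele) == 1 and len(alt) == 1:
            if alt == ref_allele:
                raise VariantError(f"REF == ALT at POS {pos1}")
            out.append(Variant(SNP, start0, alt_char=alt))
            continue
        if len(ref_allele) == len(alt):
            # multi-base same-length replacement (MNP): not one of the four
            # variant classes; callers must pre-normalize such records
            raise VariantError(
                f"same-length multi-base REF/ALT at POS {pos1} is not a "
                "SNP/DEL/INS/SV; pre-normalize the VCF")
        if ref_allele[0] != alt[0]:
            raise VariantError(
                f"REF/ALT at POS {pos1} lack a shared anchor base "
                f"({ref_allele!r} -> {alt!r}); pre-normalize the VCF")
        del_len = len(ref_allele) - 1
        ins = alt[1:]
        if del_len >= 1 and not ins:
            out.append(Variant(DEL, start0 + 1, del_len=del_len))
        elif del_len == 0 and ins:
            out.append(Variant(INS, start0 + 1, ins_seq=ins))
        else:
            out.append(Variant(SV, start0 + 1, del_len=del_len, ins_seq=ins))
    return out


class VariantDatabase:
    """All variants sorted by (effect_pos, input order), with a coarse
    position lookup table and the inverse-deletion list."""

    LOOKUP_STEP = 64

    def __init__(self, variants):
        order = sorted(range(len(variants)),
                       key=lambda i: (variants[i].effect_pos, i))
        self.variants: list[Variant] = [
            Variant(v.kind, v.effect_pos, v.del_len, v.ins_seq, v.alt_char, id=rank)
            for rank, v in enumerate(variants[i] for i in order)]
        #: permutation mapping input order -> VD id
        self.input_to_id = np.empty(len(variants), dtype=np.int64)
        for rank, i in enumerate(order):
            self.input_to_id[i] = rank
        self.eff = np.array([v.effect_pos for v in self.variants], dtype=np.int64)
        self.adv = np.array([v.adv for v in self.variants], dtype=np.int64)
        self.end_alg = self.eff + self.adv  # effect_pos + adv (Algorithm-2 "new")
        # inverse-deletion list: DEL/SV sorted by resulting position
        dels = [(v.effect_pos + v.del_len, v.id)
                for v in self.variants if v.deletes]
        dels.sort()
        self.invdel_resulting = np.array([d[0] for d in dels], dtype=np.int64)
        self.invdel_id = np.array([d[1] for d in dels], dtype=np.int64)
        self.max_del_len = max((v.del_len for v in self.variants if v.deletes),
                               default=0)
        # coarse lookup: first VD index with eff >= step*i
        n_buckets = (int(self.eff[-1]) // self.LOOKUP_STEP + 2) if len(self.variants) else 1
        self.position_lookup = np.searchsorted(
            self.eff, np.arange(n_buckets, dtype=np.int64) * self.LOOKUP_STEP)

    def __len__(self) -> int:
        return len(self.variants)

    def __getitem__(self, i: int) -> Variant:
        return self.variants[i]

    def first_at_or_after(self, pos: int) -> int:
        """Smallest VD index i with variants[i].effect_pos >= pos."""
        b = pos // self.LOOKUP_STEP
        if b + 1 < len(self.position_lookup):
            lo = int(self.position_lookup[b])
            hi = int(self.position_lookup[b + 1])
        else:
            lo, hi = 0, len(self.variants)
        return lo + int(np.searchsorted(self.eff[lo:hi], pos, side="left"))

    def spanning_deletions(self, pos: int) -> list[int]:
        """Ids of DEL/SV variants with effect_pos < pos < effect_pos+del_len,
        found by scanning the inverse-deletion list for resulting positions in
        (pos, pos + max_del_len]."""
        if self.max_del_len == 0:
            return []
        lo = int(np.searchsorted(self.invdel_resulting, pos, side="right"))
        hi = int(np.searchsorted(self.invdel_resulting, pos + self.max_del_len,
                                 side="right"))
        out = []
        for j in range(lo, hi):
            vid = int(self.invdel_id[j])
            if self.variants[vid].effect_pos < pos:
                out.append(vid)
        return out

    def deletions_ending_at(self, pos: int) -> list[int]:
        """Ids of DEL/SV variants with effect_pos + del_len == pos,
        in ascending id order."""
        lo = int(np.searchsorted(self.invdel_resulting, pos, side="left"))
        hi = int(np.searchsorted(self.invdel_resulting, pos, side="right"))
        return sorted(int(self.invdel_id[j]) for j in range(lo, hi))


@dataclass
class DecodingState:
    """Cursor state after partially decoding a path.

    ``in_ins`` is ``(variant_id, next_offset)`` when the cursor sits inside an
    insertion (``next_offset`` is the 0-based index of the next inserted
    character still to be emitted), else ``None``.
    """
    pos_curr: int
    vt_curr: int
    evidence: dict[int, int] = field(default_factory=dict)
    in_ins: tuple[int, int] | None = None
    chars_done: int = 0
    #: projection of the first emitted character: (ref_pos, ins_offset)
    start_proj: tuple[int, int] | None = None
    #: id ceiling at the start boundary for leftward decoding
    left_ceiling: int = 1 << 60


# ---------------------------------------------------------------------------
# Path-conditional decoding.  These two functions are replay decoders for a
# *known* set of present variants; the search engine's branching walkers live
# in mugi.search and follow identical mechanics.
# ---------------------------------------------------------------------------

def decode_forward(ref, vd: VariantDatabase, start: int, n: int, path,
                   chrom_end: int | None = None) -> tuple[str, bool]:
    """Decode ``n`` haplotype characters from reference position ``start``
    applying exactly the variants in ``path`` (a set of VD ids).

    Returns ``(text, hit_end)`` where ``hit_end`` flags that the chromosome
    end was reached before ``n`` characters were produced.
    """
    end = ref.length if chrom_end is None else chrom_end
    path = set(path)
    out = []
    pos = start
    vt = vd.first_at_or_after(start)
    nv = len(vd)
    while len(out) < n:
        if vt < nv and vd.eff[vt] <= pos:
            v = vd[vt]
            if v.effect_pos == pos:
                if vt in path:
                    for c in v.emit:
                        out.append(c)
                        if len(out) == n:
                            return "".join(out), False
                    pos += v.adv
                vt += 1
            else:  # effect_pos < pos: inside a previously applied deletion
                if vt in path and v.effect_pos + v.adv > pos:
                    for c in v.emit:
                        out.append(c)
                        if len(out) == n:
                            return "".join(out), False
                    pos = v.effect_pos + v.adv
                vt += 1
        else:
            if pos >= end:
                return "".join(out), True
            out.append(chr(ref[pos]))
            pos += 1
    return "".join(out), False


def decode_backward(ref, vd: VariantDatabase, end: int, n: int, path,
                    chrom_start: int = 0, in_ins: tuple[int, int] | None = None
                    ) -> tuple[str, bool]:
    """Decode the ``n`` haplotype characters immediately left of boundary
    ``end`` under ``path``, using the inverse-deletion list to jump over
    present deletions.

    ``in_ins=(variant_id, offset)`` starts the walk inside an insertion, with
    ``offset`` inserted characters (1..offset) still to the left.  Returns
    ``(text, hit_start)``; text is in left-to-right order.
    """
    path = set(path)
    out = []  # collected right-to-left

    def emit(c) -> bool:
        out.append(c)
        return len(out) == n

    # state: boundary position + id ceiling (only variants with id < ceiling
    # at the boundary's effect position may contribute characters)
    pos = end
    ceiling = 1 << 60
    if in_ins is not None:
        vid, off = in_ins
        v = vd[vid]
        for o in range(off, 0, -1):
            if emit(v.ins_seq[o - 1]):
                return "".join(reversed(out)), False
        pos, ceiling = v.effect_pos, vid
    while len(out) < n:
        # insertions anchored at the boundary, highest id first
        vt = vd.first_at_or_after(pos)
        # an SV anchored at the boundary deletes rightward; only pure INS
        # contributes characters to the left of it
        ins_here = [i for i in range(vt, len(vd))
                    if vd.eff[i] == pos and i < ceiling and vd[i].kind == INS
                    and i in path]
        if ins_here:
            v = vd[max(ins_here)]
            for o in range(len(v.ins_seq), 0, -1):
                if emit(v.ins_seq[o - 1]):
                    return "".join(reversed(out)), False
            ceiling = v.id
            continue
        # present deletion ending exactly at the boundary
        jumped = False
        for vid in sorted(vd.deletions_ending_at(pos), reverse=True):
            if vid in path and vid < ceiling:
                v = vd[vid]
                if v.kind == SV:
                    for o in range(len(v.ins_seq), 0, -1):
                        if emit(v.ins_seq[o - 1]):
                            return "".join(reversed(out)), False
                pos, ceiling = v.effect_pos, vid
                jumped = True
                break
        if jumped:
            continue
        if pos <= chrom_start:
            return "".join(reversed(out)), True
        # plain reference character (or SNP alternative) at pos-1
        pos -= 1
        ceiling = 1 << 60
        snp = None
        j = vd.first_at_or_after(pos)
        while j < len(vd) and vd.eff[j] == pos:
            if vd[j].kind == SNP and j in path:
                snp = vd[j]
            j += 1
        if snp is not None:
            if emit(snp.alt_char):
                break
            ceiling = snp.id
        else:
            if emit(chr(ref[pos])):
                break
    return "".join(reversed(out)), False
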