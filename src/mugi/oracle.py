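"""Ground truth by brute force: explicit haplotype reconstruction, a naive
sequential Hamming scan over every decoded sequence, and set-level
equivalence checking against index results.

This module is deliberately independent of the index machinery: haplotypes
are built by direct left-to-right application of carried variants, and the
scan inspects every window of every sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variants import DEL, SNP, SV, VariantDatabase

_ENC = np.zeros(256, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENC[_c] = _i
_ENC[ord("N")] = 4           # collection N: matches nothing
_PATTERN_N = 5               # pattern N: matches nothing either


@dataclass
class ProjectedHaplotype:
    """One chromosome of one haploid genome, with per-character projection
    onto reference coordinates: (pre, offset) pairs where ``pre`` is the
    0-based local position for reference characters (offset 0) and the
    insertion anchor for inserted characters (offset >= 1)."""
    chrom: str
    hap: int
    text: str
    pre: np.ndarray
    off: np.ndarray

    def codes(self) -> np.ndarray:
        return _ENC[np.frombuffer(self.text.encode("ascii"), dtype=np.uint8)]


def decode_haplotype(ref, chrom_table, vd: VariantDatabase, carried,
                     hap: int) -> list[ProjectedHaplotype]:
    """Explicitly construct haplotype ``hap`` (one entry per chromosome).

    ``carried`` is a bool vector over VD ids.  Raises if two carried
    variants overlap (the generator never emits such pairs).
    """
    out = []
    for chrom in chrom_table:
        lo, hi = chrom.global_start, chrom.global_end
        text = []
        pre = []
        off = []
        cursor = lo
        i = vd.first_at_or_after(lo)
        while i < len(vd) and vd.eff[i] < hi:
            if not carried[i]:
                i += 1
                continue
            v = vd[i]
            if v.effect_pos < cursor:
                raise ValueError(
                    f"haplotype {hap}: variant {i} overlaps a previously "
                    "applied variant")
            seg = ref.slice(cursor, v.effect_pos).decode("ascii")
            text.append(seg)
            pre.extend(range(cursor - lo, v.effect_pos - lo))
            off.extend([0] * len(seg))
            if v.kind == SNP:
                text.append(v.alt_char)
                pre.append(v.effect_pos - lo)
                off.append(0)
                cursor = v.effect_pos + 1
            elif v.kind == DEL:
                cursor = v.effect_pos + v.del_len
            else:  # INS or SV
                text.append(v.ins_seq)
                pre.extend([v.effect_pos - lo] * len(v.ins_seq))
                off.extend(range(1, len(v.ins_seq) + 1))
                cursor = v.effect_pos + (v.del_len if v.kind == SV else 0)
            i += 1
        seg = ref.slice(cursor, hi).decode("ascii")
        text.append(seg)
        pre.extend(range(cursor - lo, hi - lo))
        off.extend([0] * len(seg))
        out.append(ProjectedHaplotype(chrom.name, hap, "".join(text),
                                      np.array(pre, dtype=np.int64),
                                      np.array(off, dtype=np.int64)))
    return out


def decode_all_haplotypes(ref, chrom_table, vd, matrix) -> list[ProjectedHaplotype]:
    out = []
    for h in range(matrix.n_haplotypes):
        out.extend(decode_haplotype(ref, chrom_table, vd, matrix.rows[:, h], h))
    return out


def _pattern_codes(P: str) -> np.ndarray:
    codes = _ENC[np.frombuffer(P.encode("ascii"), dtype=np.uint8)].copy()
    codes[np.frombuffer(P.encode("ascii"), dtype=np.uint8) == ord("N")] = _PATTERN_N
    return codes


def oracle_scan(haplotypes, P: str, q: int) -> dict:
    """Hamming scan of every window of every haplotype sequence.

    Returns ``{(chrom, pre, offset, hap): min_mismatches}`` over all windows
    with at most ``q`` mismatches; the position reported is the projection
    of the window's first character.
    """
    P = P.upper()
    pc = _pattern_codes(P)
    m = len(P)
    hits: dict = {}
    for ph in haplotypes:
        n = len(ph.text)
        if n < m:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(ph.codes(), m)
        mism = (windows != pc).sum(axis=1)
        for i in np.flatnonzero(mism <= q):
            key = (ph.chrom, int(ph.pre[i]), int(ph.off[i]), ph.hap)
            mm = int(mism[i])
            if key not in hits or mm < hits[key]:
                hits[key] = mm
    return hits


def expand_records(records) -> dict:
    """Index results as ``{(chrom, pre, offset, hap): min_mismatches}``."""
    out: dict = {}
    for r in records:
        for h in np.flatnonzero(r.haplotypes):
            key = (r.chrom, r.pre, r.offset, int(h))
            if key not in out or r.mismatches < out[key]:
                out[key] = r.mismatches
    return out


@dataclass
class EquivalenceReport:
    ok: bool
    missing: list    # in oracle, not reported by the index
    extra: list      # reported by the index, not in oracle
    wrong_count: list  # same tuple, different minimum mismatch count

    def __str__(self):
        if self.ok:
            return "equivalence: PASS"
        lines = ["equivalence: FAIL"]
        for name, items in (("missing", self.missing), ("extra", self.extra),
                            ("wrong_count", self.wrong_count)):
            for it in items[:20]:
                lines.append(f"  {name}: {it}")
        return "\n".join(lines)


def equivalence_check(index_expanded: dict, oracle_hits: dict
                      ) -> EquivalenceReport:
    missing = sorted(k for k in oracle_hits if k not in index_expanded)
    extra = sorted(k for k in index_expanded if k not in oracle_hits)
    wrong = sorted((k, index_expanded[k], oracle_hits[k])
                   for k in index_expanded
                   if k in oracle_hits and index_expanded[k] != oracle_hits[k])
    return EquivalenceReport(not (missing or extra or wrong),
                             missing, extra, wrong)


def generate_query_set(haplotypes, n: int, len_range=(100, 200),
                       err_range=(0, 5), rng_seed: int = 0,
                       max_tries: int = 10_000) -> list[tuple[str, str]]:
    """Patterns as mutated excerpts of decoded haplotypes: uniform random
    haplotype chromosome, start and length, then e substitutions (e uniform
    in err_range) at distinct positions, each to a different base.
    N-containing excerpts are rejected and redrawn."""
    rng = np.random.default_rng(rng_seed)
    usable = [ph for ph in haplotypes if len(ph.text) >= len_range[0]]
    if not usable:
        raise ValueError("no haplotype long enough for the query length range")
    out = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries + 10 * n:
            raise RuntimeError("query generation rejected too many excerpts")
        ph = usable[int(rng.integers(0, len(usable)))]
        length = int(rng.integers(len_range[0], min(len_range[1], len(ph.text)) + 1))
        start = int(rng.integers(0, len(ph.text) - length + 1))
        excerpt = ph.text[start:start + length]
        if "N" in excerpt:
            continue
        e = int(rng.integers(err_range[0], err_range[1] + 1))
        chars = list(excerpt)
        if e > 0:
            idx = rng.choice(length, size=min(e, length), replace=False)
            for i in idx:
                chars[i] = _BASES_OTHER[chars[i]][int(rng.integers(0, 3))]
        out.append((str(len(out) + 1), "".join(chars)))
    return out


_BASES_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
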