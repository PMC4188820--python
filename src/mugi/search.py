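"""Seed-and-extend search over the k-mer array.

Exact search locates the pattern prefix (the *seed*) in all four subarrays by
binary search, partially decodes each hit and extends it right along every
consistent variant path.  With a sparse index, shifted seeds are additionally
located and the uncovered prefix is decoded leftward.  Approximate search
splits the pattern into q+1 disjoint segments (pigeonhole: at least one is
error-free), exact-locates each and extends bidirectionally with a shared
mismatch budget.

Mismatch model: substitutions only.  A pattern character matches a collection
character iff they are equal and not ``N`` — undetermined nucleotides never
match anything.  Insertions and deletions along a variant path are not
errors; they are alternative exact paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmers import replay_entry
from .variants import INS, SNP, SV

_INF = 1 << 60


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class Query:
    id: str
    sequence: str


@dataclass
class MatchRecord:
    chrom: str
    pre: int               # 1-based preceding reference position (0 at
                           # chromosome start); equals the 0-based local
                           # position of the first matched character
    offset: int            # position within an insertion, 0 if on reference
    haplotypes: np.ndarray  # the R vector
    mismatches: int
    evidence: tuple        # canonical sorted ((variant_id, flag), ...)

    def key(self):
        return (self.chrom, self.pre, self.offset, self.evidence)


def _match(a: str, b: str) -> bool:
    return a == b and a != "N"


def pigeonhole_split(m: int, q: int) -> list[tuple[int, int]]:
    """q+1 disjoint segments of length floor(m/(q+1)); the remainder tail
    belongs to no segment (it is still checked during extension)."""
    seg = m // (q + 1)
    if seg < 1:
        raise SearchError(f"pattern of length {m} too short for {q} mismatches")
    return [(i * seg, seg) for i in range(q + 1)]


# ---------------------------------------------------------------------------
# Rightward extension
# ---------------------------------------------------------------------------

def extend_right(index, P, ch, budget, state, chrom_hi, node_cap=10_000):
    """Depth-first enumeration of all variant paths completing the pattern to
    the right.  Returns ``[(evidence_dict, mismatches_used), ...]``; ``ch``
    is the number of pattern characters already accounted for."""
    vd = index.vd
    ref = index.ref
    eff = vd.eff
    nv = len(vd)
    m = len(P)
    out = []
    nodes = 0

    def go(pos, vt, ch, rem, ev, in_ins):
        nonlocal nodes
        nodes += 1
        if nodes > node_cap:
            raise SearchError("extension explored too many paths")
        if in_ins is not None:
            vid, off = in_ins
            ins = vd[vid].ins_seq
            for j in range(off, len(ins)):
                if ch == m:
                    break
                if not _match(ins[j], P[ch]):
                    rem -= 1
                    if rem < 0:
                        return
                ch += 1
        while True:
            if ch == m:
                out.append((ev, rem))
                return
            if vt < nv and eff[vt] <= pos:
                v = vd.variants[vt]
                new = v.effect_pos + v.adv
                if v.effect_pos == pos or new > pos:
                    fixed = ev.get(vt)
                    if fixed != 0:
                        rem2, ch2, ok = rem, ch, True
                        for c in v.emit:
                            if ch2 == m:
                                break
                            if not _match(c, P[ch2]):
                                rem2 -= 1
                                if rem2 < 0:
                                    ok = False
                                    break
                            ch2 += 1
                        if ok:
                            ev2 = dict(ev)
                            ev2[vt] = 1
                            go(max(new, pos), vt + 1, ch2, rem2, ev2, None)
                    if fixed == 1:
                        return
                    ev = dict(ev)
                    ev[vt] = 0
                vt += 1
                continue
            if pos >= chrom_hi:
                return  # chromosome end before the pattern was exhausted
            if not _match(chr(ref[pos]), P[ch]):
                rem -= 1
                if rem < 0:
                    return
            pos += 1
            ch += 1

    go(state.pos_curr, state.vt_curr, ch, budget,
       dict(state.evidence), state.in_ins)
    return [(ev, budget - rem) for ev, rem in out]


# ---------------------------------------------------------------------------
# Leftward extension
# ---------------------------------------------------------------------------

def extend_left(index, P, j, budget, start_state, base_ev, chrom_lo,
                node_cap=10_000):
    """All ways to match P[0:j] immediately left of the seed.

    ``start_state`` is ``("ref", boundary, id_ceiling)`` or
    ``("ins", variant_id, remaining_offset)``; ``base_ev`` carries every
    decision already made by the seed and the rightward extension, which the
    walk must honour.  Returns ``[(evidence_dict, mismatches_used,
    start_projection), ...]`` with the projection ``(ref_pos, ins_offset)``
    of the pattern's first character.
    """
    vd = index.vd
    ref = index.ref
    out = []
    nodes = 0

    def force_zeros(ev, ids) -> bool:
        """Record absent flags; False if a prior flag contradicts."""
        for w in ids:
            f = ev.get(w)
            if f == 1:
                return False
            ev[w] = 0
        return True

    def consuming_before(pos, id_limit):
        """Ids of consuming (adv>0) variants at effect position pos with
        id < id_limit."""
        out_ids = []
        i = vd.first_at_or_after(pos)
        while i < len(vd) and vd.eff[i] == pos:
            if i < id_limit and vd.variants[i].adv > 0:
                out_ids.append(i)
            i += 1
        return out_ids

    def go(mode, j, rem, ev, proj):
        nonlocal nodes
        nodes += 1
        if nodes > node_cap:
            raise SearchError("left extension explored too many paths")
        if j == 0:
            out.append((ev, rem, proj))
            return
        if mode[0] == "ins":
            _, vid, off = mode
            v = vd[vid]
            while off >= 1 and j > 0:
                c = v.ins_seq[off - 1]
                if not _match(c, P[j - 1]):
                    rem -= 1
                    if rem < 0:
                        return
                proj = (v.effect_pos, off)
                j -= 1
                off -= 1
            if j == 0:
                out.append((ev, rem, proj))
                return
            go(("ref", v.effect_pos, vid), j, rem, ev, proj)
            return
        _, c, ceiling = mode
        # the character left of boundary c may come from an insertion
        # anchored at c, a deletion ending at c, or position c-1 itself;
        # candidates are taken in decreasing id order (mirror of the forward
        # decode, which processes variants in increasing id order)
        cand = None
        i = vd.first_at_or_after(c)
        while i < len(vd) and vd.eff[i] == c:
            if i < ceiling and vd.variants[i].kind == INS:
                cand = i
            i += 1
        if cand is None:
            ends = [i for i in vd.deletions_ending_at(c) if i < ceiling]
            if ends:
                cand = max(ends)
        if cand is not None:
            v = vd[cand]
            fixed = ev.get(cand)
            if fixed != 0:
                ev2 = dict(ev)
                ev2[cand] = 1
                if v.kind == INS:
                    go(("ins", cand, len(v.ins_seq)), j, rem, ev2, proj)
                else:
                    # taking a deletion jump: consuming variants at its
                    # anchor with smaller id, and deletions reaching beyond
                    # the boundary from inside it, must all be absent
                    ok = force_zeros(ev2, consuming_before(v.effect_pos, cand))
                    w = cand + 1
                    while ok and w < len(vd):
                        e = int(vd.eff[w])
                        if e >= c:
                            break
                        if e > v.effect_pos:
                            u = vd.variants[w]
                            if u.deletes and e + u.del_len > c:
                                ok = force_zeros(ev2, [w])
                        w += 1
                    if ok:
                        if v.kind == SV:
                            go(("ins", cand, len(v.ins_seq)), j, rem, ev2, proj)
                        else:
                            go(("ref", v.effect_pos, cand), j, rem, ev2, proj)
            if fixed != 1:
                ev2 = dict(ev)
                ev2[cand] = 0
                go(("ref", c, cand), j, rem, ev2, proj)
            return
        # no variant supplies the character: consume position c-1
        if c <= chrom_lo:
            return  # chromosome start reached with pattern left over
        pos = c - 1
        snps = []
        dels_here = []
        i = vd.first_at_or_after(pos)
        while i < len(vd) and vd.eff[i] == pos:
            v = vd.variants[i]
            if v.kind == SNP:
                snps.append(i)
            elif v.deletes:
                dels_here.append(i)
            i += 1
        for m_id in snps:
            if ev.get(m_id) == 0:
                continue
            rem2 = rem
            if not _match(vd[m_id].alt_char, P[j - 1]):
                rem2 -= 1
                if rem2 < 0:
                    continue
            ev2 = dict(ev)
            ev2[m_id] = 1
            if force_zeros(ev2, [w for w in snps if w < m_id]) \
                    and force_zeros(ev2, [w for w in dels_here if w < m_id]):
                go(("ref", pos, m_id), j - 1, rem2, ev2, (pos, 0))
        # plain reference branch: everything consuming position c-1 absent
        ev2 = dict(ev)
        if force_zeros(ev2, snps) and force_zeros(ev2, dels_here):
            rem2 = rem
            if not _match(chr(ref[pos]), P[j - 1]):
                rem2 -= 1
            if rem2 >= 0:
                go(("ref", pos, _INF), j - 1, rem2, ev2, (pos, 0))

    go(start_state, j, budget, dict(base_ev), None)
    return [(ev, budget - rem, proj) for ev, rem, proj in out]


# ---------------------------------------------------------------------------
# Top-level search
# ---------------------------------------------------------------------------

def part_decode(index, entry, p: int):
    """Partially decode an entry ``p`` characters forward; returns the
    decoding state (cursor, evidence with implied absent flags, start
    boundary for leftward decoding)."""
    chrom = index.chrom_table.locate(entry.pos_ref)
    _, state = replay_entry(index.ref, index.vd, entry, p,
                            chrom.global_start, chrom.global_end)
    return state, chrom


def _left_start(entry, state):
    if entry.offset > 0:
        return ("ins", entry.first_vt, entry.offset - 1)
    return ("ref", entry.pos_ref, state.left_ceiling)


def _record(index, chrom, proj, evidence, mismatches):
    r = index.store.resolve(evidence)
    if not r.any():
        return None
    pos, off = proj
    return MatchRecord(chrom.name, pos - chrom.global_start, off, r,
                       mismatches, tuple(sorted(evidence.items())))


def seed_and_extend(index, P: str, seed_start: int, seed_len: int,
                    budget: int, node_cap=10_000) -> list[MatchRecord]:
    """Locate the seed P[seed_start : seed_start+seed_len] in all four
    subarrays and extend every hit right to the pattern end and left to the
    pattern start with the given mismatch budget.  The seed itself is
    matched exactly, so callers must keep it inside a region guaranteed
    error-free (the whole pattern for exact search, the pigeonhole segment
    for approximate search)."""
    m = len(P)
    L = min(index.params.k, seed_len, m - seed_start)
    if L < 1:
        return []
    seed = P[seed_start:seed_start + L].encode("ascii")
    if b"N" in seed:
        return []  # undetermined nucleotides never match
    records = []
    for sub in index.subarrays:
        lo, hi = sub.interval(seed)
        for idx in range(lo, hi):
            entry = sub.entries[idx]
            state, chrom = part_decode(index, entry, L)
            if state.chars_done < L:
                continue
            rights = extend_right(index, P, seed_start + L, budget, state,
                                  chrom.global_end, node_cap)
            left_state = _left_start(entry, state)
            for ev_r, mm_r in rights:
                if seed_start == 0:
                    rec = _record(index, chrom, state.start_proj, ev_r, mm_r)
                    if rec is not None:
                        records.append(rec)
                    continue
                lefts = extend_left(index, P, seed_start, budget - mm_r,
                                    left_state, ev_r, chrom.global_start,
                                    node_cap)
                for ev_l, mm_l, proj in lefts:
                    rec = _record(index, chrom, proj, ev_l, mm_r + mm_l)
                    if rec is not None:
                        records.append(rec)
    return records


def aggregate(records) -> list[MatchRecord]:
    """Deduplicate by (chrom, pre, offset, evidence), keeping the minimum
    mismatch count and OR-ing the haplotype vectors."""
    merged: dict = {}
    for r in records:
        k = r.key()
        got = merged.get(k)
        if got is None:
            merged[k] = r
        else:
            got.mismatches = min(got.mismatches, r.mismatches)
            got.haplotypes = got.haplotypes | r.haplotypes
    return sorted(merged.values(), key=lambda r: (r.chrom, r.pre, r.offset,
                                                  r.evidence))


def exact_search(index, P: str, min_seed_len: int = 8,
                 node_cap=10_000) -> list[MatchRecord]:
    """All exact occurrences of P: reference positions plus the haploid
    genomes carrying each matched path."""
    P = P.upper()
    if len(P) < 1:
        raise SearchError("empty pattern")
    if min(len(P), index.params.k) < min_seed_len:
        raise SearchError(
            f"seed of length {min(len(P), index.params.k)} below minimum "
            f"{min_seed_len}; short seeds produce numerous matches")
    records = []
    for j in range(index.params.sparsity):
        if j >= len(P):
            break
        records.extend(seed_and_extend(index, P, j, len(P) - j, 0, node_cap))
    return aggregate(records)


def approximate_search(index, P: str, q: int, min_seed_len: int = 8,
                       node_cap=10_000) -> list[MatchRecord]:
    """All occurrences of P with at most q mismatches."""
    if q == 0:
        return exact_search(index, P, min_seed_len, node_cap)
    P = P.upper()
    segments = pigeonhole_split(len(P), q)
    if segments[0][1] < index.params.sparsity:
        import warnings
        warnings.warn(
            f"pigeonhole segments of length {segments[0][1]} are shorter "
            f"than the index sparsity {index.params.sparsity}; occurrences "
            "whose sampled seed lies outside the error-free segment may be "
            "missed", stacklevel=2)
    if segments[0][1] < min_seed_len:
        raise SearchError(
            f"segment length {segments[0][1]} below minimum seed length "
            f"{min_seed_len} for q={q}")
    records = []
    for seg_start, seg_len in segments:
        for j in range(index.params.sparsity):
            if j >= seg_len:
                break  # shifted seed would leave the error-free segment
            records.extend(seed_and_extend(index, P, seg_start + j,
                                           seg_len - j, q, node_cap))
    return aggregate(records)
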