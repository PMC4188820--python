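"""The k-mer array (kMA): every k-length window occurring in any haplotype,
stored as a decoding recipe (reference start + evidence list) in one of four
lexicographically sorted subarrays.

Subarrays
---------
* kMA0 — windows equal to the plain reference (only the position is kept),
* kMA1 — windows requiring a short run of consecutive variant evidences,
* kMA2 — windows starting inside an inserted string (offset > 0),
* kMA3 — windows with non-consecutive evidences or more than E_max of them.

An *evidence list* records, for each variant decided while decoding the
window, whether it was introduced (1) or absent (0).  Evidence implied by the
geometry alone — deletions spanning the window start must be absent, and for
a window starting inside an insertion the smaller-id consuming variants at
the same anchor must be absent — is not stored; it is re-derived at query
time (and during presence filtering) from the variant database.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np

from .variants import DEL, INS, SV, DecodingState, VariantDatabase

_INF = 1 << 60


@dataclass(frozen=True)
class IndexParams:
    k: int
    sparsity: int = 1
    e_max: int = 16
    lut_width: int = 12
    path_cap: int = 1 << 20

    def __post_init__(self):
        if self.k < 1 or self.sparsity < 1 or self.e_max < 1 or self.lut_width < 1:
            raise ValueError("index parameters must be positive")
        if self.k < min(self.lut_width, self.k):
            raise ValueError("k must be >= lut_width")


@dataclass(frozen=True)
class KmerEntry:
    category: int
    pos_ref: int           # 0-based global reference start (insertion anchor
                           # for offset entries)
    offset: int = 0        # 1-based position inside the inserted string
    first_vt: int = -1
    evidence: tuple = ()   # ((variant_id, flag), ...) in id order

    def key(self):
        return (self.pos_ref, self.offset, self.evidence)


class PathExplosionError(RuntimeError):
    pass


def categorize_entry(evidence: tuple, offset: int, e_max: int) -> int:
    """Category 0-3 from the stored evidence shape alone."""
    if not evidence:
        return 0
    ids = [vid for vid, _ in evidence]
    consecutive = ids[-1] - ids[0] + 1 == len(ids)
    if consecutive and len(ids) <= e_max:
        return 1 if offset == 0 else 2
    return 3


def implied_evidence(vd: VariantDatabase, entry_pos: int, offset: int,
                     first_vt: int) -> dict[int, int]:
    """Evidence not stored in the entry but forced by its coordinates."""
    ev = {vid: 0 for vid in vd.spanning_deletions(entry_pos)}
    if offset > 0:
        # consuming variants at the same anchor with smaller id would have
        # prevented the insertion from being introduced
        j = vd.first_at_or_after(entry_pos)
        while j < first_vt:
            if vd.eff[j] == entry_pos and vd[j].adv > 0:
                ev[j] = 0
            j += 1
    return ev


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def _enumerate_start(ref, vd, s, k, hi, cap, out):
    """DFS over variant paths for windows starting at reference position s.

    At zero emitted characters an INS/SV present-branch is suppressed (those
    windows start inside the insertion and belong to the offset enumeration);
    the SV absent flag is still recorded since an SV deletes the start
    character.
    """
    eff = vd.eff
    nv = len(vd)
    text: list[str] = []
    ev: list[tuple[int, int]] = []
    nodes = 0

    def dfs(pos, vt):
        nonlocal nodes
        nodes += 1
        if nodes > cap:
            raise PathExplosionError(
                f"more than {cap} decoding paths for window start {s}")
        if len(text) == k:
            out.append(("".join(text), tuple(ev), s, 0))
            return
        if vt < nv and eff[vt] <= pos:
            v = vd.variants[vt]
            if v.effect_pos == pos:
                start_phase = not text
                if start_phase and v.kind == INS:
                    dfs(pos, vt + 1)                      # no flag: precedes window
                elif start_phase and v.kind == SV:
                    ev.append((vt, 0))                    # SV deletes the start char
                    dfs(pos, vt + 1)
                    ev.pop()
                else:
                    ev.append((vt, 1))
                    n0 = len(text)
                    ok = True
                    for c in v.emit:
                        text.append(c)
                        if len(text) == k:
                            break
                    dfs(pos + v.adv, vt + 1)
                    del text[n0:]
                    ev[-1] = (vt, 0)
                    dfs(pos, vt + 1)
                    ev.pop()
            else:  # v.effect_pos < pos: overlaps a previously applied deletion
                new = v.effect_pos + v.adv
                if new > pos:  # deletes beyond the previous deletion
                    if not text and v.kind == SV:
                        ev.append((vt, 0))
                        dfs(pos, vt + 1)
                        ev.pop()
                    else:
                        ev.append((vt, 1))
                        n0 = len(text)
                        for c in v.emit:
                            text.append(c)
                            if len(text) == k:
                                break
                        dfs(new, vt + 1)
                        del text[n0:]
                        ev[-1] = (vt, 0)
                        dfs(pos, vt + 1)
                        ev.pop()
                else:
                    dfs(pos, vt + 1)                      # entirely inside: pointless
        else:
            if pos >= hi:
                return                                    # window truncated: drop
            text.append(chr(ref[pos]))
            dfs(pos + 1, vt)
            text.pop()

    dfs(s, vd.first_at_or_after(s))


def _enumerate_insertion(ref, vd, v, k, hi, cap, out):
    """Windows starting at each internal offset of insertion variant v."""
    ins = v.ins_seq
    for o in range(1, len(ins) + 1):
        text = list(ins[o - 1:k + o - 1])
        ev = [(v.id, 1)]
        eff = vd.eff
        nv = len(vd)
        nodes = 0
        results: list = []

        def dfs(pos, vt):
            nonlocal nodes
            nodes += 1
            if nodes > cap:
                raise PathExplosionError(
                    f"more than {cap} decoding paths inside insertion at "
                    f"{v.effect_pos}")
            if len(text) == k:
                results.append(("".join(text), tuple(ev), v.effect_pos, o))
                return
            if vt < nv and eff[vt] <= pos:
                w = vd.variants[vt]
                new = w.effect_pos + w.adv
                if w.effect_pos == pos or new > pos:
                    ev.append((vt, 1))
                    n0 = len(text)
                    for c in w.emit:
                        text.append(c)
                        if len(text) == k:
                            break
                    dfs(max(new, pos), vt + 1)
                    del text[n0:]
                    ev[-1] = (vt, 0)
                    dfs(pos, vt + 1)
                    ev.pop()
                else:
                    dfs(pos, vt + 1)
            else:
                if pos >= hi:
                    return
                text.append(chr(ref[pos]))
                dfs(pos + 1, vt)
                text.pop()

        dfs(v.effect_pos + (v.del_len if v.kind == SV else 0), v.id + 1)
        out.extend(results)


def enumerate_kmer_paths(ref, chrom_table, vd: VariantDatabase,
                         params: IndexParams):
    """All (window text, evidence, pos_ref, offset) candidates, before
    presence filtering.  Windows never cross chromosome boundaries and
    windows beginning with N are dropped."""
    k = params.k
    out: list = []
    eff = vd.eff
    for chrom in chrom_table:
        lo_c, hi_c = chrom.global_start, chrom.global_end
        starts = np.arange(lo_c, max(lo_c, hi_c - k + 1))
        if len(starts):
            v_lo = np.searchsorted(eff, starts, side="left")
            v_hi = np.searchsorted(eff, starts + k, side="left")
            plain = v_lo == v_hi
            for s in starts[plain]:
                s = int(s)
                text = ref.slice(s, s + k)
                if text[0] != 78:  # ord('N')
                    out.append((text.decode("ascii"), (), s, 0))
            for s in starts[~plain]:
                _enumerate_start(ref, vd, int(s), k, hi_c, params.path_cap, out)
        # tail starts: a window can still reach k characters through an
        # insertion even when fewer than k reference characters remain
        for s in range(max(lo_c, hi_c - k + 1), hi_c):
            _enumerate_start(ref, vd, s, k, hi_c, params.path_cap, out)
    for v in vd.variants:
        if v.inserts:
            chrom = chrom_table.locate(v.effect_pos)
            _enumerate_insertion(ref, vd, v, k, chrom.global_end,
                                 params.path_cap, out)
    return [(t, ev, p, o) for (t, ev, p, o) in out if not t.startswith("N")]


# ---------------------------------------------------------------------------
# Subarrays
# ---------------------------------------------------------------------------

class KmerSubarray:
    """One lexicographically sorted subarray plus its prefix lookup table."""

    def __init__(self, texts: list[bytes], entries: list[KmerEntry],
                 lut_width: int):
        self.texts = texts
        self.entries = entries
        self.lut_width = lut_width
        self.lut: dict[bytes, tuple[int, int]] = {}
        i = 0
        n = len(texts)
        while i < n:
            p = texts[i][:lut_width]
            j = i
            while j < n and texts[j][:lut_width] == p:
                j += 1
            if not any(c == 78 for c in p):  # ACGT prefixes only
                self.lut[p] = (i, j)
            i = j

    def __len__(self):
        return len(self.entries)

    def interval(self, seed: bytes) -> tuple[int, int]:
        """Maximal interval of entries whose window has ``seed`` as prefix."""
        m = len(seed)
        lo, hi = 0, len(self.texts)
        if m >= self.lut_width and 78 not in seed[:self.lut_width]:
            got = self.lut.get(seed[:self.lut_width])
            if got is None:
                # fall back for N-prefixed entries which are outside the LUT
                pass
            else:
                lo, hi = got
        key = lambda t: t[:m]
        left = bisect.bisect_left(self.texts, seed, lo, hi, key=key)
        right = bisect.bisect_right(self.texts, seed, lo, hi, key=key)
        return left, right


def presence_filter(store, vd, candidate) -> bool:
    """Keep a candidate only if at least one haploid genome carries exactly
    its flagged variant combination."""
    text, ev, pos_ref, offset = candidate
    first_vt = ev[0][0] if ev else -1
    full = implied_evidence(vd, pos_ref, offset, first_vt)
    full.update(dict(ev))
    return bool(store.resolve(full).any())


def build_kmer_array(candidates, params: IndexParams, store=None, vd=None
                     ) -> list[KmerSubarray]:
    """Deduplicate, presence-filter, categorize, sort and index candidates
    into the four subarrays."""
    seen = set()
    buckets: list[list] = [[], [], [], []]
    for cand in candidates:
        text, ev, pos_ref, offset = cand
        full_ev = ev
        if all(flag == 0 for _, flag in ev):
            ev = ()  # pure-reference path: evidence reconstructed at query time
        key = (text, pos_ref, offset, ev)
        if key in seen:
            continue
        seen.add(key)
        # the filter must see the absent flags even when they are not stored
        if store is not None and not presence_filter(
                store, vd, (text, full_ev, pos_ref, offset)):
            continue
        cat = categorize_entry(ev, offset, params.e_max)
        first_vt = ev[0][0] if ev else -1
        entry = KmerEntry(cat, pos_ref, offset, first_vt, ev)
        buckets[cat].append((text.encode("ascii"), entry))
    subs = []
    for cat, bucket in enumerate(buckets):
        bucket.sort(key=lambda te: (te[0], te[1].pos_ref, te[1].offset,
                                    te[1].first_vt, te[1].evidence))
        texts = [t for t, _ in bucket]
        entries = [e for _, e in bucket]
        subs.append(KmerSubarray(texts, entries, min(params.lut_width, params.k)))
    return subs


def sparsify(subarrays: list[KmerSubarray], d: int, vd: VariantDatabase,
             lut_width: int) -> list[KmerSubarray]:
    """Keep kMA0/kMA1 entries whose start position is a multiple of d; kMA1
    additionally keeps windows that begin with a present DEL/INS/SV anchored
    at the window start.  kMA2/kMA3 are unchanged."""
    if d == 1:
        return subarrays
    out = []
    for cat, sub in enumerate(subarrays):
        if cat >= 2:
            out.append(sub)
            continue
        texts, entries = [], []
        for t, e in zip(sub.texts, sub.entries):
            keep = e.pos_ref % d == 0
            if not keep and cat == 1:
                vid, flag = e.evidence[0]
                v = vd[vid]
                if flag == 1 and v.kind in (DEL, INS, SV) \
                        and v.effect_pos == e.pos_ref:
                    keep = True
            if keep:
                texts.append(t)
                entries.append(e)
        out.append(KmerSubarray(texts, entries, lut_width))
    return out


# ---------------------------------------------------------------------------
# Entry replay: reconstruct a window's text and decoding state
# ---------------------------------------------------------------------------

def replay_entry(ref, vd: VariantDatabase, entry: KmerEntry, p: int,
                 chrom_lo: int, chrom_hi: int
                 ) -> tuple[str, DecodingState]:
    """Decode ``p`` characters of the entry's window along its recorded path.

    Returns the text together with the cursor state needed to extend further
    right (and the start boundary information needed to extend left).  For
    category-0 entries the zero evidence of every decided variant is
    reconstructed on the fly.
    """
    decisions = dict(entry.evidence)
    ev = implied_evidence(vd, entry.pos_ref, entry.offset, entry.first_vt)
    text: list[str] = []
    eff = vd.eff
    nv = len(vd)
    in_ins: tuple[int, int] | None = None
    start_proj = None
    left_ceiling = _INF

    if entry.offset > 0:
        v = vd[entry.first_vt]
        ev[v.id] = 1
        start_proj = (v.effect_pos, entry.offset)
        ins = v.ins_seq
        for j in range(entry.offset - 1, len(ins)):
            text.append(ins[j])
            if len(text) == p:
                if j + 1 < len(ins):
                    in_ins = (v.id, j + 1)
                break
        pos = v.effect_pos + (v.del_len if v.kind == SV else 0)
        vt = v.id + 1
    else:
        pos = entry.pos_ref
        vt = vd.first_at_or_after(entry.pos_ref)

    while len(text) < p:
        if vt < nv and eff[vt] <= pos:
            v = vd.variants[vt]
            if v.effect_pos == pos:
                if not text and entry.offset == 0 and v.kind == INS:
                    vt += 1   # precedes the window, no evidence
                    continue
                if not text and entry.offset == 0 and v.kind == SV:
                    ev[vt] = 0
                    vt += 1
                    continue
                flag = decisions.get(vt, 0)
                ev[vt] = flag
                if flag:
                    if not text and v.emit and v.adv > 0:
                        # first char produced by a consuming variant (SNP):
                        # only smaller-id insertions may sit left-adjacent
                        left_ceiling = vt
                    for j, c in enumerate(v.emit):
                        text.append(c)
                        if len(text) == p:
                            if v.inserts and j + 1 < len(v.emit):
                                in_ins = (vt, j + 1)
                            break
                    if text and start_proj is None:
                        start_proj = ((v.effect_pos, j + 1) if v.inserts
                                      else (v.effect_pos, 0))
                    pos += v.adv
                vt += 1
            else:
                new = v.effect_pos + v.adv
                if new > pos:
                    flag = decisions.get(vt, 0)
                    ev[vt] = flag
                    if flag:
                        for j, c in enumerate(v.emit):
                            text.append(c)
                            if len(text) == p:
                                if v.inserts and j + 1 < len(v.emit):
                                    in_ins = (vt, j + 1)
                                break
                        pos = new
                vt += 1
        else:
            if pos >= chrom_hi:
                break
            if start_proj is None:
                start_proj = (pos, 0)
            text.append(chr(ref[pos]))
            pos += 1

    state = DecodingState(pos_curr=pos, vt_curr=vt, evidence=ev,
                          in_ins=in_ins, chars_done=len(text),
                          start_proj=start_proj, left_ceiling=left_ceiling)
    return "".join(text), state
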