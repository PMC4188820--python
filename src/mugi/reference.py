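"""Packed reference sequence and chromosome coordinate table.

The collection is represented against a single concatenated reference: every
chromosome is appended into one global 0-based coordinate space and a
:class:`ChromosomeTable` maps global positions back to per-chromosome
coordinates.  The sequence itself is stored 4 bits per base (two bases per
byte), which keeps random access trivial while halving memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# 4-bit nucleotide codes.  Values are arbitrary but fixed: they are written
# into the serialized index container.
_CODE = {"A": 1, "C": 2, "G": 3, "T": 4, "N": 15}
_CHAR = {v: k for k, v in _CODE.items()}

ALPHABET = frozenset("ACGTN")


class ReferenceError(ValueError):
    """Malformed reference sequence or out-of-range access."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    global_start: int
    length: int

    @property
    def global_end(self) -> int:
        return self.global_start + self.length


class ChromosomeTable:
    """Ordered chromosome intervals over the concatenated coordinate space."""

    def __init__(self, entries):
        self.entries: list[Chromosome] = list(entries)
        names = [c.name for c in self.entries]
        if len(set(names)) != len(names):
            raise ReferenceError("duplicate chromosome name in table")
        prev_end = 0
        for c in self.entries:
            if c.global_start != prev_end or c.length <= 0:
                raise ReferenceError("chromosome intervals must tile the global space")
            prev_end = c.global_end
        self._starts = np.array([c.global_start for c in self.entries], dtype=np.int64)
        self.total_length = prev_end

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromosomeTable) and self.entries == other.entries

    def by_name(self, name: str) -> Chromosome:
        for c in self.entries:
            if c.name == name:
                return c
        raise KeyError(name)

    def locate(self, global_pos: int) -> Chromosome:
        """Chromosome containing ``global_pos`` (end positions map to the
        chromosome they terminate, so an insertion anchored at a chromosome
        end still resolves)."""
        i = int(np.searchsorted(self._starts, global_pos, side="right")) - 1
        if i < 0 or global_pos > self.entries[i].global_end:
            raise ReferenceError(f"global position {global_pos} outside reference")
        return self.entries[i]

    def to_local(self, global_pos: int) -> tuple[str, int]:
        c = self.locate(global_pos)
        return c.name, global_pos - c.global_start


class PackedReference:
    """Concatenated reference, 4 bits per base."""

    def __init__(self, sequence: str | bytes):
        if isinstance(sequence, bytes):
            sequence = sequence.decode("ascii")
        bad = set(sequence) - ALPHABET
        if bad:
            raise ReferenceError(f"non-nucleotide character(s) {sorted(bad)!r} in reference")
        self.length = len(sequence)
        codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
        lut = np.zeros(256, dtype=np.uint8)
        for ch, code in _CODE.items():
            lut[ord(ch)] = code
        codes = lut[codes]
        if self.length % 2:
            codes = np.append(codes, np.uint8(0))
        self._packed = (codes[0::2] << 4) | codes[1::2]
        # Cache the plain bytes: queries slice constantly and the packed form
        # is the storage contract, not the hot path.
        self._bytes = sequence.encode("ascii")

    @classmethod
    def from_packed(cls, packed: np.ndarray, length: int) -> "PackedReference":
        codes = np.empty(2 * len(packed), dtype=np.uint8)
        codes[0::2] = packed >> 4
        codes[1::2] = packed & 0x0F
        codes = codes[:length]
        chars = np.zeros(16, dtype=np.uint8)
        for code, ch in _CHAR.items():
            chars[code] = ord(ch)
        obj = cls.__new__(cls)
        obj.length = length
        obj._packed = np.asarray(packed, dtype=np.uint8)
        obj._bytes = chars[codes].tobytes()
        return obj

    @property
    def packed(self) -> np.ndarray:
        return self._packed

    def get(self, i: int) -> str:
        if not 0 <= i < self.length:
            raise ReferenceError(f"reference position {i} out of range [0, {self.length})")
        return chr(self._bytes[i])

    def slice(self, start: int, end: int) -> bytes:
        return self._bytes[start:end]

    def __len__(self) -> int:
        return self.length

    def __getitem__(self, i: int) -> int:
        """Raw byte (ASCII code) at position ``i`` — hot-path access."""
        return self._bytes[i]

    def to_string(self) -> str:
        return self._bytes.decode("ascii")
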