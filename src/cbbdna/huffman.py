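"""Static n-ary Huffman coding over bytes, for barcode compression.

Barcodes must be deterministic, so the code is *static*: one fixed
frequency profile, shipped as a constant, is used for every encode. The
profile favours printable ASCII the way attribute names and rendered
values look in practice (digits and '=' are common because every mapped
string has the shape ``value=emanetubirtta``); all other byte values get
weight 1 so the code covers the full byte range. A reserved end symbol
terminates every encoded string, which lets the decoder ignore whatever
trailing digits the DNA framing produces.

The same profile yields codes of base 2, 3 or 4 depending on the DNA
converter in use. Tie-breaking during tree construction is by insertion
order over symbols sorted numerically, making the table a pure function
of (base, frequency profile).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

from .errors import DecodeError

END_SYMBOL = 256  # reserved terminator, outside the byte range

FREQUENCY_TABLE_VERSION = "ascii-en-digits/1"

# per-mille English letter frequencies (x10), digits and the punctuation
# that attribute/value strings actually contain.
_LETTER_WEIGHTS = {
    "e": 1270, "t": 906, "a": 817, "o": 751, "i": 697, "n": 675, "s": 633,
    "h": 609, "r": 599, "d": 425, "l": 403, "c": 278, "u": 276, "m": 241,
    "w": 236, "f": 223, "g": 202, "y": 197, "p": 193, "b": 149, "v": 98,
    "k": 77, "j": 15, "x": 15, "q": 10, "z": 7,
}


def _build_frequencies() -> dict:
    freqs = {b: 1 for b in range(256)}
    for ch, w in _LETTER_WEIGHTS.items():
        freqs[ord(ch)] = w
        freqs[ord(ch.upper())] = max(1, w // 3)
    for d in "0123456789":
        freqs[ord(d)] = 800
    freqs[ord(" ")] = 1000
    freqs[ord("=")] = 800  # present in every mapped attribute/value string
    freqs[ord(".")] = 400  # segment-index suffixes
    for ch in ",-_:/":
        freqs[ord(ch)] = 150
    freqs[END_SYMBOL] = 1
    return freqs


DEFAULT_FREQUENCIES = _build_frequencies()


@dataclass(frozen=True)
class HuffmanTable:
    """A prefix-free code over the 256 byte values plus the end symbol."""

    base: int
    code_map: dict  # symbol -> tuple of digits in range(base)

    def __post_init__(self):
        if self.base not in (2, 3, 4):
            raise ValueError("supported code bases are 2, 3 and 4")

    @classmethod
    def build(cls, base: int, frequencies: dict = None) -> "HuffmanTable":
        freqs = dict(frequencies or DEFAULT_FREQUENCIES)
        symbols = sorted(freqs)
        # pad with zero-weight dummies so every internal node is full
        n_dummy = 0
        if base > 2:
            while (len(symbols) + n_dummy - 1) % (base - 1) != 0:
                n_dummy += 1
        heap = []
        order = 0
        for sym in symbols:
            heap.append((freqs[sym], order, sym))
            order += 1
        for d in range(n_dummy):
            heap.append((0, order, ("dummy", d)))
            order += 1
        heapq.heapify(heap)
        while len(heap) > 1:
            children = [heapq.heappop(heap) for _ in range(min(base, len(heap)))]
            weight = sum(c[0] for c in children)
            node = tuple(c[2] for c in children)
            heapq.heappush(heap, (weight, order, node))
            order += 1
        root = heap[0][2]
        code_map = {}

        def walk(node, prefix):
            if isinstance(node, int):
                code_map[node] = tuple(prefix)
                return
            if isinstance(node, tuple) and node and node[0] == "dummy":
                return
            for digit, child in enumerate(node):
                walk(child, prefix + [digit])

        walk(root, [])
        return cls(base=base, code_map=code_map)

    def decode_trie(self) -> dict:
        trie = {}
        for sym, code in self.code_map.items():
            node = trie
            for d in code[:-1]:
                node = node.setdefault(d, {})
            node[code[-1]] = sym
        return trie


def huffman_encode(text: str, table: HuffmanTable):
    """UTF-8 bytes -> concatenated codewords -> digit list, end-terminated."""
    digits = []
    for byte in text.encode("utf-8"):
        digits.extend(table.code_map[byte])
    digits.extend(table.code_map[END_SYMBOL])
    return digits


def huffman_decode(digits, table: HuffmanTable) -> str:
    """Inverse of :func:`huffman_encode`; ignores digits after the end symbol."""
    trie = table.decode_trie()
    out = bytearray()
    node = trie
    for d in digits:
        nxt = node.get(d)
        if nxt is None:
            raise DecodeError("invalid Huffman digit stream")
        if isinstance(nxt, dict):
            node = nxt
            continue
        if nxt == END_SYMBOL:
            return out.decode("utf-8")
        out.append(nxt)
        node = trie
    raise DecodeError("Huffman stream ended without the end symbol")
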