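"""Splitting over-long Info-DNA across m fixed-length oligos.

Each segment oligo reserves c bases for framing/padding and r_off bases
for the permutation offset, so the usable capacity per segment is
L_Info - c - r_off and the segment count is

    m = ceil(|seq| / (L_Info - c - r_off)).

Slices are uniform: segment i (1-based) starts at the 0-based index
(i-1) * ceil(|seq|/m) and spans ceil(|seq|/m) bases (the final slice may
be shorter); their concatenation is exactly the original sequence. A
separate header oligo stores m (plus the attribute/value pair needed to
derive the segment barcodes) as its own fountain-coded Info-DNA, and each
segment i is barcoded with the base value suffixed ``.i``.

The reassembly path is gap-tolerant: because slice geometry follows from
m and the message header at the start of slice 1, a missing non-leading
segment only removes the packets that overlap it, and the fountain
redundancy can absorb the loss. The strict :func:`assemble` contract
(all m segments or an error) is kept for callers that need it.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError, DecodeError, IncompleteSegmentSetError
from . import info as info_codec


def segment_count(seq_len: int, l_info: int, c: int, r_off: int) -> int:
    """m = ceil(seq_len / (L_Info - c - r_off)); 0 for an empty payload."""
    capacity = l_info - c - r_off
    if capacity < 1:
        raise ConfigError(
            f"segment capacity L_Info - c - r_off = {capacity} must be >= 1"
        )
    if seq_len < 0:
        raise ValueError("sequence length cannot be negative")
    return -(-seq_len // capacity)


def slice_length(seq_len: int, m: int) -> int:
    return -(-seq_len // m)


def split_payload(seq: str, m: int):
    """Slice *seq* into m pieces under the uniform start-index rule."""
    if m < 1:
        raise ValueError("m must be >= 1")
    s = slice_length(len(seq), m)
    return [seq[(i - 1) * s : (i - 1) * s + s] for i in range(1, m + 1)]


def assemble(segments) -> str:
    """Concatenate inverse-transformed segment bodies, strictly.

    *segments* is a sequence of m bodies in index order; ``None`` marks a
    missing segment and triggers :class:`IncompleteSegmentSetError` naming
    the 1-based indices.
    """
    missing = [i + 1 for i, s in enumerate(segments) if s is None]
    if missing:
        raise IncompleteSegmentSetError(missing)
    return "".join(segments)


def assemble_with_gaps(bodies: dict, m: int):
    """Best-effort reassembly from a partial segment set.

    *bodies* maps 1-based segment index to the inverse-transformed slice.
    Returns ``(chars, mask)`` where *mask* flags bases belonging to missing
    segments; the pair feeds :func:`cbbdna.info.decode_info`. Slice 1 must
    be present (it holds the message header, from which the true total
    length is read back and the arrays trimmed).
    """
    present = sorted(i for i in bodies if 1 <= i <= m)
    if not present:
        raise IncompleteSegmentSetError(range(1, m + 1))
    missing = [i for i in range(1, m + 1) if i not in bodies]
    if m == 1:
        body = bodies[1]
        return np.array(list(body), dtype="U1"), np.zeros(len(body), dtype=bool)
    if 1 not in bodies:
        raise IncompleteSegmentSetError(
            missing, "segment 1 (message header) is missing"
        )
    s = len(bodies[1])
    if s < 1:
        raise DecodeError("empty leading segment")
    for i in present[:-1] if present[-1] == m else present:
        if i < m and len(bodies[i]) != s:
            raise DecodeError(
                f"segment {i} has {len(bodies[i])} bases, expected {s}"
            )
    # upper bound m*s, trimmed after the header reveals the true length
    total_cap = s * m
    chars = np.full(total_cap, "A", dtype="U1")
    mask = np.ones(total_cap, dtype=bool)
    for i in present:
        start = (i - 1) * s
        piece = bodies[i]
        chars[start : start + len(piece)] = list(piece)
        mask[start : start + len(piece)] = False
    if info_codec.HEADER_BASES > s and 2 not in bodies:
        raise IncompleteSegmentSetError(missing, "message header spans a gap")
    off = info_codec._W_VERSION
    count, off = info_codec._read_field(chars, mask, off, info_codec._W_COUNT)
    symbol_size, _ = info_codec._read_field(chars, mask, off, info_codec._W_SYMSIZE)
    total = info_codec.expected_total_length(count, symbol_size)
    if total > total_cap or total < (m - 1) * s:
        raise DecodeError("segment geometry inconsistent with message header")
    return chars[:total], mask[:total]
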