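"""Info-DNA codec: serialization, compression, fountain coding, framing.

An Info-DNA message is produced in stages:

    bytes -> CRC32 append -> fountain repair packets -> C1/C2 filter
          -> quaternary header + per-packet (ESI, payload) DNA

Header layout (fixed-width base-4 numerals, digit map 0A 1C 2G 3T):

    version          2 bases   (currently 1)
    packet count     8 bases
    symbol size      8 bases   (bytes)
    transfer length 16 bases   (bytes, CRC included)

followed, per packet, by an 8-base ESI and the payload mapped 2 bits per
base (00A 01T 10C 11G). The trailing CRC32 turns any undetected channel
corruption into a reported decode failure instead of a silently wrong
record. The packet filter keeps only repair packets whose payload DNA
passes C1/C2 and stops once k + epsilon survivors exist *and* a trial
decode of exactly those survivors succeeds.

The byte-level serializers used above this layer are here too:
``pack_record`` (length-prefixed canonical text per attribute, then raw
DEFLATE) and ``compress_id_list`` (sorted ids as first + deltas in LEB128
varints, then raw DEFLATE). DEFLATE is raw, level 9, no metadata, so
output is byte-deterministic across runs and platforms.
"""

from __future__ import annotations

import zlib

import numpy as np

from . import fountain
from .config import CodecConfig
from .constraints import ConstraintThresholds, check_c1_c2, validate_dna
from .errors import DecodeError, InsufficientPacketsError, UnencodableError
from .transforms import decode_quaternary, encode_quaternary

HEADER_VERSION = 1
_W_VERSION, _W_COUNT, _W_SYMSIZE, _W_TRANSFER, _W_ESI = 2, 8, 8, 16, 8
HEADER_BASES = _W_VERSION + _W_COUNT + _W_SYMSIZE + _W_TRANSFER
FOUNTAIN_CODEC_ID = "rlf256/1"  # random-linear fountain over GF(256)

_BIT_PAIRS = ("A", "T", "C", "G")  # index = (bit1 << 1) | bit0 of the pair
_PAIR_MAP = {"00": "A", "01": "T", "10": "C", "11": "G"}
_PAIR_INV = {v: k for k, v in _PAIR_MAP.items()}


# ---------------------------------------------------------------------------
# varints
# ---------------------------------------------------------------------------


def encode_varint(value: int) -> bytes:
    """Unsigned LEB128."""
    if value < 0:
        raise ValueError("varints encode non-negative integers only")
    out = bytearray()
    while True:
        byte = value & 0x7F
        value >>= 7
        if value:
            out.append(byte | 0x80)
        else:
            out.append(byte)
            return bytes(out)


def decode_varint(data: bytes, offset: int = 0) -> tuple:
    """Return ``(value, next_offset)``."""
    value, shift = 0, 0
    while True:
        if offset >= len(data):
            raise DecodeError("truncated varint")
        byte = data[offset]
        offset += 1
        value |= (byte & 0x7F) << shift
        if not byte & 0x80:
            return value, offset
        shift += 7


# ---------------------------------------------------------------------------
# deterministic DEFLATE
# ---------------------------------------------------------------------------


def deflate(data: bytes) -> bytes:
    comp = zlib.compressobj(9, zlib.DEFLATED, -15)
    return comp.compress(data) + comp.flush()


def inflate(data: bytes) -> bytes:
    try:
        return zlib.decompress(data, -15)
    except zlib.error as exc:
        raise DecodeError(f"DEFLATE stream corrupt: {exc}") from exc


# ---------------------------------------------------------------------------
# record and posting-list serialization
# ---------------------------------------------------------------------------


def pack_record(record, fields) -> bytes:
    """Serialize *record* (a mapping) over the named *fields*, in order.

    Each value is rendered to canonical text, UTF-8 encoded and
    length-prefixed with a varint; the concatenation is DEFLATE'd.
    """
    from .cbb import canonical_text

    out = bytearray()
    for name in fields:
        if name not in record:
            raise KeyError(f"record is missing attribute {name!r}")
        blob = canonical_text(record[name]).encode("utf-8")
        out += encode_varint(len(blob)) + blob
    return deflate(bytes(out))


def unpack_record(data: bytes, fields) -> dict:
    """Inverse of :func:`pack_record`; values come back as text."""
    raw = inflate(data)
    record, offset = {}, 0
    for name in fields:
        length, offset = decode_varint(raw, offset)
        if offset + length > len(raw):
            raise DecodeError("record payload truncated")
        record[name] = raw[offset : offset + length].decode("utf-8")
        offset += length
    if offset != len(raw):
        raise DecodeError("trailing bytes after last record attribute")
    return record


def delta_encode_ids(ids) -> bytes:
    """Sorted first value + successive deltas, LEB128 (pre-compression)."""
    ids = sorted(ids)
    if not ids:
        raise ValueError("id list must be non-empty")
    if ids[0] < 0:
        raise ValueError("ids must be non-negative")
    out = bytearray(encode_varint(ids[0]))
    for prev, cur in zip(ids, ids[1:]):
        out += encode_varint(cur - prev)
    return bytes(out)


def compress_id_list(ids) -> bytes:
    return deflate(delta_encode_ids(ids))


def decompress_id_list(data: bytes) -> list:
    raw = inflate(data)
    ids, offset = [], 0
    while offset < len(raw):
        delta, offset = decode_varint(raw, offset)
        ids.append(delta if not ids else ids[-1] + delta)
    if not ids:
        raise DecodeError("empty posting list payload")
    return ids


# ---------------------------------------------------------------------------
# bit <-> base mapping
# ---------------------------------------------------------------------------


def bits_to_dna(bits: str) -> str:
    """Map consecutive bit pairs 00A 01T 10C 11G."""
    if len(bits) % 2:
        raise ValueError("bit string length must be even")
    try:
        return "".join(_PAIR_MAP[bits[i : i + 2]] for i in range(0, len(bits), 2))
    except KeyError:
        raise ValueError("bit string may contain only '0' and '1'") from None


def dna_to_bits(seq: str) -> str:
    validate_dna(seq)
    return "".join(_PAIR_INV[b] for b in seq)


_BYTE_TO_DNA = None


def _byte_table():
    global _BYTE_TO_DNA
    if _BYTE_TO_DNA is None:
        _BYTE_TO_DNA = [bits_to_dna(format(b, "08b")) for b in range(256)]
    return _BYTE_TO_DNA


def bytes_to_dna(data: bytes) -> str:
    table = _byte_table()
    return "".join(table[b] for b in data)


def dna_to_bytes(seq: str) -> bytes:
    if len(seq) % 4:
        raise ValueError("DNA byte string length must be a multiple of 4")
    bits = dna_to_bits(seq)
    return bytes(int(bits[i : i + 8], 2) for i in range(0, len(bits), 8))


# ---------------------------------------------------------------------------
# packet filtering and message framing
# ---------------------------------------------------------------------------


def choose_symbol_size(transfer_length: int, config: CodecConfig) -> int:
    """Symbol size in bytes: at least ``min_symbol_size`` and large enough
    that k = ceil(transfer_length / symbol_size) <= max_source_symbols."""
    need = -(-transfer_length // config.max_source_symbols)
    return max(config.min_symbol_size, need)


def packet_dna(packet: fountain.Packet) -> str:
    """ESI numeral plus 2-bit-mapped payload."""
    return encode_quaternary(packet.esi, _W_ESI) + bytes_to_dna(packet.payload)


def filter_packets(
    message: bytes,
    symbol_size: int,
    thresholds: ConstraintThresholds,
    needed: int,
    batch: int = 8,
    cap_factor: int = 100,
):
    """Generate repair packets until *needed* C1/C2-clean survivors exist
    and a trial decode of the survivors succeeds.

    The C1/C2 check applies to the packet *payload* DNA (the fixed-width
    ESI numeral is framing, like the message header, and is smoothed out
    by the later whole-segment permutation). A design cap of
    ``cap_factor * k`` generated packets bounds the search; hitting it
    raises :class:`UnencodableError`.
    """
    k = fountain.source_symbol_count(len(message), symbol_size)
    cap = max(cap_factor * k, cap_factor)
    survivors = []
    esi = k
    while True:
        if esi - k >= cap:
            raise UnencodableError(
                f"no {needed}-packet constraint-satisfying set found after "
                f"generating {esi - k} repair packets"
            )
        for p in fountain.generate_repair_packets(
            message, symbol_size, count=batch, start_esi=esi
        ):
            if check_c1_c2(bytes_to_dna(p.payload), thresholds).passed:
                survivors.append(p)
        esi += batch
        if len(survivors) >= needed:
            try:
                fountain.decode(survivors[:needed], len(message), symbol_size)
            except InsufficientPacketsError:
                needed += 1  # extremely rare with dense GF(256) coefficients
                continue
            return survivors[:needed]


def encode_info(payload: bytes, config: CodecConfig, epsilon: int = None) -> str:
    """Encode *payload* into header + packet DNA (pre-framing/permutation).

    *epsilon* overrides the configured redundancy (used e.g. to cap a
    segment-count header's packet count to its oligo's capacity).
    """
    message = payload + (zlib.crc32(payload) & 0xFFFFFFFF).to_bytes(4, "big")
    transfer_length = len(message)
    symbol_size = choose_symbol_size(transfer_length, config)
    k = fountain.source_symbol_count(transfer_length, symbol_size)
    eps = config.epsilon if epsilon is None else epsilon
    packets = filter_packets(
        message, symbol_size, config.thresholds, needed=k + eps
    )
    for width, value, name in (
        (_W_COUNT, len(packets), "packet count"),
        (_W_SYMSIZE, symbol_size, "symbol size"),
        (_W_TRANSFER, transfer_length, "transfer length"),
        (_W_ESI, packets[-1].esi, "ESI"),
    ):
        if value >= 4**width:
            raise UnencodableError(f"{name} {value} exceeds its header field")
    parts = [
        encode_quaternary(HEADER_VERSION, _W_VERSION),
        encode_quaternary(len(packets), _W_COUNT),
        encode_quaternary(symbol_size, _W_SYMSIZE),
        encode_quaternary(transfer_length, _W_TRANSFER),
    ]
    parts.extend(packet_dna(p) for p in packets)
    return "".join(parts)


def info_dna_length(payload_length: int, config: CodecConfig) -> int:
    """Length in bases of :func:`encode_info` output, before filtering can
    add packets (the usual case: exactly k + epsilon survivors)."""
    transfer = payload_length + 4
    symbol_size = choose_symbol_size(transfer, config)
    k = fountain.source_symbol_count(transfer, symbol_size)
    return HEADER_BASES + (k + config.epsilon) * (_W_ESI + 4 * symbol_size)


def _read_field(chars, mask, start, width):
    if mask is not None and mask[start : start + width].any():
        raise DecodeError("message header overlaps a missing region")
    return decode_quaternary("".join(chars[start : start + width])), start + width


def decode_info(dna, config: CodecConfig = None, missing_mask=None) -> bytes:
    """Inverse of :func:`encode_info`.

    *dna* may be a string or a character array; *missing_mask* marks bases
    lost to erasure (packets overlapping a masked base are discarded, the
    header must be intact). Raises :class:`InsufficientPacketsError` when
    fewer than k packets survive and :class:`DecodeError` on structural or
    checksum failure.
    """
    if isinstance(dna, str):
        chars = np.array(list(dna), dtype="U1")
    else:
        chars = np.asarray(dna, dtype="U1")
    mask = None if missing_mask is None else np.asarray(missing_mask, dtype=bool)
    if len(chars) < HEADER_BASES:
        raise DecodeError("Info-DNA shorter than its header")
    pos = 0
    version, pos = _read_field(chars, mask, pos, _W_VERSION)
    if version != HEADER_VERSION:
        raise DecodeError(f"unsupported Info-DNA header version {version}")
    count, pos = _read_field(chars, mask, pos, _W_COUNT)
    symbol_size, pos = _read_field(chars, mask, pos, _W_SYMSIZE)
    transfer_length, pos = _read_field(chars, mask, pos, _W_TRANSFER)
    if count < 1 or symbol_size < 1 or transfer_length < 5:
        raise DecodeError("implausible Info-DNA header")
    packet_bases = _W_ESI + 4 * symbol_size
    if pos + count * packet_bases > len(chars):
        raise DecodeError("Info-DNA truncated relative to its header")
    packets = []
    for _ in range(count):
        end = pos + packet_bases
        if mask is None or not mask[pos:end].any():
            esi = decode_quaternary("".join(chars[pos : pos + _W_ESI]))
            payload = dna_to_bytes("".join(chars[pos + _W_ESI : end]))
            packets.append(fountain.Packet(esi=esi, payload=payload))
        pos = end
    message = fountain.decode(packets, transfer_length, symbol_size)
    payload, crc = message[:-4], message[-4:]
    if (zlib.crc32(payload) & 0xFFFFFFFF).to_bytes(4, "big") != crc:
        raise DecodeError("payload checksum mismatch")
    return payload


def expected_total_length(count: int, symbol_size: int) -> int:
    return HEADER_BASES + count * (_W_ESI + 4 * symbol_size)
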