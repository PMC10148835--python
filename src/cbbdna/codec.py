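"""The assembled codec: configuration-bound encode/decode machinery.

:class:`Codec` binds a :class:`~cbbdna.config.CodecConfig` to its derived
state (padding bank, Huffman table, converter) and exposes the complete
per-object pipeline: an (attribute, value, message) triple becomes either
one oligo or a header oligo plus m segment oligos, and the reverse path
turns fetched Info-DNA parts back into message bytes.

Message framing: every fountain-coded payload starts with a 1-byte tag so
a pool is decodable with no stored object index:

    0x00  record          all schema attributes of one row, packed
    0x01  posting list    compressed primary keys sharing one value
    0x02  segment header  (m, attribute, value) of a segmented message

The segment header embeds the attribute/value pair, which is what lets a
full-table decode (and the gap-tolerant query path) re-derive the m
segment barcodes without any in-silico mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import fountain
from . import info as info_codec
from . import segmentation
from .cbb import canonical_text, derive_segment_cbb, encode_cbb, get_converter
from .config import CodecConfig
from .errors import CodecError, DecodeError, SegmentationRequiredError
from .huffman import FREQUENCY_TABLE_VERSION, HuffmanTable
from ._prng import mix64
from .transforms import (
    MARKER_SEGMENTED,
    MARKER_SINGLE,
    PaddingBank,
    transform_forward,
    transform_inverse,
)

TAG_RECORD = 0x00
TAG_POSTING = 0x01
TAG_SEGMENT_HEADER = 0x02

_BANK_TWEAK = 0x62616E6B  # "bank"


@dataclass(frozen=True)
class EncodedObject:
    """Oligos produced for one (attribute, value, message) triple."""

    cbbs: tuple  # barcode of each oligo; index 0 is the header when segmented
    info_parts: tuple  # matching Info-DNA parts, each of length L_Info
    segmented: bool

    def oligos(self):
        return [c + i for c, i in zip(self.cbbs, self.info_parts)]


class Codec:
    """All encode/decode operations for one configuration."""

    def __init__(self, config: CodecConfig):
        self.config = config
        bank_len = max(config.l_cbb, config.l_info)
        self.bank = PaddingBank.generate(
            length=bank_len,
            max_homopolymer=config.thresholds.max_homopolymer,
            seed=mix64(config.master_seed ^ _BANK_TWEAK),
        )
        self.huffman = HuffmanTable.build(get_converter(config.converter).base)
        self._cbb_cache = {}

    # -- barcodes -----------------------------------------------------------

    def encode_cbb(self, attribute: str, value) -> str:
        key = (attribute, canonical_text(value))
        hit = self._cbb_cache.get(key)
        if hit is None:
            hit = encode_cbb(attribute, value, self.config, self.bank, self.huffman)
            self._cbb_cache[key] = hit
        return hit

    def segment_cbb(self, attribute: str, value, index: int) -> str:
        key = (attribute, canonical_text(value), index)
        hit = self._cbb_cache.get(key)
        if hit is None:
            hit = derive_segment_cbb(
                attribute, value, index, self.config, self.bank, self.huffman
            )
            self._cbb_cache[key] = hit
        return hit

    # -- message framing ----------------------------------------------------

    @staticmethod
    def record_message(record, fields) -> bytes:
        return bytes([TAG_RECORD]) + info_codec.pack_record(record, fields)

    @staticmethod
    def posting_message(ids) -> bytes:
        return bytes([TAG_POSTING]) + info_codec.compress_id_list(ids)

    @staticmethod
    def header_message(m: int, attribute: str, value) -> bytes:
        a = attribute.encode("utf-8")
        v = canonical_text(value).encode("utf-8")
        return (
            bytes([TAG_SEGMENT_HEADER])
            + info_codec.encode_varint(m)
            + info_codec.encode_varint(len(a))
            + a
            + info_codec.encode_varint(len(v))
            + v
        )

    @staticmethod
    def parse_message(message: bytes) -> tuple:
        """Return ``(tag, body)``; for segment headers the body is the
        decoded ``(m, attribute, value)`` triple."""
        if not message:
            raise DecodeError("empty message")
        tag, body = message[0], message[1:]
        if tag == TAG_SEGMENT_HEADER:
            m, off = info_codec.decode_varint(body)
            alen, off = info_codec.decode_varint(body, off)
            attribute = body[off : off + alen].decode("utf-8")
            off += alen
            vlen, off = info_codec.decode_varint(body, off)
            value = body[off : off + vlen].decode("utf-8")
            return tag, (m, attribute, value)
        if tag in (TAG_RECORD, TAG_POSTING):
            return tag, body
        raise DecodeError(f"unknown message tag {tag:#x}")

    # -- transforms bound to the config -------------------------------------

    def _forward(self, body: str, target: int, marker: str) -> str:
        cfg = self.config
        return transform_forward(
            body, target, marker, cfg.n_permutations, cfg.r_off,
            self.bank, cfg.weights, cfg.thresholds,
        )

    def inverse_info(self, info_part: str) -> tuple:
        """Invert an oligo's Info-DNA part; returns ``(body, marker)``."""
        cfg = self.config
        return transform_inverse(info_part, cfg.n_permutations, cfg.r_off)

    # -- object-level encoding ----------------------------------------------

    @property
    def single_capacity(self) -> int:
        """Longest Info-DNA body that still fits one oligo (framing incl.)."""
        return self.config.l_info - self.config.r_off - 3

    def encode_object(self, attribute: str, value, message: bytes) -> EncodedObject:
        """Encode one message under its (attribute, value) barcode.

        Produces a single oligo when the fountain-coded DNA fits, and a
        header oligo plus m segment oligos otherwise.
        """
        cfg = self.config
        dna = info_codec.encode_info(message, cfg)
        target = cfg.l_info - cfg.r_off
        if len(dna) <= self.single_capacity:
            part = self._forward(dna, target, MARKER_SINGLE)
            return EncodedObject(
                cbbs=(self.encode_cbb(attribute, value),),
                info_parts=(part,),
                segmented=False,
            )
        m = segmentation.segment_count(
            len(dna), cfg.l_info, cfg.c_pad_reserve, cfg.r_off
        )
        header = self._encode_header(m, attribute, value)
        cbbs = [self.encode_cbb(attribute, value)]
        parts = [self._forward(header, target, MARKER_SEGMENTED)]
        for i, piece in enumerate(segmentation.split_payload(dna, m), start=1):
            cbbs.append(self.segment_cbb(attribute, value, i))
            try:
                parts.append(self._forward(piece, target, MARKER_SEGMENTED))
            except SegmentationRequiredError as exc:  # pragma: no cover
                raise CodecError(f"segment {i} exceeds its capacity") from exc
        return EncodedObject(
            cbbs=tuple(cbbs), info_parts=tuple(parts), segmented=True
        )

    def _encode_header(self, m: int, attribute: str, value) -> str:
        """Fountain-code the segment-count header, capping its redundancy
        so it always fits a single oligo."""
        cfg = self.config
        message = self.header_message(m, attribute, value)
        symbol_size = info_codec.choose_symbol_size(len(message) + 4, cfg)
        k = fountain.source_symbol_count(len(message) + 4, symbol_size)
        room = (self.single_capacity - info_codec.HEADER_BASES) // (
            info_codec._W_ESI + 4 * symbol_size
        )
        if room < k:
            raise CodecError(
                "segment-count header does not fit one oligo; "
                "raise L_Oligo or shorten attribute/value names"
            )
        header = info_codec.encode_info(
            message, cfg, epsilon=min(cfg.epsilon, room - k)
        )
        if len(header) > self.single_capacity:  # filtering added packets
            raise CodecError("segment-count header does not fit one oligo")
        return header

    # -- object-level decoding ----------------------------------------------

    def decode_single(self, info_part: str) -> tuple:
        """Decode an unsegmented (or header) Info-DNA part.

        Returns ``(tag, body, marker)`` as in :meth:`parse_message`.
        """
        body, marker = self.inverse_info(info_part)
        tag, parsed = self.parse_message(info_codec.decode_info(body))
        return tag, parsed, marker

    def decode_segments(self, bodies: dict, m: int) -> tuple:
        """Decode a (possibly partial) segment set.

        *bodies* maps 1-based indices to inverse-transformed slices.
        """
        chars, mask = segmentation.assemble_with_gaps(bodies, m)
        message = info_codec.decode_info(chars, missing_mask=mask)
        return self.parse_message(message)

    # -- metadata ------------------------------------------------------------

    def metadata(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "fountain_codec": info_codec.FOUNTAIN_CODEC_ID,
            "huffman_frequencies": FREQUENCY_TABLE_VERSION,
            "padding_bank_seed": self.bank.generation_seed,
        }
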