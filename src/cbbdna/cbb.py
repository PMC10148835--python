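"""Content-based barcodes (CBBs).

A CBB deterministically encodes one (attribute, value) pair into a DNA
barcode of exactly L_CBB bases, so that printing the barcode (or its
complement) on a microarray retrieves the oligo that carries it. The
pipeline is:

1. *Mapping*   -- ``value=attribute`` rendered and reversed, e.g.
   ``(Id, 100) -> "001=dI"``; reversal puts the varying characters first,
   where the stateful converters are most sensitive.
2. *Compression* -- static Huffman code of the converter's base.
3. *DNA conversion* -- digits to bases via one of four converters.
4. *Padding* toward 50% GC and
5. *best-of-n permutation*, shared with every other sequence
   (:mod:`cbbdna.transforms`).

Injectivity: the mapping step is injective on rendered strings, Huffman
codes are prefix-free and the transform is invertible, so two distinct
values of one attribute can never collide (and distinct attributes never
collide because the attribute name is part of the code).

Converters
----------
``NaiveQuattro``    stateless 0A 1C 2G 3T (the baseline).
``RotatingQuattro`` stateful: emitted index = (prev + digit + 1) mod 4;
                    one changed digit re-keys every later base, which is
                    what keeps near-identical inputs far apart.
``RotatingTre``     base 3: the three bases != previous, in alphabetical
                    order, indexed by the digit; structurally free of
                    homopolymers.
``Bin``             base 2: bit pairs via the payload map 00A 01T 10C 11G
                    (one zero bit of padding when the stream is odd).
"""

from __future__ import annotations

from .config import CodecConfig
from .constraints import validate_dna
from .errors import CbbOverflowError, DecodeError, SegmentationRequiredError
from .huffman import HuffmanTable, huffman_encode
from .transforms import MARKER_SINGLE, PaddingBank, transform_forward

_QUATTRO = "ACGT"
_QUATTRO_INDEX = {b: i for i, b in enumerate(_QUATTRO)}
_BIT_PAIR = {(0, 0): "A", (0, 1): "T", (1, 0): "C", (1, 1): "G"}
_BIT_PAIR_INV = {v: k for k, v in _BIT_PAIR.items()}


class NaiveQuattro:
    base = 4
    name = "NaiveQuattro"

    @staticmethod
    def to_dna(digits) -> str:
        return "".join(_QUATTRO[d] for d in digits)

    @staticmethod
    def from_dna(seq) -> list:
        validate_dna(seq)
        return [_QUATTRO_INDEX[b] for b in seq]


class RotatingQuattro:
    base = 4
    name = "RotatingQuattro"

    @staticmethod
    def to_dna(digits) -> str:
        prev = 0  # index of A
        out = []
        for d in digits:
            if not 0 <= d < 4:
                raise ValueError(f"digit {d} out of range for base 4")
            prev = (prev + d + 1) % 4
            out.append(_QUATTRO[prev])
        return "".join(out)

    @staticmethod
    def from_dna(seq) -> list:
        validate_dna(seq)
        prev = 0
        out = []
        for b in seq:
            cur = _QUATTRO_INDEX[b]
            out.append((cur - prev - 1) % 4)
            prev = cur
        return out


class RotatingTre:
    base = 3
    name = "RotatingTre"

    @staticmethod
    def to_dna(digits) -> str:
        prev = "A"
        out = []
        for d in digits:
            if not 0 <= d < 3:
                raise ValueError(f"digit {d} out of range for base 3")
            choices = [b for b in _QUATTRO if b != prev]
            prev = choices[d]
            out.append(prev)
        return "".join(out)

    @staticmethod
    def from_dna(seq) -> list:
        validate_dna(seq)
        prev = "A"
        out = []
        for b in seq:
            choices = [c for c in _QUATTRO if c != prev]
            if b == prev:
                raise DecodeError("homopolymer in RotatingTre stream")
            out.append(choices.index(b))
            prev = b
        return out


class Bin:
    base = 2
    name = "Bin"

    @staticmethod
    def to_dna(digits) -> str:
        bits = list(digits)
        if len(bits) % 2:
            bits.append(0)  # pad bit; harmless past the end codeword
        return "".join(
            _BIT_PAIR[(bits[i], bits[i + 1])] for i in range(0, len(bits), 2)
        )

    @staticmethod
    def from_dna(seq) -> list:
        validate_dna(seq)
        out = []
        for b in seq:
            out.extend(_BIT_PAIR_INV[b])
        return out


CONVERTERS = {
    c.name: c for c in (NaiveQuattro, RotatingQuattro, RotatingTre, Bin)
}


def get_converter(name: str):
    try:
        return CONVERTERS[name]
    except KeyError:
        raise ValueError(
            f"unknown converter {name!r}; choose from {sorted(CONVERTERS)}"
        ) from None


# ---------------------------------------------------------------------------
# value rendering and mapping
# ---------------------------------------------------------------------------


def canonical_text(value) -> str:
    """Deterministic, locale-independent string rendering of a cell value.

    Integers (including numpy integers) render as plain decimal; strings
    pass through; everything else falls back to ``str``.
    """
    if isinstance(value, str):
        return value
    if isinstance(value, bool):
        return "true" if value else "false"
    try:
        as_int = int(value)
        if as_int == value:
            return str(as_int)
    except (TypeError, ValueError):
        pass
    return str(value)


def map_attribute_value(attribute: str, value) -> str:
    """``(Id, 100) -> "001=dI"``: render, join with '=', reverse."""
    if not attribute:
        raise ValueError("attribute name must be non-empty")
    return (attribute + "=" + canonical_text(value))[::-1]


# ---------------------------------------------------------------------------
# barcode encoding
# ---------------------------------------------------------------------------


def convert_to_dna(digits, converter) -> str:
    return get_converter(converter).to_dna(digits) if isinstance(converter, str) else converter.to_dna(digits)


def convert_from_dna(seq, converter):
    return get_converter(converter).from_dna(seq) if isinstance(converter, str) else converter.from_dna(seq)


def encode_cbb(
    attribute: str,
    value,
    config: CodecConfig,
    bank: PaddingBank,
    table: HuffmanTable,
) -> str:
    """Full 5-step barcode of exactly ``config.l_cbb`` bases."""
    converter = get_converter(config.converter)
    if table.base != converter.base:
        raise ValueError(
            f"Huffman table base {table.base} does not match "
            f"converter base {converter.base}"
        )
    mapped = map_attribute_value(attribute, value)
    body = converter.to_dna(huffman_encode(mapped, table))
    target = config.l_cbb - config.r_off
    if len(body) + 3 > target:  # marker + body + 2-base delimiter
        raise CbbOverflowError(
            f"barcode body for {attribute}={canonical_text(value)!r} needs "
            f"{len(body) + 3} bases but L_CBB leaves {target}; raise L_CBB"
        )
    try:
        return transform_forward(
            body,
            target,
            MARKER_SINGLE,
            config.n_permutations,
            config.r_off,
            bank,
            config.weights,
            config.thresholds,
        )
    except SegmentationRequiredError as exc:  # pragma: no cover - guarded above
        raise CbbOverflowError(str(exc)) from exc


def derive_segment_cbb(
    attribute: str,
    value,
    index: int,
    config: CodecConfig,
    bank: PaddingBank,
    table: HuffmanTable,
) -> str:
    """Barcode of segment *index* (1-based): the value suffixed ``.index``."""
    if index < 1:
        raise ValueError("segment indices are 1-based")
    suffixed = canonical_text(value) + "." + str(index)
    return encode_cbb(attribute, suffixed, config, bank, table)
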