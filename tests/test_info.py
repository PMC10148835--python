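"""Serialization, fountain coding and the Info-DNA frame."""

import pytest

from cbbdna import fountain
from cbbdna.config import CodecConfig
from cbbdna.constraints import LAX_THRESHOLDS, check_c1_c2
from cbbdna.errors import (
    DecodeError,
    InsufficientPacketsError,
    UnencodableError,
)
from cbbdna.info import (
    HEADER_BASES,
    bits_to_dna,
    bytes_to_dna,
    choose_symbol_size,
    compress_id_list,
    decode_info,
    decode_varint,
    decompress_id_list,
    delta_encode_ids,
    dna_to_bits,
    dna_to_bytes,
    encode_info,
    encode_varint,
    pack_record,
    unpack_record,
)
from cbbdna._prng import SplitMix64

from dataclasses import replace

CFG = CodecConfig(master_seed=1)


# --- varints and serializers ----------------------------------------------


def test_varint_roundtrip():
    for v in [0, 1, 127, 128, 300, 2**21, 2**40]:
        data = encode_varint(v)
        assert decode_varint(data) == (v, len(data))
    with pytest.raises(ValueError):
        encode_varint(-1)


def test_pack_record_roundtrips_worked_example():
    record = {"Time": 1015430211, "Velocity": 512}
    fields = ["Time", "Velocity"]
    packed = pack_record(record, fields)
    assert unpack_record(packed, fields) == {
        "Time": "1015430211",
        "Velocity": "512",
    }


def test_pack_record_random_and_empty():
    rng = SplitMix64(12)
    alphabet = "abcdefghij0123456789"
    for _ in range(1000):
        rec = {
            f"f{i}": "".join(
                alphabet[rng.randbelow(20)] for _ in range(rng.randbelow(12))
            )
            for i in range(1 + rng.randbelow(5))
        }
        fields = sorted(rec)
        assert unpack_record(pack_record(rec, fields), fields) == rec
    assert unpack_record(pack_record({}, []), []) == {}


def test_id_list_delta_layout_and_roundtrip():
    # [100, 103] stores first value 100 then delta 3, pre-compression
    assert delta_encode_ids([100, 103]) == encode_varint(100) + encode_varint(3)
    assert decompress_id_list(compress_id_list([100, 103])) == [100, 103]
    assert decompress_id_list(compress_id_list([5])) == [5]
    with pytest.raises(ValueError):
        compress_id_list([-1, 3])
    with pytest.raises(ValueError):
        compress_id_list([])


def test_id_list_random_roundtrip():
    rng = SplitMix64(13)
    for _ in range(2000):
        ids = sorted(
            {rng.randbelow(10**6) for _ in range(1 + rng.randbelow(60))}
        )
        assert decompress_id_list(compress_id_list(ids)) == ids


# --- bit/base mapping ------------------------------------------------------


@pytest.mark.parametrize(
    "bits,dna",
    [("1100110110", "GAGTC"), ("1111111111", "GGGGG"), ("00", "A")],
)
def test_bits_to_dna_printed_map(bits, dna):
    assert bits_to_dna(bits) == dna
    assert dna_to_bits(dna) == bits


def test_bits_to_dna_errors():
    with pytest.raises(ValueError):
        bits_to_dna("101")
    with pytest.raises(ValueError):
        bits_to_dna("1x")


def test_bytes_to_dna_roundtrip():
    rng = SplitMix64(14)
    for _ in range(200):
        blob = rng.next_bytes(rng.randbelow(40))
        assert dna_to_bytes(bytes_to_dna(blob)) == blob


# --- fountain --------------------------------------------------------------


def test_packets_are_deterministic_and_repair_only():
    msg = b"the quick brown fox jumps over the lazy dog"
    k = fountain.source_symbol_count(len(msg), 8)
    a = fountain.generate_repair_packets(msg, 8, count=12)
    b = fountain.generate_repair_packets(msg, 8, count=12)
    assert [(p.esi, p.payload) for p in a] == [(p.esi, p.payload) for p in b]
    assert all(p.esi >= k and p.is_repair for p in a)
    with pytest.raises(ValueError):
        fountain.generate_repair_packets(msg, 8, count=12, start_esi=0)


def test_any_k_plus_2_of_10_packets_decode():
    """Random k+2 subsets of 10 repair packets decode in >= 99/100 trials."""
    msg = bytes(range(64))  # k = 8 symbols of 8 bytes
    packets = fountain.generate_repair_packets(msg, 8, count=10)
    k = fountain.source_symbol_count(len(msg), 8)
    assert k == 8
    rng = SplitMix64(101)
    successes = 0
    for _ in range(100):
        subset = list(packets)
        for _ in range(len(subset) - (k + 2)):
            subset.pop(rng.randbelow(len(subset)))
        try:
            if fountain.decode(subset, len(msg), 8) == msg:
                successes += 1
        except InsufficientPacketsError:
            pass
    assert successes >= 99


def test_decode_needs_k_packets():
    msg = b"0123456789abcdef"
    packets = fountain.generate_repair_packets(msg, 4, count=3)
    with pytest.raises(InsufficientPacketsError):
        fountain.decode(packets, len(msg), 4)


# --- encode_info / decode_info ---------------------------------------------


def _parse_packets(dna, cfg=CFG):
    from cbbdna.transforms import decode_quaternary

    count = decode_quaternary(dna[2:10])
    symbol_size = decode_quaternary(dna[10:18])
    esis, payload_dnas = [], []
    pos = HEADER_BASES
    for _ in range(count):
        esis.append(decode_quaternary(dna[pos : pos + 8]))
        payload_dnas.append(dna[pos + 8 : pos + 8 + 4 * symbol_size])
        pos += 8 + 4 * symbol_size
    return count, symbol_size, esis, payload_dnas


def test_lax_thresholds_keep_first_k_plus_epsilon_packets():
    cfg = replace(CFG, thresholds=LAX_THRESHOLDS)
    payload = bytes(range(40))
    k = fountain.source_symbol_count(len(payload) + 4, choose_symbol_size(44, cfg))
    dna = encode_info(payload, cfg)
    count, _, esis, _ = _parse_packets(dna)
    assert count == k + cfg.epsilon
    assert esis == list(range(k, k + count))  # no packet was filtered out


def test_surviving_packets_pass_c1_c2():
    payload = b"constraint-filtered payload bytes 123"
    dna = encode_info(payload, CFG)
    _, _, _, payload_dnas = _parse_packets(dna)
    assert payload_dnas
    for pdna in payload_dnas:
        assert check_c1_c2(pdna, CFG.thresholds).passed


def test_strict_filtering_drops_some_candidates():
    """With active thresholds the survivors are a strict subset of the
    generated ESI range (packets were filtered, as in the worked example
    where 4 generated packets yield 2 survivors)."""
    payload = bytes(range(30))
    dna = encode_info(payload, CFG)
    _, _, esis, _ = _parse_packets(dna)
    k = fountain.source_symbol_count(len(payload) + 4,
                                     choose_symbol_size(34, CFG))
    generated_span = esis[-1] - k + 1
    assert len(esis) <= generated_span  # subset of what was generated
    assert decode_info(dna) == payload


def test_encode_decode_roundtrip_sizes():
    rng = SplitMix64(500)
    for _ in range(60):
        n = 10 + rng.randbelow(1990)
        payload = rng.next_bytes(n)
        dna = encode_info(payload, CFG)
        assert decode_info(dna) == payload


def test_single_packet_erasure_tolerated():
    """Deleting any one packet still decodes when epsilon >= 1."""
    payload = bytes(range(100))
    dna = encode_info(payload, CFG)
    count, symbol_size, esis, payload_dnas = _parse_packets(dna)
    ok = 0
    for drop in range(count):
        packets = [
            fountain.Packet(esi=e, payload=dna_to_bytes(p))
            for i, (e, p) in enumerate(zip(esis, payload_dnas))
            if i != drop
        ]
        try:
            message = fountain.decode(packets, len(payload) + 4, symbol_size)
            ok += message[: len(payload)] == payload
        except InsufficientPacketsError:
            pass
    assert ok >= max(1, int(0.95 * count))


def test_erasure_success_grows_with_redundancy():
    """Decode success under one random packet loss is non-decreasing in
    epsilon (0, 1, 2)."""
    payload = bytes(range(48))
    rates = []
    for eps in (0, 1, 2):
        cfg = replace(CFG, epsilon=eps)
        dna = encode_info(payload, cfg)
        count, symbol_size, esis, payload_dnas = _parse_packets(dna)
        rng = SplitMix64(600 + eps)
        ok = 0
        for _ in range(60):
            drop = rng.randbelow(count)
            packets = [
                fountain.Packet(esi=e, payload=dna_to_bytes(p))
                for i, (e, p) in enumerate(zip(esis, payload_dnas))
                if i != drop
            ]
            try:
                msg = fountain.decode(packets, len(payload) + 4, symbol_size)
                ok += msg[: len(payload)] == payload
            except InsufficientPacketsError:
                pass
        rates.append(ok / 60)
    assert rates == sorted(rates)
    assert rates[-1] == 1.0


def test_corruption_is_reported_not_silent():
    payload = b"some important record content"
    dna = encode_info(payload, CFG)
    # flip a base inside the first packet payload
    pos = HEADER_BASES + 10
    flipped = dna[:pos] + ("A" if dna[pos] != "A" else "C") + dna[pos + 1 :]
    with pytest.raises((DecodeError, InsufficientPacketsError)):
        decode_info(flipped)


def test_empty_payload_is_a_reported_error():
    # all-zero message symbols can never satisfy C2 -> explicit failure
    with pytest.raises(UnencodableError):
        encode_info(b"", CFG)


def test_gc_extreme_payload_encodable_or_reported():
    # highly repetitive payloads either survive filtering or fail loudly
    payload = b"\xff" * 64
    dna = encode_info(payload, CFG)
    assert decode_info(dna) == payload
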