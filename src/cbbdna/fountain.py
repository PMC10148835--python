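"""Deterministic rateless erasure code over GF(256).

The payload codec needs a fountain-code contract: a k-symbol message can
be expanded into an unbounded stream of *repair* packets, any k + eps of
which reconstruct the message with overwhelming probability. This module
provides that contract with a random-linear fountain over GF(256): the
packet with encoding-symbol identifier (ESI) e carries

    payload(e) = sum_i  c_i(e) * s_i          (arithmetic in GF(256))

where the coefficient vector c(e) is produced by a splitmix64 stream
seeded from (e, k) -- so packets are a pure function of (message, ESI)
and the decoder can rebuild every coefficient vector from the ESIs alone.
Decoding is Gaussian elimination; k packets suffice whenever their
coefficient matrix has full rank, which for dense uniform GF(256) vectors
fails with probability about 256^-(eps+1) given k + eps packets. Source
symbols themselves are never emitted (ESIs start at k): verbatim source
data tends to carry long homopolymers into the DNA mapping, while dense
combinations look random.

GF(256) uses the primitive polynomial x^8+x^4+x^3+x^2+1 (0x11D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._prng import SplitMix64, mix64
from .errors import InsufficientPacketsError

# --- GF(256) tables --------------------------------------------------------

_EXP = np.zeros(512, dtype=np.uint8)
_LOG = np.zeros(256, dtype=np.int32)


def _init_tables():
    x = 1
    for i in range(255):
        _EXP[i] = x
        _LOG[x] = i
        x <<= 1
        if x & 0x100:
            x ^= 0x11D
    _EXP[255:510] = _EXP[:255]


_init_tables()


def gf_scale(vec: np.ndarray, scalar: int) -> np.ndarray:
    """scalar * vec elementwise over GF(256)."""
    if scalar == 0:
        return np.zeros_like(vec)
    out = np.zeros_like(vec)
    nz = vec != 0
    out[nz] = _EXP[_LOG[vec[nz]] + _LOG[scalar]]
    return out


def gf_matvec(coeffs: np.ndarray, symbols: np.ndarray) -> np.ndarray:
    """coeffs (k,) . symbols (k, s) over GF(256) -> (s,)."""
    acc = np.zeros(symbols.shape[1], dtype=np.uint8)
    for c, row in zip(coeffs, symbols):
        if c:
            acc ^= gf_scale(row, int(c))
    return acc


# --- packets ---------------------------------------------------------------


@dataclass(frozen=True)
class Packet:
    """One encoded symbol: its ESI and symbol_size payload bytes."""

    esi: int
    payload: bytes

    @property
    def is_repair(self) -> bool:
        return True  # the codec emits repair packets only


_COEFF_TWEAK = 0x666E74636F656666  # "fntcoeff"


def coefficient_vector(esi: int, k: int) -> np.ndarray:
    """Dense GF(256) coefficients of packet *esi* for a k-symbol message."""
    rng = SplitMix64(mix64((esi << 20) ^ (k * 0x9E3779B9) ^ _COEFF_TWEAK))
    vec = np.frombuffer(rng.next_bytes(k), dtype=np.uint8).copy()
    if not vec.any():  # probability 256^-k; keep every packet useful
        vec[esi % k] = 1
    return vec


def symbol_matrix(message: bytes, symbol_size: int) -> np.ndarray:
    """Zero-padded (k, symbol_size) view of the message bytes."""
    if symbol_size < 1:
        raise ValueError("symbol_size must be positive")
    k = max(1, -(-len(message) // symbol_size))
    buf = np.zeros(k * symbol_size, dtype=np.uint8)
    raw = np.frombuffer(message, dtype=np.uint8)
    buf[: len(raw)] = raw
    return buf.reshape(k, symbol_size)


def source_symbol_count(transfer_length: int, symbol_size: int) -> int:
    return max(1, -(-transfer_length // symbol_size))


def generate_repair_packets(
    message: bytes, symbol_size: int, count: int, start_esi: int = None
):
    """*count* repair packets with consecutive ESIs (default: starting at k).

    Deterministic: equal inputs give byte-identical packets.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    symbols = symbol_matrix(message, symbol_size)
    k = symbols.shape[0]
    first = k if start_esi is None else start_esi
    if first < k:
        raise ValueError("repair ESIs start at k; source symbols are not emitted")
    packets = []
    for esi in range(first, first + count):
        payload = gf_matvec(coefficient_vector(esi, k), symbols)
        packets.append(Packet(esi=esi, payload=payload.tobytes()))
    return packets


def decode(packets, transfer_length: int, symbol_size: int) -> bytes:
    """Recover the message from any full-rank set of packets.

    Raises :class:`InsufficientPacketsError` when fewer than k packets are
    given or their coefficient matrix is rank-deficient.
    """
    k = source_symbol_count(transfer_length, symbol_size)
    packets = list(packets)
    if len(packets) < k:
        raise InsufficientPacketsError(
            f"need at least {k} packets, got {len(packets)}"
        )
    A = np.stack([coefficient_vector(p.esi, k) for p in packets]).astype(np.uint8)
    B = np.stack(
        [np.frombuffer(p.payload, dtype=np.uint8) for p in packets]
    ).astype(np.uint8)
    if B.shape[1] != symbol_size:
        raise InsufficientPacketsError("packet payload width mismatch")

    rank = 0
    for col in range(k):
        pivot = None
        for row in range(rank, len(packets)):
            if A[row, col]:
                pivot = row
                break
        if pivot is None:
            raise InsufficientPacketsError(
                f"coefficient matrix rank-deficient at column {col}"
            )
        if pivot != rank:
            A[[rank, pivot]] = A[[pivot, rank]]
            B[[rank, pivot]] = B[[pivot, rank]]
        inv = int(_EXP[255 - _LOG[A[rank, col]]])
        A[rank] = gf_scale(A[rank], inv)
        B[rank] = gf_scale(B[rank], inv)
        for row in range(len(packets)):
            if row != rank and A[row, col]:
                f = int(A[row, col])
                A[row] ^= gf_scale(A[rank], f)
                B[row] ^= gf_scale(B[rank], f)
        rank += 1
    return B[:k].reshape(-1)[:transfer_length].tobytes()
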