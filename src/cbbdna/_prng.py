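"""Deterministic 64-bit PRNG used everywhere randomness must be replayable.

The codec's permutations, padding banks and fountain coefficients must be
reproducible across runs, platforms and languages, so no runtime default
generator is used. Instead we fix the splitmix64 recurrence:

    state   <- (state + 0x9E3779B97F4A7C15) mod 2^64
    z       <- state
    z       <- (z XOR (z >> 30)) * 0xBF58476D1CE4E5B9 mod 2^64
    z       <- (z XOR (z >> 27)) * 0x94D049BB133111EB mod 2^64
    output  <- z XOR (z >> 31)

Bounded draws use plain modulo reduction; the bias is below 2^-32 for the
bound sizes that occur here (sequence lengths, offsets) and determinism,
not statistical perfection, is the requirement.
"""

from __future__ import annotations

MASK64 = 0xFFFFFFFFFFFFFFFF
_GAMMA = 0x9E3779B97F4A7C15
_MUL1 = 0xBF58476D1CE4E5B9
_MUL2 = 0x94D049BB133111EB


def mix64(z: int) -> int:
    """The splitmix64 output mixer as a pure function."""
    z &= MASK64
    z = ((z ^ (z >> 30)) * _MUL1) & MASK64
    z = ((z ^ (z >> 27)) * _MUL2) & MASK64
    return z ^ (z >> 31)


class SplitMix64:
    """Minimal splitmix64 stream generator."""

    __slots__ = ("_state",)

    def __init__(self, seed: int):
        self._state = seed & MASK64

    def next_u64(self) -> int:
        self._state = (self._state + _GAMMA) & MASK64
        return mix64(self._state)

    def randbelow(self, n: int) -> int:
        """Uniform-ish draw in [0, n) by modulo reduction (documented bias)."""
        if n <= 0:
            raise ValueError("bound must be positive")
        return self.next_u64() % n

    def next_bytes(self, n: int) -> bytes:
        out = bytearray()
        while len(out) < n:
            out += self.next_u64().to_bytes(8, "big")
        return bytes(out[:n])

    def next_float(self) -> float:
        """Uniform in [0, 1) with 53 random bits."""
        return (self.next_u64() >> 11) / float(1 << 53)
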