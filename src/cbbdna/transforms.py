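"""Reversible stabilizer transforms: GC-optimizing padding and seeded
best-of-n permutation.

Every barcode and every Info-DNA segment passes through the same two
transforms before it is placed in an oligo:

1.  *Padding*: the body is framed as ``marker + body + "AC"`` and filled
    up to the target length L with a prefix of one of eleven pre-computed
    padding sequences p_0..p_10 whose GC contents step from 0% to 100% in
    10% increments.  The bank index is

        i = max(0, floor(10 * (L/2 - gc_count(frame)) / (L - |frame|)))

    clamped to 10 from above, which steers the padded sequence's GC
    content toward 50%.  The delimiter "AC" never occurs inside a bank
    sequence, so the rightmost "AC" in a padded frame is always the
    delimiter and decoding is unambiguous.

2.  *Permutation*: n candidate Fisher-Yates shuffles are generated with
    seeds ``seed + k`` (k = 0..n-1) where

        seed = count_A * count_C * count_T * count_G

    is a function of the base multiset only, hence recomputable from the
    permuted sequence.  The candidate with the lowest constraint error is
    kept and its offset k is written, unpermuted, as an r_off-base
    quaternary prefix so the decoder can rebuild the swap list.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._prng import MASK64, SplitMix64, mix64
from .constraints import (
    ConstraintThresholds,
    ErrorWeights,
    check_c1_c2,
    error_score,
    validate_dna,
)
from .errors import (
    CorruptFrameError,
    EmptySequenceError,
    SegmentationRequiredError,
)

DELIMITER = "AC"
MARKER_SINGLE = "C"  # payload fits a single oligo
MARKER_SEGMENTED = "A"  # payload is one slice of a segmented message
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


# ---------------------------------------------------------------------------
# padding bank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PaddingBank:
    """Eleven delimiter-free padding sequences with stepped GC content.

    ``sequences[i]`` has GC content within 2 percentage points of i*10%,
    contains no "AC" substring and no homopolymer longer than the bound it
    was generated with.
    """

    sequences: tuple
    generation_seed: int = 0

    def __post_init__(self):
        if len(self.sequences) != 11:
            raise ValueError("a padding bank holds exactly 11 sequences")
        for i, p in enumerate(self.sequences):
            validate_dna(p)
            if DELIMITER in p:
                raise ValueError(f"p_{i} contains the delimiter {DELIMITER!r}")

    def __getitem__(self, i: int) -> str:
        return self.sequences[i]

    @property
    def length(self) -> int:
        return min(len(p) for p in self.sequences)

    @classmethod
    def generate(
        cls, length: int, max_homopolymer: int = 3, seed: int = 0
    ) -> "PaddingBank":
        """Deterministically build a bank of the given sequence length.

        Each p_i is grown base by base: the G/C-vs-A/T choice is biased so
        that exactly round(length * i/10) strong bases are emitted, a 'C'
        is never placed directly after an 'A' (keeps the bank
        delimiter-free) and no run may exceed *max_homopolymer*.  Under
        these rules a legal base always exists, so construction never
        backtracks and the GC target is met exactly (within rounding).
        """
        if length < 1:
            raise ValueError("bank sequences need positive length")
        rng = SplitMix64(mix64(seed ^ 0x70616462616E6B))  # tweak: "padbank"
        seqs = []
        for i in range(11):
            target = round(length * i / 10)
            seqs.append(_grow_padding_seq(length, target, max_homopolymer, rng))
        return cls(sequences=tuple(seqs), generation_seed=seed)


def _grow_padding_seq(length, gc_target, max_hp, rng):
    seq = []
    gc_done = 0
    run_base, run_len = None, 0
    for pos in range(length):
        remaining = length - pos
        need = gc_target - gc_done
        p_gc = min(1.0, max(0.0, need / remaining))
        want_gc = rng.next_float() < p_gc
        if need >= remaining:
            want_gc = True
        elif need <= 0:
            want_gc = False
        pool = ["G", "C"] if want_gc else ["A", "T"]
        if run_len >= max_hp and run_base in pool:
            pool = [b for b in pool if b != run_base]
        if seq and seq[-1] == "A" and "C" in pool:
            pool = [b for b in pool if b != "C"]
        base = pool[rng.randbelow(len(pool))]
        seq.append(base)
        if base in "GC":
            gc_done += 1
        if base == run_base:
            run_len += 1
        else:
            run_base, run_len = base, 1
    return "".join(seq)


# ---------------------------------------------------------------------------
# padding
# ---------------------------------------------------------------------------


def frame(body: str, marker: str) -> str:
    """Attach the marker prefix and the delimiter suffix to a body."""
    if marker not in (MARKER_SINGLE, MARKER_SEGMENTED):
        raise ValueError(f"marker must be 'C' or 'A', got {marker!r}")
    validate_dna(body)
    return marker + body + DELIMITER


def compute_padding_index(framed_prefix: str, L: int) -> int:
    """Bank index steering the padded sequence's GC content toward 50%.

    Integer evaluation of floor(10*(L/2 - gc)/(L - |s|)) with the result
    clamped to [0, 10].
    """
    validate_dna(framed_prefix)
    s = len(framed_prefix)
    if s >= L:
        raise ValueError(f"padding applies only when |seq| < L ({s} >= {L})")
    g = framed_prefix.count("G") + framed_prefix.count("C")
    raw = (5 * L - 10 * g) // (L - s)  # == floor(10*(L/2 - g)/(L - s))
    return max(0, min(10, raw))


def pad(body: str, L: int, marker: str, bank: PaddingBank) -> str:
    """Frame *body* and fill it to exactly L bases from the padding bank."""
    f = frame(body, marker)
    if len(f) > L:
        raise SegmentationRequiredError(
            f"framed body has {len(f)} bases but the target length is {L}; "
            "segment the payload first"
        )
    if len(f) == L:
        return f
    i = compute_padding_index(f, L)
    tail = bank[i][: L - len(f)]
    if len(tail) < L - len(f):
        raise ValueError(
            f"padding bank sequences are too short ({len(bank[i])}) "
            f"for target length {L}"
        )
    return f + tail


def unpad(padded: str) -> tuple:
    """Recover ``(body, marker)`` from a padded frame.

    The delimiter is located as the *rightmost* "AC": the pad tail is
    delimiter-free by bank construction and the junction after the
    delimiter's final C cannot create a later occurrence.
    """
    validate_dna(padded)
    if not padded or padded[0] not in (MARKER_SINGLE, MARKER_SEGMENTED):
        raise CorruptFrameError("frame does not start with a marker base")
    idx = padded.rfind(DELIMITER)
    if idx < 1:
        raise CorruptFrameError("no delimiter found in padded frame")
    return padded[1:idx], padded[0]


# ---------------------------------------------------------------------------
# permutation
# ---------------------------------------------------------------------------


def compute_seed(seq: str) -> int:
    """Product of the four base counts; invariant under permutation."""
    validate_dna(seq)
    n = 1
    for b in _BASES:
        n *= seq.count(b)
    return n


def fisher_yates_swaps(length: int, seed: int):
    """Deterministic Fisher-Yates swap list for a sequence of *length*.

    Pairs (i, rand_i) with rand_i drawn uniformly from {0..i}, for
    i = length-1 down to 1, from a splitmix64 stream seeded with *seed*.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = SplitMix64(seed & MASK64)
    return [(i, rng.randbelow(i + 1)) for i in range(length - 1, 0, -1)]


def apply_swaps(seq: str, swaps) -> str:
    chars = list(seq)
    n = len(chars)
    for i, j in swaps:
        if i >= n or j >= n:
            raise IndexError(f"swap ({i},{j}) out of range for length {n}")
        chars[i], chars[j] = chars[j], chars[i]
    return "".join(chars)


def invert_swaps(seq: str, swaps) -> str:
    chars = list(seq)
    n = len(chars)
    for i, j in reversed(swaps):
        if i >= n or j >= n:
            raise IndexError(f"swap ({i},{j}) out of range for length {n}")
        chars[i], chars[j] = chars[j], chars[i]
    return "".join(chars)


def select_best_permutation(
    seq: str,
    n: int,
    weights: ErrorWeights = ErrorWeights(),
    thresholds: ConstraintThresholds = ConstraintThresholds(),
) -> tuple:
    """Return ``(offset_k, permuted)`` minimizing the constraint error.

    Candidates are the Fisher-Yates shuffles seeded with seed+0..seed+n-1;
    ties break toward the smallest offset. n == 0 means "no permutation"
    (identity, offset 0).
    """
    if not seq:
        raise EmptySequenceError("cannot permute an empty sequence")
    if n <= 0:
        return 0, seq
    seed = compute_seed(seq)
    best_k, best_seq, best_err = 0, None, None
    for k in range(n):
        cand = apply_swaps(seq, fisher_yates_swaps(len(seq), (seed + k) & MASK64))
        err = error_score(cand, weights, thresholds)
        if best_err is None or err < best_err:
            best_k, best_seq, best_err = k, cand, err
    return best_k, best_seq


# ---------------------------------------------------------------------------
# offset prefix
# ---------------------------------------------------------------------------


def encode_quaternary(value: int, width: int) -> str:
    """Fixed-width base-4 numeral with digit map 0A 1C 2G 3T (MSB first)."""
    if value < 0 or (width >= 0 and value >= 4**width):
        raise ValueError(f"value {value} does not fit in {width} quaternary digits")
    digits = []
    for _ in range(width):
        digits.append(_BASES[value % 4])
        value //= 4
    return "".join(reversed(digits))


def decode_quaternary(seq: str) -> int:
    validate_dna(seq)
    value = 0
    for b in seq:
        value = value * 4 + _BASE_INDEX[b]
    return value


def attach_offset_prefix(permuted: str, offset_k: int, r_off: int) -> str:
    return encode_quaternary(offset_k, r_off) + permuted


def read_offset_prefix(seq: str, r_off: int) -> tuple:
    if len(seq) < r_off:
        raise CorruptFrameError("sequence shorter than its offset prefix")
    return decode_quaternary(seq[:r_off]), seq[r_off:]


# ---------------------------------------------------------------------------
# composed transform
# ---------------------------------------------------------------------------


def transform_forward(
    body: str,
    L: int,
    marker: str,
    n: int,
    r_off: int,
    bank: PaddingBank,
    weights: ErrorWeights = ErrorWeights(),
    thresholds: ConstraintThresholds = ConstraintThresholds(),
) -> str:
    """pad -> best-of-n permute -> offset prefix; output length r_off + L.

    Candidates are ranked on the *emitted* sequence (offset prefix
    attached), preferring C1/C2-passing candidates and breaking ties by
    error then smallest offset, so the prefix cannot silently extend a
    homopolymer across the junction.
    """
    padded = pad(body, L, marker, bank)
    if n <= 0:
        return attach_offset_prefix(padded, 0, r_off)
    seed = compute_seed(padded)
    best = None
    for k in range(n):
        cand = apply_swaps(padded, fisher_yates_swaps(len(padded), (seed + k) & MASK64))
        emitted = attach_offset_prefix(cand, k, r_off)
        rank = (
            not check_c1_c2(emitted, thresholds).passed,
            error_score(emitted, weights, thresholds),
        )
        if best is None or rank < best[0]:
            best = (rank, emitted)
    return best[1]


def transform_inverse(seq: str, n: int, r_off: int) -> tuple:
    """Invert :func:`transform_forward`; returns ``(body, marker)``.

    The permutation seed is recomputed from the permuted body's base
    counts (the seed is multiset-invariant), so no side information
    beyond (n, r_off) is needed.
    """
    k, permuted = read_offset_prefix(seq, r_off)
    if n <= 0:
        padded = permuted
    else:
        if k >= n:
            raise CorruptFrameError(f"offset {k} >= permutation count {n}")
        seed = compute_seed(permuted)
        swaps = fisher_yates_swaps(len(permuted), (seed + k) & MASK64)
        padded = invert_swaps(permuted, swaps)
    return unpad(padded)
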