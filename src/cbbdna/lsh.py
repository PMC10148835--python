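"""MinHash/LSH approximation of Jaccard similarity among oligos.

Cross-hybridization constraints (C3-C5) require the pairwise similarity
of barcodes, payloads and whole oligos to stay low, but all-pairs exact
Jaccard is quadratic in the pool size. The standard estimator is used
instead: a sequence is reduced to its set of k-shingles (length-k
substrings), each of r independent hash functions contributes the minimum
hash over the set, and the fraction of agreeing signature positions
estimates the Jaccard similarity with standard error sqrt(J(1-J)/r).
Banding the r rows into b bands turns the signatures into a candidate
generator for high-similarity pairs: two sequences collide when some band
of r/b rows agrees entirely, which happens with probability
1 - (1 - J^(r/b))^b.

Hash family: the shingle is 2-bit packed, dispersed through a splitmix64
finalizer, then passed through per-function 64-bit multiply-add hashes
whose parameters derive deterministically from ``hash_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._prng import SplitMix64, mix64
from .config import LshParams
from .constraints import validate_dna
from .errors import EmptySequenceError

_BASE_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
_MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)


def shingles(seq: str, k: int) -> set:
    """All length-k substrings of *seq* (empty set when |seq| < k)."""
    validate_dna(seq)
    if len(seq) < k:
        return set()
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _pack_shingles(seq: str, k: int) -> np.ndarray:
    """Distinct k-shingles as 2-bit packed uint64 values."""
    codes = np.array([_BASE_BITS[b] for b in seq], dtype=np.uint64)
    if len(codes) < k:
        return np.empty(0, dtype=np.uint64)
    packed = np.zeros(len(codes) - k + 1, dtype=np.uint64)
    for j in range(k):
        packed = (packed << np.uint64(2)) | codes[j : j + len(packed)]
    return np.unique(packed)


def _mix_vector(values: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer, vectorized."""
    z = values.copy()
    with np.errstate(over="ignore"):
        z ^= z >> np.uint64(30)
        z *= np.uint64(0xBF58476D1CE4E5B9)
        z ^= z >> np.uint64(27)
        z *= np.uint64(0x94D049BB133111EB)
        z ^= z >> np.uint64(31)
    return z


@dataclass(frozen=True)
class MinHashSignature:
    values: tuple  # r minimum hash values
    params: LshParams


class _HashFamily:
    """r multiply-add hash functions (a_i odd, b_i arbitrary) from one seed."""

    _cache = {}

    @classmethod
    def get(cls, params: LshParams):
        key = (params.num_hashes_r, params.hash_seed)
        hit = cls._cache.get(key)
        if hit is None:
            rng = SplitMix64(mix64(params.hash_seed ^ 0x6C7368))  # "lsh"
            a = np.array(
                [rng.next_u64() | 1 for _ in range(params.num_hashes_r)],
                dtype=np.uint64,
            )
            b = np.array(
                [rng.next_u64() for _ in range(params.num_hashes_r)],
                dtype=np.uint64,
            )
            hit = (a, b)
            cls._cache[key] = hit
        return hit


def minhash_signature(seq: str, params: LshParams) -> MinHashSignature:
    """Deterministic MinHash signature of the sequence's k-shingle set."""
    packed = _pack_shingles(seq, params.shingle_k)
    if packed.size == 0:
        raise EmptySequenceError(
            f"sequence shorter than shingle length {params.shingle_k}"
        )
    values = _signature_row(packed, params)
    return MinHashSignature(values=tuple(int(v) for v in values), params=params)


def _signature_row(packed: np.ndarray, params: LshParams) -> np.ndarray:
    a, b = _HashFamily.get(params)
    mixed = _mix_vector(packed)
    with np.errstate(over="ignore"):
        table = a[:, None] * mixed[None, :] + b[:, None]
    return table.min(axis=1)


def signature_matrix(sequences, params: LshParams) -> np.ndarray:
    """Stacked signatures, one row per sequence -- (N, r) uint64."""
    rows = np.empty((len(sequences), params.num_hashes_r), dtype=np.uint64)
    for i, seq in enumerate(sequences):
        packed = _pack_shingles(seq, params.shingle_k)
        if packed.size == 0:
            raise EmptySequenceError(f"sequence {i} shorter than the shingle")
        rows[i] = _signature_row(packed, params)
    return rows


def estimate_jaccard_distance(a: MinHashSignature, b: MinHashSignature) -> float:
    """1 - (fraction of agreeing signature positions)."""
    if a.params != b.params:
        raise ValueError("signatures were built with different parameters")
    va = np.asarray(a.values, dtype=np.uint64)
    vb = np.asarray(b.values, dtype=np.uint64)
    return float(1.0 - np.mean(va == vb))


def exact_jaccard_distance(x: str, y: str, k: int) -> float:
    """Brute-force Jaccard distance of the two shingle sets (the oracle)."""
    sx, sy = shingles(x, k), shingles(y, k)
    union = sx | sy
    if not union:
        return 0.0
    return 1.0 - len(sx & sy) / len(union)


def lsh_candidate_pairs(signatures, params: LshParams) -> set:
    """Index pairs sharing at least one band bucket."""
    if len(signatures) < 2:
        return set()
    mat = np.stack(
        [np.asarray(s.values if isinstance(s, MinHashSignature) else s,
                    dtype=np.uint64) for s in signatures]
    )
    rows = params.rows_per_band
    pairs = set()
    for band in range(params.bands_b):
        buckets = {}
        block = mat[:, band * rows : (band + 1) * rows]
        for i, row in enumerate(block):
            buckets.setdefault(row.tobytes(), []).append(i)
        for members in buckets.values():
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    pairs.add((members[x], members[y]))
    return pairs


@dataclass(frozen=True)
class PoolDistanceStats:
    average_distance: float
    min_distance: float
    flagged_pairs: tuple  # (i, j, estimated similarity) above max_similarity
    pairs_evaluated: int

    def to_dict(self) -> dict:
        return {
            "average_distance": self.average_distance,
            "min_distance": self.min_distance,
            "flagged_pairs": [list(p) for p in self.flagged_pairs],
            "pairs_evaluated": self.pairs_evaluated,
        }


def pool_distance_stats(
    sequences,
    params: LshParams,
    max_similarity: float = 0.5,
    exhaustive_limit: int = 10_000,
    sample_pairs: int = 100_000,
    sample_seed: int = 0,
) -> PoolDistanceStats:
    """Average/minimum estimated Jaccard distance over sequence pairs.

    All pairs are evaluated below *exhaustive_limit* sequences; above it a
    fixed-size seeded uniform pair sample is used (all-pairs computation
    at millions of oligos is exactly what LSH exists to avoid). Pairs with
    estimated similarity above *max_similarity* are flagged as C3/C5
    violations.
    """
    n = len(sequences)
    if n < 2:
        raise ValueError("need at least two sequences")
    mat = signature_matrix(sequences, params)
    r = params.num_hashes_r
    total = 0.0
    min_dist = 1.0
    flagged = []
    pairs_done = 0
    if n < exhaustive_limit:
        chunk = max(1, (8 << 20) // (n * r))  # ~8M signature cells per block
        for start in range(0, n - 1, chunk):
            stop = min(start + chunk, n - 1)
            for i in range(start, stop):
                agree = (mat[i + 1 :] == mat[i]).sum(axis=1) / r
                dists = 1.0 - agree
                total += dists.sum()
                pairs_done += dists.size
                m = dists.min()
                if m < min_dist:
                    min_dist = float(m)
                for j in np.nonzero(agree > max_similarity)[0]:
                    flagged.append((i, i + 1 + int(j), float(agree[j])))
    else:
        rng = SplitMix64(mix64(sample_seed ^ 0x70616972))  # "pair"
        for _ in range(sample_pairs):
            i = rng.randbelow(n)
            j = rng.randbelow(n)
            while j == i:
                j = rng.randbelow(n)
            agree = float(np.mean(mat[i] == mat[j]))
            d = 1.0 - agree
            total += d
            pairs_done += 1
            if d < min_dist:
                min_dist = d
            if agree > max_similarity:
                flagged.append((min(i, j), max(i, j), agree))
    return PoolDistanceStats(
        average_distance=total / pairs_done,
        min_distance=min_dist,
        flagged_pairs=tuple(sorted(set(flagged))),
        pairs_evaluated=pairs_done,
    )
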