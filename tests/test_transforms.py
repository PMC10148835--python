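"""Padding, seeded permutation, and their composition."""

import pytest

from cbbdna.constraints import (
    ConstraintThresholds,
    ErrorWeights,
    error_score,
    gc_content,
    max_homopolymer_run,
)
from cbbdna.errors import CorruptFrameError, SegmentationRequiredError
from cbbdna.transforms import (
    DELIMITER,
    PaddingBank,
    apply_swaps,
    attach_offset_prefix,
    compute_padding_index,
    compute_seed,
    fisher_yates_swaps,
    frame,
    invert_swaps,
    pad,
    read_offset_prefix,
    select_best_permutation,
    transform_forward,
    transform_inverse,
    unpad,
)
from cbbdna._prng import MASK64, SplitMix64

from conftest import random_dna

# bank matching the worked padding example: p_6 starts CAG...
EXAMPLE_P6 = "CAGTCGGCGAGA"


@pytest.fixture(scope="module")
def bank():
    return PaddingBank.generate(length=200, max_homopolymer=3, seed=11)


# --- padding ---------------------------------------------------------------


def test_padding_index_worked_example():
    # frame C + GTGTTA + AC, L = 12 -> bank index 6
    assert frame("GTGTTA", "C") == "CGTGTTAAC"
    assert compute_padding_index("CGTGTTAAC", 12) == 6


@pytest.mark.parametrize(
    "framed,L,expected",
    [
        ("GCGCAT", 8, 0),  # floor(10*(4-4)/2) = 0
        ("GGGGGG", 8, 0),  # clamp below: max(0, -10)
        ("AATTAA", 8, 10),  # clamp above: AT-rich remainder
    ],
)
def test_padding_index_clamps(framed, L, expected):
    assert compute_padding_index(framed, L) == expected


def test_padding_index_requires_room():
    with pytest.raises(ValueError):
        compute_padding_index("ACGTACGT", 8)


def test_pad_worked_example():
    example_bank = PaddingBank(
        sequences=tuple(
            EXAMPLE_P6 if i == 6 else PaddingBank.generate(12, 3, 5)[i]
            for i in range(11)
        )
    )
    padded = pad("GTGTTA", 12, "C", example_bank)
    assert padded == "CGTGTTAACCAG"
    assert gc_content(padded) == 0.5
    assert len(padded) == 12
    assert unpad(padded) == ("GTGTTA", "C")


def test_pad_exact_fill_has_no_pad_bases(bank):
    padded = pad("GCGCGTAT", 11, "C", bank)
    assert padded == "C" + "GCGCGTAT" + DELIMITER
    assert len(padded) == 11


def test_pad_rejects_overlong_body(bank):
    with pytest.raises(SegmentationRequiredError):
        pad("ACGTACGTACGT", 10, "C", bank)


def test_unpad_error_paths():
    with pytest.raises(CorruptFrameError):
        unpad("GGGG")  # no delimiter
    with pytest.raises(CorruptFrameError):
        unpad("GACGTAC")  # first base is not a marker


def test_pad_roundtrip_random_bodies(bank):
    rng = SplitMix64(21)
    for _ in range(1000):
        body = random_dna(rng, rng.randbelow(60))
        marker = "C" if rng.randbelow(2) else "A"
        L = len(body) + 3 + rng.randbelow(40)
        padded = pad(body, L, marker, bank)
        assert len(padded) == L
        assert unpad(padded) == (body, marker)


def test_padding_improves_gc_statistically(bank):
    """Mean |GC - 0.5| of padded outputs is below that of the inputs."""
    rng = SplitMix64(33)
    raw_dev, padded_dev = [], []
    for _ in range(1000):
        gc_target = 0.1 + 0.8 * rng.next_float()
        body = "".join(
            ("GC"[rng.randbelow(2)] if rng.next_float() < gc_target
             else "AT"[rng.randbelow(2)])
            for _ in range(40)
        )
        raw_dev.append(abs(gc_content(body) - 0.5))
        padded_dev.append(abs(gc_content(pad(body, 80, "C", bank)) - 0.5))
    assert sum(padded_dev) / 1000 < sum(raw_dev) / 1000


def test_bank_invariants():
    b = PaddingBank.generate(length=199, max_homopolymer=3, seed=4)
    for i, p in enumerate(b.sequences):
        assert len(p) == 199
        assert abs(gc_content(p) - i / 10) <= 0.02
        assert DELIMITER not in p
        assert max_homopolymer_run(p) <= 3
    # deterministic given the seed
    assert PaddingBank.generate(199, 3, 4).sequences == b.sequences


# --- permutation -----------------------------------------------------------


@pytest.mark.parametrize(
    "seq,expected",
    [("AGCTG", 2), ("AAAA", 0), ("ACGT", 1), ("AACCTTGG", 16)],
)
def test_compute_seed(seq, expected):
    assert compute_seed(seq) == expected


def test_seed_is_permutation_invariant():
    rng = SplitMix64(5)
    for _ in range(1000):
        seq = random_dna(rng, 2 + rng.randbelow(80))
        swaps = fisher_yates_swaps(len(seq), rng.next_u64())
        assert compute_seed(apply_swaps(seq, swaps)) == compute_seed(seq)


def test_fisher_yates_shape_and_determinism():
    assert fisher_yates_swaps(1, 99) == []
    a = fisher_yates_swaps(50, 1234)
    assert a == fisher_yates_swaps(50, 1234)
    assert len(a) == 49
    for expected_i, (i, j) in zip(range(49, 0, -1), a):
        assert i == expected_i and 0 <= j <= i


def test_fisher_yates_matches_independent_prng_reimplementation():
    """Cross-check the swap list against a from-scratch splitmix64."""

    def sm64_stream(seed):
        state = seed & 0xFFFFFFFFFFFFFFFF
        while True:
            state = (state + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
            z = state
            z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
            z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
            yield z ^ (z >> 31)

    for seed in (0, 1, 7, 123456789):
        stream = sm64_stream(seed)
        expected = [(i, next(stream) % (i + 1)) for i in range(4, 0, -1)]
        assert fisher_yates_swaps(5, seed) == expected


def test_permutation_worked_example():
    swaps = [(3, 2), (2, 2), (1, 0)]
    assert apply_swaps("ACTC", swaps) == "CACT"
    assert invert_swaps("CACT", swaps) == "ACTC"
    assert apply_swaps("AG", [(1, 1)]) == "AG"


def test_swap_index_out_of_range():
    with pytest.raises(IndexError):
        apply_swaps("ACG", [(3, 0)])


def test_select_best_permutation_contract():
    thr, w = ConstraintThresholds(), ErrorWeights()
    k, out = select_best_permutation("ACGTACGT", 1, w, thr)
    assert k == 0 and sorted(out) == sorted("ACGTACGT")
    k0, out0 = select_best_permutation("ACGTACGT", 0, w, thr)
    assert (k0, out0) == (0, "ACGTACGT")  # n=0 means identity
    rng = SplitMix64(44)
    for _ in range(200):
        seq = random_dna(rng, 20 + rng.randbelow(40))
        _, best8 = select_best_permutation(seq, 8, w, thr)
        _, best1 = select_best_permutation(seq, 1, w, thr)
        assert error_score(best8, w, thr) <= error_score(best1, w, thr)


def test_mean_error_decreases_with_more_permutations():
    """Best-of-n selection: mean error strictly drops from n=1 to n=32."""
    thr, w = ConstraintThresholds(), ErrorWeights()
    rng = SplitMix64(55)
    seqs = [random_dna(rng, 60) for _ in range(1000)]
    mean = {}
    for n in (1, 32):
        mean[n] = sum(
            error_score(select_best_permutation(s, n, w, thr)[1], w, thr)
            for s in seqs
        ) / len(seqs)
    assert mean[32] < mean[1]


def test_distinct_seeds_give_distinct_permutations():
    """The 32 candidate shuffles of one sequence are pairwise distinct in
    at least 99% of random length-60 sequences."""
    rng = SplitMix64(66)
    all_distinct = 0
    for _ in range(1000):
        seq = random_dna(rng, 60)
        seed = compute_seed(seq)
        perms = {
            apply_swaps(seq, fisher_yates_swaps(60, (seed + k) & MASK64))
            for k in range(32)
        }
        all_distinct += len(perms) == 32
    assert all_distinct >= 990


# --- offset prefix ---------------------------------------------------------


def test_offset_prefix_examples_and_roundtrip():
    assert attach_offset_prefix("", 0, 1) == "A"
    assert attach_offset_prefix("", 5, 2) == "CC"  # base-4 numeral 11
    for r in range(4):
        for k in range(4**r):
            got_k, rest = read_offset_prefix(
                attach_offset_prefix("GATTACA", k, r), r
            )
            assert (got_k, rest) == (k, "GATTACA")
    with pytest.raises(ValueError):
        attach_offset_prefix("A", 4, 1)


# --- composition -----------------------------------------------------------


@pytest.mark.parametrize("n", [1, 4, 32])
def test_transform_roundtrip(bank, n):
    thr, w = ConstraintThresholds(), ErrorWeights()
    r_off = 0
    while 4**r_off < n:
        r_off += 1
    rng = SplitMix64(77 + n)
    for _ in range(334):
        body = random_dna(rng, rng.randbelow(50))
        marker = "C" if rng.randbelow(2) else "A"
        L = len(body) + 3 + rng.randbelow(30)
        out = transform_forward(body, L, marker, n, r_off, bank, w, thr)
        assert len(out) == r_off + L
        assert transform_inverse(out, n, r_off) == (body, marker)


def test_transform_length_matches_worked_example(bank):
    # L = 12 with a 2-base offset reserve gives a total length of 14
    out = transform_forward(
        "GTGTTA", 12, "C", 3, 2, bank, ErrorWeights(), ConstraintThresholds()
    )
    assert len(out) == 14
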