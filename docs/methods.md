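# Methods

This note documents the codec's model, its tunables, the numerical and
design choices that were genuinely open, what the synthetic fixtures do and
do not emulate, and known limitations.

## Biochemical constraint model

Five constraints drive every encoding decision: C1 — GC content near 50%;
C2 — no long homopolymer runs; C3/C4/C5 — low pairwise similarity among
barcodes, payloads and whole oligos (cross-hybridization noise). C1/C2 are
hard predicates with thresholds (defaults: GC ∈ [0.40, 0.60], maximum run
3). C3–C5 are audited statistically via MinHash/LSH rather than enforced
per pair. Candidate sequences are ranked by the scalar error

```
error(s) = w_gc·|gc(s) − 0.5| + w_hp·(Σ_runs max(0, run − H)) / |s|
```

with default weights (1, 1) and H the homopolymer bound. This functional is
zero exactly when C1 is ideally met (GC = 50%) and C2 holds, and is
monotone in both defect types; its precise shape is a package choice — any
functional with those properties yields the same qualitative behaviour, and
only relative ranking of candidates matters.

## Stabilizer transforms

**Padding.** A body is framed `marker · body · "AC"` (marker `C` =
single-oligo payload, `A` = segment of a segmented payload) and filled to
the target length with a prefix of one of eleven bank sequences p_0…p_10
(GC 0%…100% in 10% steps, within ±2 points). The bank is generated
deterministically from the master seed by steered sampling: exact GC
budget, no `AC` substring, no run above the homopolymer bound — under these
rules a legal base always exists, so generation never backtracks. Because
the bank is `AC`-free and the junction after the delimiter's `C` cannot
create a new `AC`, the *rightmost* `AC` in a padded frame is always the
delimiter; decoding is unambiguous even when the body itself contains `AC`.
The bank index formula is clamped to [0, 10] on both sides (the raw value
exceeds 10 for very AT-rich short remainders).

**Permutation.** n candidate Fisher–Yates shuffles are generated with
seeds `seed + k`, where `seed` is the product of the four base counts —
a multiset invariant, hence recomputable from the permuted sequence. The
PRNG is a fixed splitmix64 recurrence (constants in `cbbdna/_prng.py`), so
swap lists are reproducible across platforms and languages; bounded draws
use modulo reduction (bias < 2⁻³², irrelevant at these bound sizes).
`seed = 0` (some base absent) is a legal seed. The chosen offset k is
written as an unpermuted quaternary prefix of `r_off = ⌈log₄ max(n,1)⌉`
bases — it must be readable before the permutation can be rebuilt. The
composed transform ranks candidates on the *emitted* sequence (prefix
attached), preferring C1/C2-passing candidates, then lower error, then
smaller k; this stops the prefix from silently extending a homopolymer
across the junction. `n = 0` means "no permutation" (identity, no prefix).

## Barcodes

Pipeline: `(attribute, value)` → `"value=emanetubirtta"` (reversal puts the
varying characters first, where the stateful converters are most
sensitive) → static Huffman code (fixed frequency profile shipped as a
constant: English-letter weights, digits, and the punctuation that rendered
values contain; all 256 byte values covered; a reserved end symbol
terminates every stream) → DNA conversion → padding → permutation. The
four converters:

| converter | base | rule |
|---|---|---|
| NaiveQuattro | 4 | stateless 0A 1C 2G 3T |
| RotatingQuattro | 4 | emitted index = (prev + digit + 1) mod 4 |
| RotatingTre | 3 | the 3 bases ≠ prev, alphabetical, indexed by digit |
| Bin | 2 | bit pairs 00A 01T 10C 11G, one pad bit when odd |

RotatingQuattro's state chain makes one changed digit re-key every later
base, which is what keeps barcodes of near-identical values far apart;
RotatingTre is structurally homopolymer-free. Injectivity holds because the
mapping is injective, Huffman codes are prefix-free and end-terminated, and
the transform is invertible. Value rendering is canonical (decimal for
integers, pass-through for text), since barcode determinism requires one
rendering per value.

## Payload coding

Payload bytes (packed record, or delta+varint-coded posting list; both
DEFLATE-compressed — raw streams, level 9, no metadata, hence byte-
deterministic) are extended with a CRC32 and expanded into *repair-only*
fountain packets over GF(256): packet ESI e carries Σᵢ cᵢ(e)·sᵢ with dense
coefficients derived from (e, k) via splitmix64. Verbatim source symbols
are never emitted — repetitive payloads would carry homopolymers straight
into the DNA — and dense random combinations both look random and give the
code its strength: any k + ε packets fail to decode only when their
coefficient matrix is rank-deficient, probability ≈ 256^−(ε+1). Default
ε = 2. The CRC turns any undetected channel corruption into a reported
decode failure rather than a silently wrong record; an all-zero payload is
reported as unencodable (its packets cannot satisfy C2).

Packets whose payload DNA fails C1/C2 are discarded; generation continues
until k + ε survivors exist *and* a trial decode of exactly those survivors
succeeds, with a design cap of 100·k generated packets. The constraint
check applies to the packet payload, not to the fixed-width ESI numeral or
the message header — these are framing, like the header fields themselves,
and the whole Info-DNA is permuted afterwards.

Frame layout (quaternary numerals, digit map 0A 1C 2G 3T): version (2
bases), packet count (8), symbol size (8), transfer length (16), then per
packet ESI (8) + payload (4 bases/byte). Symbol size is
`max(4, ⌈transfer/64⌉)` bytes, keeping k ≤ 64 at desk scale.

## Segmentation and queries

Payloads whose coded DNA exceeds one oligo are split into
`m = ⌈|seq|/(L_Info − c − r)⌉` uniform slices (slice i starts at
`(i−1)·⌈|seq|/m⌉`; the final slice may be shorter). A header oligo, keyed
by the base barcode, stores m plus the attribute/value pair — embedding the
pair is what lets both the query path and a full-table decode re-derive the
segment barcodes `value.i` with no stored index. The header caps its own
fountain redundancy at its oligo's capacity. Segmentation triggers on
length alone, once; there is no iterative re-segmentation on a failed
similarity audit.

Reassembly is gap-tolerant: slice geometry follows from m and the message
header at the start of slice 1, so a missing non-leading segment only
discards the packets overlapping it, and the fountain redundancy absorbs
the loss. The strict `assemble` contract (all m segments or an error
naming the missing indices) is kept for callers that need it; losing the
leading slice (which holds the frame header) is reported as an incomplete
segment set.

Queries count *sequential hybridization rounds*; one `hybridize` call —
however many probes it prints — is one round. Unique attribute: round 1
fetches the record (or its segment header), round 2 fetches all segments
in parallel; ≤ 2 rounds. Non-unique: rounds 1–2 build the posting list,
rounds 3–4 fetch all listed records in parallel; ≤ 4 rounds. Hybridization
is modelled as exact matching on the barcode prefix (complement-strand
binding treated as identity), with an optional Hamming tolerance for
cross-hybridization studies.

Record messages pack **all** schema attributes, including the primary key,
behind a one-byte message tag (record / posting list / segment header).
The key costs a few bytes per record but makes the pool self-describing:
a full-table decode needs only oligos + metadata, never a key inventory.

## Similarity auditing

k-shingle MinHash with r multiply-add 64-bit hash functions (parameters
from one hash seed; shingles 2-bit packed and dispersed through a
splitmix64 finalizer) estimates Jaccard similarity with standard error
√(J(1−J)/r); banding r rows into b bands surfaces candidate pairs with the
usual S-curve recall 1 − (1 − J^(r/b))^b. Defaults (k=4, r=200, b=20).
Pool statistics are exhaustive below 10,000 sequences and otherwise use a
fixed-size seeded sample of 100,000 pairs — all-pairs computation at
millions of oligos is precisely what LSH exists to avoid.

A caveat observed in this implementation's experiments: with n ≥ 1 a
seeded Fisher–Yates shuffle already randomizes base order completely, so
the *mean* pairwise distance over all barcode pairs saturates near the
unrelated-pair baseline and is flat (to within ±0.3%) in n. What more
permutations demonstrably buy is fewer *similar* pairs: the count of pairs
above the similarity threshold falls sharply with n under RotatingQuattro,
and the mean barcode error falls monotonically (candidate sets are nested,
so this is exact). Distance gains at the mean level require comparing
against no permutation at all (n = 0).

## Defaults

| parameter | default | note |
|---|---|---|
| L_Oligo / L_CBB / L_Info | 250 / 60 / 190 bases | synthesis-scale oligo length; 60 bases hold every fixture value with padding room |
| n (permutations) | 8 | speed/quality compromise; 32 makes every emitted barcode pass C1/C2 outright and is used where that is asserted |
| c (segment pad reserve) | 10 bases | ≥ 3 required (marker + delimiter) |
| ε (fountain redundancy) | 2 | ≈ 256⁻³ residual failure probability |
| thresholds | GC ∈ [0.4, 0.6], run ≤ 3, similarity ≤ 0.5 | standard synthesis guidance |
| LSH (k, r, b) | (4, 200, 20) | r/b = 10 rows per band |
| symbol size | max(4, ⌈bytes/64⌉) | keeps k ≤ 64 |

All randomness flows from `master_seed` (padding bank, channel simulation,
pair sampling); encoding itself is deterministic given the configuration.

## Fixtures: what they do and do not emulate

The toy table (4 records, attributes Id/Time/Velocity) exercises every code
path: segmented records, posting lists, both query kinds. `random_table`
generates integer-keyed tables whose text attributes draw from pools of
configurable cardinality, so posting lists have controllable expected
length (rows/cardinality). The generators emulate table *shape* —
key structure, value cardinality, posting-list length — not the value
distributions, column correlations or record widths of real operational
data; nor do the tests model thermodynamic hybridization, polymerase
errors, or synthesis yield. Passing tests show the codec's combinatorial
and statistical contracts hold, not that a wet-lab run would succeed.
The channel simulator applies i.i.d. per-base substitutions/indels and
per-oligo dropout — a stress harness for the redundancy contract, not a
sequencer error model.

## Sizes used by the shipped experiments

Statistical tests run at desk scale by design: 5,000 barcodes for the
permutation-count sweep, 10,000 for the converter ranking, 100-trial
erasure experiments, 500-row tables for the end-to-end roundtrip. These
sizes give stable statistics (MinHash mean-estimate noise < 10⁻³ at
12.5 M pairs) while keeping the whole suite in minutes on one CPU.

## Known limitations

* Range predicates are out of scope — barcodes are not locality-preserving.
* Filter attributes must be declared at encoding time.
* Hybridization is information-level (exact/Hamming matching), not
  thermodynamic; melting temperature and secondary structure are not
  modelled.
* Each logical oligo exists in one copy; physical copy redundancy is
  represented only through the erasure-channel experiments.
* The fountain decoder is dense Gaussian elimination, O(k³) — fine for
  k ≤ 64 payload symbols, not tuned for large single messages.
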