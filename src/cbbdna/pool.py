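"""The oligo pool, in-silico hybridization, table encoders and queries.

A :class:`Pool` is nothing but the multiset of oligo sequences plus the
codec metadata (configuration and table schema) needed to interpret them
-- deliberately *no* per-object index, because retrieval is
content-addressed: a query renders its predicate ``attribute=value`` as a
barcode, "prints" it on a simulated microarray, and keeps the oligos
whose barcode prefix hybridizes (matches within a Hamming tolerance,
exact by default, standing in for complement-strand binding).

Query cost is counted in *sequential hybridization rounds*: one
:func:`hybridize` call is one round regardless of how many probes it
carries, mirroring microarray parallelism. Unique-attribute queries need
at most two rounds (record, then its segments); non-unique queries at
most four (posting list, its segments, the records, their segments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .codec import (
    Codec,
    TAG_POSTING,
    TAG_RECORD,
    TAG_SEGMENT_HEADER,
)
from .cbb import canonical_text
from .config import CodecConfig
from .errors import CodecError, DecodeError, DuplicateKeyError
from .info import unpack_record
from .schema import TableSchema
from .transforms import MARKER_SEGMENTED, MARKER_SINGLE
from ._prng import SplitMix64, mix64

log = logging.getLogger(__name__)


@dataclass
class Pool:
    """Oligo multiset plus the metadata required for self-contained decode."""

    oligos: list
    config: CodecConfig
    schema: TableSchema
    meta: dict = field(default_factory=dict)

    _codec: Codec = field(default=None, repr=False, compare=False)

    @property
    def codec(self) -> Codec:
        if self._codec is None:
            self._codec = Codec(self.config)
        return self._codec

    def cbb_part(self, oligo: str) -> str:
        return oligo[: self.config.l_cbb]

    def info_part(self, oligo: str) -> str:
        return oligo[self.config.l_cbb :]

    def validate_lengths(self):
        for i, o in enumerate(self.oligos):
            if len(o) != self.config.l_oligo:
                raise CodecError(
                    f"oligo {i} has length {len(o)}, expected {self.config.l_oligo}"
                )


@dataclass
class QueryResult:
    """Decoded records plus the cost accounting of the retrieval."""

    records: list
    sequential_rounds: int
    oligos_read: int
    matched_ids: list = field(default_factory=list)

    def to_records(self):
        return list(self.records)


def _hamming_within(a: str, b: str, t: int) -> bool:
    if len(a) != len(b):
        return False
    budget = t
    for x, y in zip(a, b):
        if x != y:
            budget -= 1
            if budget < 0:
                return False
    return True


def hybridize(pool: Pool, probes, mismatch_tolerance: int = 0):
    """One simulated microarray round: oligos whose barcode prefix matches
    some probe within the Hamming tolerance (0 = exact binding)."""
    probes = list(probes)
    if not probes:
        return []
    plen = len(probes[0])
    if any(len(p) != plen for p in probes):
        raise ValueError("all probes in one round must share a length")
    if mismatch_tolerance == 0:
        probe_set = set(probes)
        return [o for o in pool.oligos if o[:plen] in probe_set]
    return [
        o
        for o in pool.oligos
        if any(_hamming_within(o[:plen], p, mismatch_tolerance) for p in probes)
    ]


# ---------------------------------------------------------------------------
# table encoding
# ---------------------------------------------------------------------------


def encode_table(
    table,
    schema: TableSchema,
    config: CodecConfig,
    unique_attrs=None,
    nonunique_attrs=None,
) -> Pool:
    """Encode a relational table (a pandas DataFrame) into an oligo pool.

    Every value of each unique attribute becomes barcode + full record;
    every distinct value of each non-unique attribute becomes barcode +
    posting list of primary keys. Filterable attributes must be declared
    here -- predicates on anything else cannot be answered later.
    """
    pk = schema.primary_key
    unique_attrs = list(unique_attrs) if unique_attrs is not None else [pk]
    nonunique_attrs = list(nonunique_attrs or [])
    if pk not in unique_attrs:
        unique_attrs.insert(0, pk)
    rows = table.to_dict("records")
    keys = [canonical_text(r[pk]) for r in rows]
    seen = set()
    for k in keys:
        if k in seen:
            raise DuplicateKeyError(f"duplicate primary key value {k!r}")
        seen.add(k)

    codec = Codec(config)
    oligos = []
    n_segmented = 0
    for attr in unique_attrs:
        vals = [canonical_text(r[attr]) for r in rows]
        if len(set(vals)) != len(vals):
            raise DuplicateKeyError(f"attribute {attr!r} is not unique")
        for row in rows:
            message = codec.record_message(row, schema.names)
            enc = codec.encode_object(attr, row[attr], message)
            oligos.extend(enc.oligos())
            n_segmented += enc.segmented
    for attr in nonunique_attrs:
        groups = {}
        for row in rows:
            groups.setdefault(canonical_text(row[attr]), []).append(row[pk])
        for value in sorted(groups):
            ids = [int(i) for i in groups[value]]
            if any(i < 0 for i in ids):
                raise ValueError("posting lists require non-negative integer keys")
            enc = codec.encode_object(attr, value, codec.posting_message(ids))
            oligos.extend(enc.oligos())
            n_segmented += enc.segmented
    log.info(
        "encoded %d rows into %d oligos (%d segmented objects)",
        len(rows), len(oligos), n_segmented,
    )
    schema = TableSchema(
        attributes=schema.attributes,
        primary_key=pk,
        filterable=tuple(dict.fromkeys(list(unique_attrs) + nonunique_attrs)),
    )
    pool = Pool(oligos=oligos, config=config, schema=schema,
                meta={**codec.metadata(), "unique_attrs": unique_attrs,
                      "nonunique_attrs": nonunique_attrs})
    pool._codec = codec
    pool.validate_lengths()
    return pool


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------


def _typed(record_text: dict, schema: TableSchema) -> dict:
    return {n: schema.coerce(n, record_text[n]) for n in schema.names}


def _fetch_message(pool: Pool, attribute: str, value, tolerance: int = 0):
    """Fetch and decode the message stored under (attribute, value).

    Returns ``(tag, body, rounds, oligos_read)``; ``(None, None, 1, 0)``
    when nothing hybridizes.
    """
    codec = pool.codec
    probe = codec.encode_cbb(attribute, value)
    hits = hybridize(pool, [probe], tolerance)
    rounds, read = 1, len(hits)
    if not hits:
        return None, None, rounds, read
    tag, body, marker = codec.decode_single(pool.info_part(hits[0]))
    if marker == MARKER_SINGLE:
        return tag, body, rounds, read
    if tag != TAG_SEGMENT_HEADER:
        raise DecodeError("segmented marker without a segment-count header")
    m, attr2, val2 = body
    probes = {codec.segment_cbb(attr2, val2, i): i for i in range(1, m + 1)}
    seg_hits = hybridize(pool, list(probes), tolerance)
    rounds += 1
    read += len(seg_hits)
    bodies = {}
    for oligo in seg_hits:
        idx = probes.get(pool.cbb_part(oligo))
        if idx is None or idx in bodies:
            continue
        try:
            piece, marker = codec.inverse_info(pool.info_part(oligo))
        except CodecError:
            continue  # a corrupt segment counts as an erasure
        if marker == MARKER_SEGMENTED:
            bodies[idx] = piece
    tag, parsed = codec.decode_segments(bodies, m)
    return tag, parsed, rounds, read


def query_unique(pool: Pool, attribute: str, value,
                 mismatch_tolerance: int = 0) -> QueryResult:
    """Answer the filter predicate ``attribute = value`` on a unique
    attribute; at most two sequential hybridization rounds."""
    tag, body, rounds, read = _fetch_message(
        pool, attribute, value, mismatch_tolerance
    )
    if tag is None:
        return QueryResult([], rounds, read)
    if tag != TAG_RECORD:
        raise DecodeError(
            f"{attribute!r} is not encoded as a unique (record) attribute"
        )
    record = _typed(unpack_record(body, pool.schema.names), pool.schema)
    return QueryResult([record], rounds, read)


def query_nonunique(pool: Pool, attribute: str, value,
                    mismatch_tolerance: int = 0) -> QueryResult:
    """Answer ``attribute = value`` on a non-unique attribute: fetch the
    posting list, then all listed records in parallel; at most four
    sequential rounds."""
    codec = pool.codec
    schema = pool.schema
    tag, body, rounds, read = _fetch_message(
        pool, attribute, value, mismatch_tolerance
    )
    if tag is None:
        return QueryResult([], rounds, read)
    if tag != TAG_POSTING:
        raise DecodeError(
            f"{attribute!r} is not encoded as a non-unique (posting) attribute"
        )
    from .info import decompress_id_list

    ids = decompress_id_list(body)
    pk = schema.primary_key
    probes = {codec.encode_cbb(pk, i): i for i in ids}
    hits = hybridize(pool, list(probes), mismatch_tolerance)
    rounds += 1
    read += len(hits)
    records = []
    pending = []  # (id, m, attr, value) for segmented records
    for oligo in hits:
        ident = probes.get(pool.cbb_part(oligo))
        if ident is None:
            continue
        tag2, body2, marker = codec.decode_single(pool.info_part(oligo))
        if marker == MARKER_SINGLE and tag2 == TAG_RECORD:
            records.append(_typed(unpack_record(body2, schema.names), schema))
        elif tag2 == TAG_SEGMENT_HEADER:
            m, attr2, val2 = body2
            pending.append((ident, m, attr2, val2))
        else:
            raise DecodeError(f"unexpected message under key {ident!r}")
    if pending:
        seg_probes = {}
        for ident, m, attr2, val2 in pending:
            for i in range(1, m + 1):
                seg_probes[codec.segment_cbb(attr2, val2, i)] = (ident, i)
        seg_hits = hybridize(pool, list(seg_probes), mismatch_tolerance)
        rounds += 1
        read += len(seg_hits)
        per_record = {ident: {} for ident, *_ in pending}
        for oligo in seg_hits:
            hit = seg_probes.get(pool.cbb_part(oligo))
            if hit is None:
                continue
            ident, i = hit
            try:
                piece, marker = codec.inverse_info(pool.info_part(oligo))
            except CodecError:
                continue
            if marker == MARKER_SEGMENTED and i not in per_record[ident]:
                per_record[ident][i] = piece
        for ident, m, _attr, _val in pending:
            tag2, message = codec.decode_segments(per_record[ident], m)
            if tag2 != TAG_RECORD:
                raise DecodeError(f"unexpected message under key {ident!r}")
            records.append(_typed(unpack_record(message, schema.names), schema))
    records.sort(key=lambda r: r[pk])
    return QueryResult(records, rounds, read, matched_ids=sorted(ids))


def fetch_posting_list(pool: Pool, attribute: str, value):
    """Decode just the posting list for (attribute, value).

    Returns ``(sorted ids, sequential_rounds)``; ``([], 1)`` on no match.
    """
    tag, body, rounds, _ = _fetch_message(pool, attribute, value)
    if tag is None:
        return [], rounds
    if tag != TAG_POSTING:
        raise DecodeError(f"{attribute!r} does not carry posting lists")
    from .info import decompress_id_list

    return sorted(decompress_id_list(body)), rounds


# ---------------------------------------------------------------------------
# full-table decode
# ---------------------------------------------------------------------------


def decode_table(pool: Pool):
    """Rebuild the stored table from oligos + metadata alone.

    Single-oligo record messages decode directly; segment headers are
    reassembled by re-deriving their segment barcodes. Posting lists are
    derived data and are skipped. Returns a DataFrame sorted by key.
    """
    import pandas as pd

    codec = pool.codec
    schema = pool.schema
    records = {}
    headers = []
    for oligo in pool.oligos:
        try:
            tag, body, marker = codec.decode_single(pool.info_part(oligo))
        except CodecError:
            continue  # segment slices are not standalone messages
        if marker == MARKER_SINGLE and tag == TAG_RECORD:
            rec = _typed(unpack_record(body, schema.names), schema)
            records[rec[schema.primary_key]] = rec
        elif marker == MARKER_SEGMENTED and tag == TAG_SEGMENT_HEADER:
            headers.append(body)
    for m, attr, value in headers:
        probes = {codec.segment_cbb(attr, value, i): i for i in range(1, m + 1)}
        bodies = {}
        for oligo in hybridize(pool, list(probes)):
            idx = probes.get(pool.cbb_part(oligo))
            if idx is None or idx in bodies:
                continue
            piece, marker = codec.inverse_info(pool.info_part(oligo))
            if marker == MARKER_SEGMENTED:
                bodies[idx] = piece
        tag, message = codec.decode_segments(bodies, m)
        if tag == TAG_RECORD:
            rec = _typed(unpack_record(message, schema.names), schema)
            records[rec[schema.primary_key]] = rec
    frame = pd.DataFrame(
        sorted(records.values(), key=lambda r: r[schema.primary_key]),
        columns=list(schema.names),
    )
    return frame


# ---------------------------------------------------------------------------
# error channel
# ---------------------------------------------------------------------------


def inject_channel_errors(
    pool: Pool,
    sub_rate: float = 0.0,
    del_rate: float = 0.0,
    ins_rate: float = 0.0,
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> Pool:
    """Stress harness: per-base substitutions/indels and per-oligo dropout.

    Deterministic given *seed*. The returned pool may hold oligos of
    unequal length when indel rates are non-zero; decoding such oligos is
    expected to fail loudly, never silently.
    """
    for rate in (sub_rate, del_rate, ins_rate, dropout_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = SplitMix64(mix64(seed ^ 0x6368616E))  # "chan"
    bases = "ACGT"
    damaged = []
    for oligo in pool.oligos:
        if dropout_rate and rng.next_float() < dropout_rate:
            continue
        if not (sub_rate or del_rate or ins_rate):
            damaged.append(oligo)
            continue
        out = []
        for base in oligo:
            if ins_rate and rng.next_float() < ins_rate:
                out.append(bases[rng.randbelow(4)])
            if del_rate and rng.next_float() < del_rate:
                continue
            if sub_rate and rng.next_float() < sub_rate:
                others = bases.replace(base, "")
                out.append(others[rng.randbelow(3)])
            else:
                out.append(base)
        damaged.append("".join(out))
    new = Pool(oligos=damaged, config=pool.config, schema=pool.schema,
               meta=dict(pool.meta))
    new._codec = pool._codec
    return new
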