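"""CSV, FASTA and metadata I/O.

Pools persist as a FASTA file (one record per oligo, opaque running ids
-- never content-derived, which would amount to an in-silico index) plus
a JSON metadata sidecar holding the codec configuration and table schema.
That pair is everything needed to decode: reloading in a fresh process
reproduces the pool bit-exactly.
"""

from __future__ import annotations

import json

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cbb import canonical_text
from .config import CodecConfig
from .errors import CodecError, DuplicateKeyError
from .pool import Pool
from .schema import TableSchema

POOL_FORMAT_VERSION = 1


def read_table_csv(path, schema: TableSchema) -> pd.DataFrame:
    """Read a typed table; validates columns and primary-key uniqueness."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [n for n in schema.names if n not in frame.columns]
    if missing:
        raise CodecError(f"CSV is missing columns {missing}")
    frame = frame[list(schema.names)]
    for name, typ in schema.attributes:
        if typ == "integer" and len(frame):
            frame[name] = frame[name].astype("int64")
    keys = frame[schema.primary_key].tolist()
    seen = set()
    for k in keys:
        ck = canonical_text(k)
        if ck in seen:
            raise DuplicateKeyError(
                f"duplicate primary key value {ck!r} in {path}"
            )
        seen.add(ck)
    return frame


def write_table_csv(frame: pd.DataFrame, path):
    frame.to_csv(path, index=False)


def write_pool(pool: Pool, fasta_path, meta_path):
    """Persist oligos (FASTA) and decoding metadata (JSON sidecar)."""
    records = [
        SeqRecord(Seq(o), id=f"oligo_{i}", description="")
        for i, o in enumerate(pool.oligos)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    meta = {
        "format_version": POOL_FORMAT_VERSION,
        "config": pool.config.to_dict(),
        "schema": pool.schema.to_dict(),
        **{k: v for k, v in pool.meta.items() if k != "config"},
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def read_pool(fasta_path, meta_path) -> Pool:
    """Inverse of :func:`write_pool`; validates oligo lengths."""
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta.get("format_version") != POOL_FORMAT_VERSION:
        raise CodecError("unsupported pool metadata version")
    config = CodecConfig.from_dict(meta["config"])
    schema = TableSchema.from_dict(meta["schema"])
    oligos = [
        str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    pool = Pool(
        oligos=oligos,
        config=config,
        schema=schema,
        meta={k: v for k, v in meta.items()
              if k not in ("format_version", "config", "schema")},
    )
    pool.validate_lengths()
    return pool
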