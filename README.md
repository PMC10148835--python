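# cbbdna — content-addressable DNA data storage for relational tables

`cbbdna` encodes relational tables into pools of fixed-length synthetic DNA
oligonucleotides so that **ad-hoc filter queries can be answered on the DNA
pool alone**, with no in-silico index. It is aimed at researchers studying
DNA data storage systems who want a desk-scale, fully reproducible codec and
query simulator.

## The idea

Every oligo of length `L_Oligo` is the concatenation of two parts:

```
oligo = CBB (L_CBB bases)  ||  Info-DNA (L_Info = L_Oligo − L_CBB bases)
```

* The **content-based barcode (CBB)** is derived deterministically from one
  `attribute=value` pair: the rendered string is reversed, compressed with a
  static Huffman code, converted to bases (converters `NaiveQuattro`,
  `RotatingQuattro`, `RotatingTre`, `Bin`), padded toward 50% GC content and
  permuted. Distinct values always give distinct barcodes
  (`v ≠ w ⇔ CBB_v ≠ CBB_w`), and the same value always gives the same
  barcode, so a barcode doubles as the *address* of its oligo: printing it on
  a (simulated) microarray retrieves the oligo by hybridization.
* The **Info-DNA** carries the payload — a packed record, or the posting
  list of primary keys sharing one value of a non-unique attribute —
  compressed (DEFLATE), expanded into fountain-code repair packets over
  GF(256) (any `k + ε` packets reconstruct a `k`-symbol message with
  overwhelming probability), filtered against biochemical constraints, and
  mapped to bases two bits at a time (`00→A, 01→T, 10→C, 11→G`).

Two reversible stabilizer transforms are applied to every barcode and every
payload segment: *padding* with one of eleven pre-computed sequences
(GC contents 0%…100% in 10% steps, index
`i = max(0, ⌊10·(L/2 − |seq|_GC)/(L − |seq|)⌋)`), and a *best-of-n seeded
permutation* (Fisher–Yates with seed `|seq|_A·|seq|_C·|seq|_T·|seq|_G + k`,
the offset `k` stored as a quaternary prefix). Both keep GC near 50% and
suppress homopolymers, the two dominant synthesis/sequencing error sources.

Payloads longer than one oligo are **segmented**:
`m = ⌈|seq| / (L_Info − c − r)⌉` segments, a header oligo storing `m`, and
per-segment barcodes derived by suffixing the value with `.i`. A filter
query on a unique attribute therefore needs at most **2** sequential
hybridization rounds, and on a non-unique attribute at most **4**.

Similarity among barcodes, payloads and oligos (cross-hybridization noise)
is audited with MinHash/LSH-estimated Jaccard distances.

## Worked example

```bash
cbbdna fixture --kind toy --out-csv toy.csv --out-schema toy.schema.json
cbbdna encode --csv toy.csv --schema toy.schema.json \
              --out-pool pool.fa --out-meta pool.json --nonunique Velocity
cbbdna query --pool pool.fa --meta pool.json --attr Id --value 101
```

The toy table holds four flight-tracking records (Ids 100–103). Encoding
produces 14 oligos of 250 bases each: one record object per Id (each
segmented into a header plus two segment oligos at this geometry) and one
posting-list oligo per distinct Velocity value. The query prints:

```json
{
  "records": [
    {"Id": 101, "Time": 332012549, "Velocity": 280}
  ],
  "sequential_rounds": 2,
  "oligos_read": 3
}
```

`sequential_rounds: 2` — one hybridization fetched the header oligo keyed
by the barcode of `Id=101` (whose Info-DNA says the record spans m=2
segments), and one parallel hybridization fetched both segments, which were
then reassembled and fountain-decoded. A non-unique query
(`--attr Velocity --value 512`) decodes the posting list `[100, 103]` first
and then fetches those records in parallel, here in 3 sequential rounds
(bounded by 4).

The same pipeline is available as a library:

```python
from cbbdna import CodecConfig, encode_table, query_unique, toy_table

table, schema = toy_table()
pool = encode_table(table, schema, CodecConfig(master_seed=1),
                    nonunique_attrs=["Velocity"])
print(query_unique(pool, "Id", 101).records)
# [{'Id': 101, 'Time': 332012549, 'Velocity': 280}]
```

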