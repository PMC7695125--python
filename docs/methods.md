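# Methods

## The model: NoDB-style in-situ queries over indexed genomic files

`trackquery` treats the indexed file formats the genomics community
already uses as the database. A BBI file (BigWig for continuous signal,
BigBed for interval records) embeds a chromosome B+ tree and an R-tree
over `(chromosome, start, end)` regions whose leaves point at
(optionally deflate-compressed) data blocks; a Tabix `.tbi` index maps
a hierarchical position binning to chunks of a BGZF-compressed table.
A range query therefore decomposes into: resolve the chromosome id,
walk only the index nodes whose bounding region overlaps the query,
fetch the overlapping data blocks, decode, and overlap-filter. Every
read goes through one byte-range layer (`range_io`) that works
identically over local files (positional reads) and HTTP URLs (RFC 7233
`Range:` requests, 206 expected), so remote files cost exactly the same
*byte ranges* as local ones plus latency.

Assumptions: files conform to the BBI standard (magics `0x888FFC26` /
`0x8789F2EB`, B+ tree `0x78CA8C91`, R-tree `0x2468ACE0`, either byte
order) or to Tabix/BGZF; coordinates in results are uniformly 0-based
half-open (1-based tables are converted at parse time); a single signal
track has non-overlapping records (BigWig semantics — internal overlaps
are rejected, never silently averaged); Tabix coordinates stay below
2^29 (CSI is out of scope).

## Raw query semantics

Overlapping records are returned with their original, unclipped
coordinates. Clipping is deliberately left to the summarizer so the
parser is lossless: a browser fetching `chr1:512-515` over a 100 bp
tile gets the whole `[500, 600)` tile and its exact value. Values are
decoded as 32-bit floats and carried as such; round-trip tests compare
bit-for-bit at float32.

## Computed measurements

A `ComputeSpec` names an ordered source list, a NumPy-style function,
an axis and a missing policy. Evaluation per query:

1. fetch each source's raw frame for the query range (concurrently;
   results are assembled by source position, so completion order cannot
   affect the answer);
2. *disjoin*: cut the query range at every clipped record boundary of
   every source; each resulting sub-interval is covered-or-not by each
   source with a constant value; sub-intervals covered by no source are
   dropped (sparse payloads for rendering);
3. apply the function — row-wise across the k source values
   (`numpy.diff` giving successive differences in source-list order) or
   column-wise along each source column (e.g. mean centering). Output
   arity is fixed by the first row and enforced after.

Missing policy defaults to `propagate` (the function sees NaN and NaN
arithmetic flows through, matching array-library behavior);
`drop_row` and `fill_zero` cover the common analyst intents. Computed
sources may themselves be computed; evaluation recurses.

Where sources carry zoom levels, a binned computed query is evaluated
on raw-resolution aligned rows first and binned after (values-first).
The alternative — binning each source, then transforming — commutes
only for affine functions; values-first is the interpretation that
keeps `lazy == eager` exact for arbitrary functions.

## Summarization

`bins = b` over width `w` targets `⌊w / b⌋` bp per bin (the browser
example: 10,000 bp on an 800-pixel canvas → 12 bp per bin). Among the
file's zoom levels (reductions strictly increasing), the largest
reduction not exceeding the target is read; if even the finest is too
coarse, raw records are used. The range is split into `b` near-equal
bins (the first `w mod b` bins get one extra base) and each bin's value
is the overlap-weighted mean of record values, i.e. the per-base mean —
the unambiguous reading of "mean across the bin" and exact on
integer-coordinate fixtures. Zero-coverage bins carry NaN (JSON
`null`). Zoom records are whole-record: a record partially overlapping
the query edge contributes with its overlap weight; no sub-record
interpolation is attempted. Note that binning *zoom* records equals
binning raw data exactly only when bins align with zoom spans and
coverage is complete; tests exercise exactly that regime, and the
general case differs by design of the format, not of this library.

## Cache

Block cache keyed by `(uri, offset, length)`, capacity 256 MiB by
default (configurable; the right value depends on deployment, so it is
a parameter, not a constant). Eviction removes unpinned entries in
ascending (access frequency, last access) order — a deterministic
reading of "recently and frequently accessed". Pinned entries (file
header, zoom headers, chromosome tree — the metadata every query
touches) always survive, even if they alone exceed capacity, and the
stats report the overrun honestly. The cache is strictly transparent:
hits return the identical bytes a backend read would, verified
wholesale in tests. Parsed file objects can be serialized (magic +
version byte + pickled metadata and pinned blocks) and restored; a
restored handle answers queries byte-identically, re-reading only data
blocks. Spill-to-disk scheduling is left to the embedding application:
the library provides `save`/`load`, not a daemon.

## REST layer and concurrency

The server is a threaded stdlib HTTP server returning columnar JSON
(`rows.start[]`, `rows.end[]`, `values.<col>[]`) — column arrays
minimize payload for browser clients. The concurrency contract is
semantic, not mechanical: queries share only the thread-safe cache and
catalog, so any interleaving of overlapping requests yields payloads
identical to serial execution; tests issue concurrent batches and
assert equality. No authentication, no push channels.

## Synthetic data generator

Fixtures emulate the *shape* of browser data, not its content:

- `tiled_fixed_step` — uniform tiles covering every base
  (methylation-like; default step 100 bp);
- `random_intervals` — sparse non-overlapping intervals with random
  lengths (20–200 bp) and gaps (0–100 bp), bedGraph-like coverage;
- `peaks` — Poisson-placed summits with triangular signal of half-width
  500 bp, run-length encoded (ChIP-seq-like).

Values are uniform draws quantized to quarters in [0, 16): exactly
representable in float32, so round trips, zoom sums and bin means can
be asserted with no tolerance. The generators record full ground truth
(the interval list, and for BBI files the byte-accurate block layout),
which is what makes access-minimality assertions possible at all. The
BigWig/BigBed writer is this package's own (layout reporting requires
it); Tabix compression and indexing delegate to pysam/htslib so that
index *creation* stays independent of the query code under test, and
pyBigWig independently cross-reads the written files in tests.

What the fixtures do not emulate: real read-depth autocorrelation,
chromosome-scale files (test chromosomes are 50 kb–1 Mb), CSI-indexed
coordinates, and adversarially malformed files beyond byte flips and
truncation. Passing tests therefore demonstrate format conformance,
exact query semantics and access minimality — not performance on
hundred-gigabyte repositories.

## Numerical and design choices

- Zoom-record means are computed as `sum / valid_count` in float64 from
  float32-stored sums; a record with zero valid bases yields NaN and is
  excluded from bin weighting.
- `select_zoom_level` uses floor division and largest-not-exceeding;
  not-exceeding guarantees each output bin spans at least one zoom
  record boundary, so no bin is interpolated from coarser data.
- The remote-range probe is a 1-byte `Range:` GET; a 200 response means
  the server ignored the header and the resource is refused
  (`RangesUnsupported`) rather than silently streamed.
- Tabix chunks from multiple bins are merged (sort + coalesce) before
  scanning so no line is parsed twice; the linear index prunes chunks
  ending below the query window's lower bound.
- Tabular value columns are auto-typed numeric only when every
  retrieved cell parses; a per-measurement column schema overrides.
- Degenerate inputs: empty query results are zero-row frames with the
  measurement's value columns; a BBI file with no data gets a valid
  empty R-tree leaf; an all-pinned over-capacity cache evicts nothing.

## Problem sizes

Test fixtures use chromosomes of 50 kb–1 Mb with hundreds to thousands
of records per track, 20-fixture round-trip/oracle suites with 200
random regions each, 500-block files for fetch accounting, and
computed means over up to 20 sources — sizes chosen so the exact
per-base oracles (the strongest available checks) stay cheap while
every code path, including multi-level R-trees and multi-chunk Tabix
queries, is exercised. `scripts/acceptance.py` re-measures the same
quantities from freshly generated fixtures at a caller-supplied seed.

## Known limitations

BAM/SAM are not parsed (the base classes stop at BBI and Tabix); BigBed
autoSql schemas beyond tab-splitting are ignored; whole-genome
statistics from the total-summary block are not exposed; the cache is
per-process (no cross-process sharing); network hub importers are
replaced by a local JSON/manifest workflow.
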