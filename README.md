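# trackquery

In-situ query, transformation and REST serving of indexed genomic
files.

Genomic data repositories (ENCODE, Roadmap Epigenomics, hub listings)
publish signal and region data as flat indexed files — BigWig, BigBed
and Tabix-indexed tables. Loading them into a database just to look at
a few regions dominates the time-to-first-plot. `trackquery` instead
answers genomic-range queries *directly from the files*, local or on
any HTTP server that honors Range requests, by walking each file's own
spatial index and fetching only the byte ranges it points at. It is
written for tool builders (genome-browser backends, exploratory
analysis services) and analysts who want transformations over many
tracks without precomputing anything.

## What it does

- **BBI parsing** (BigWig / BigBed): 64-byte header, chromosome B+
  tree, R-tree block index, bedGraph / fixed-step / variable-step
  section decoding, zoom-level records — bit-exact against the format
  written by the UCSC/libBigWig tool chain, in either byte order.
- **Tabix / BGZF**: virtual-offset random access into BGZF blocks, the
  6-level / 37,449-bin position index, linear-index chunk pruning, and
  normalization of every table to 0-based half-open coordinates.
- **Computed measurements**: a named transformation `f` over an ordered
  list of source tracks. For a query range `[s, e)` on measurements
  `m_1..m_k` with record boundaries `B_i`, the engine forms the disjoint
  partition cut at `sort(unique(∪ B_i ∩ [s, e)))`, aligns each source's
  value per sub-interval (missing marker where uncovered), and applies
  `f` row-wise (`axis = across measurements`, e.g. `numpy.diff`) or
  column-wise (`axis = along rows`, e.g. mean centering). Evaluation is
  lazy: nothing is computed until the region is asked for.
- **Screen-resolution summaries**: for a `bins = b` request over width
  `w`, the target resolution is `⌊w / b⌋` bp per bin; the zoom level
  with the largest reduction not exceeding it is read (else raw
  records), then summarized to exactly `b` coverage-weighted means
  `Σ v_j · o_j / Σ o_j` (overlap `o_j` in bp), which equals the
  per-base mean of the signal in the bin.
- **Block cache**: `(uri, offset, length)` → bytes, LFU eviction with
  LRU tie-break; headers, chromosome trees and zoom headers are pinned.
  Parsed file objects serialize to disk and restore with their pinned
  blocks.
- **REST API + CLI**: `GET /measurements`, `GET /data?...` returning
  columnar JSON; `trackquery serve` and a one-shot `trackquery query`.

## Worked example

```python
from trackquery import BBIFile, BlockCache
from trackquery.fixtures import SyntheticTrackSpec, make_signal_track

spec = SyntheticTrackSpec(seed=42, chrom_sizes={"chr1": 200_000},
                          model="peaks", n_peaks=40, zoom=True)
truth = make_signal_track(spec, "signal.bw")

track = BBIFile(truth.path, cache=BlockCache())
frame = track.query("chr1", 50_000, 60_000)
print(len(frame), track.handle.fetch_count, track.handle.bytes_fetched)
```

Running `python examples/01_query_bigwig.py` (this example with fetch
accounting) prints:

```
file: .../signal.bw (71593 bytes, 3768 intervals)
query chr1:50,000-60,000 -> 75 records
  chrom  start    end  value
0  chr1  55082  55095   0.25
...
backend reads: 12, bytes fetched: 1382 (1.9% of file)
```

75 signal intervals overlap the region; answering took 12 byte-range
reads totaling 1.9% of the file — the header, the index path and the
few data blocks covering the region, nothing else. The other scripts in
`examples/` demonstrate lazy computed measurements, zoom/bin
summarization (`zoom:10:binned:800` for a 10 kb window on 800 pixels)
and the REST API.

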