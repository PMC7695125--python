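"""Screen-resolution summarization: zoom levels and bin means.

A genome browser drawing a 10,000 bp window into 800 pixels needs ~12 bp
per bin, so the engine reads the zoom level with the largest reduction
not exceeding that, then summarizes to exactly the requested number of
coverage-weighted bin means.
"""
import os
import tempfile

from trackquery import (
    Catalog,
    FileMeasurement,
    GenomicRange,
    QueryEngine,
)
from trackquery.fixtures import SyntheticTrackSpec, make_signal_track

workdir = tempfile.mkdtemp()
spec = SyntheticTrackSpec(
    seed=9, chrom_sizes={"chr1": 1_000_000},
    model="tiled_fixed_step", step=100, zoom=True,
    zoom_reductions=(10, 40, 160, 640))
truth = make_signal_track(spec, os.path.join(workdir, "roadmap.bw"))
catalog = Catalog()
catalog.add(FileMeasurement("chip", "ChIP signal", truth.path,
                            "bigwig"))
engine = QueryEngine(catalog)

raw = engine.get_data("chip", GenomicRange("chr1", 500_000, 510_000))
print(f"raw query: {len(raw.frame)} records ({raw.resolution})")

binned = engine.get_data("chip", GenomicRange("chr1", 500_000, 510_000),
                         bins=800)
print(f"binned query: {len(binned.frame)} rows ({binned.resolution})")
print(binned.frame.head())
# resolution 'zoom:10:binned:800' means: 10,000 bp / 800 bins wants
# 12 bp per bin, the 10 bp zoom level was read instead of raw data,
# then summarized to 800 weighted means — far fewer values than the
# 100 raw records, and far fewer bytes than full resolution.
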