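"""Serve a catalog over REST and query it like a genome browser would.

Starts the JSON API on an ephemeral port, lists the measurements, and
fetches a binned region — the payload decodes to exactly the values an
in-process call returns.
"""
import json
import os
import tempfile
import urllib.request

import numpy as np

from trackquery import (
    ApiServer,
    Catalog,
    ComputeSpec,
    FileMeasurement,
    QueryEngine,
    add_computed_measurement,
)
from trackquery.fixtures import SyntheticTrackSpec, make_signal_track

workdir = tempfile.mkdtemp()
catalog = Catalog()
for i in range(2):
    spec = SyntheticTrackSpec(seed=10 + i,
                              chrom_sizes={"chr1": 100_000},
                              model="peaks", zoom=True)
    truth = make_signal_track(spec, os.path.join(workdir, f"s{i}.bw"))
    catalog.add(FileMeasurement(f"sample{i}", f"Sample {i}",
                                truth.path, "bigwig",
                                annotations={"assay": "H3K27ac"}))
add_computed_measurement(catalog, ComputeSpec(
    "mean", "Mean signal", ["sample0", "sample1"], np.mean))

with ApiServer(QueryEngine(catalog)) as server:
    listing = json.load(urllib.request.urlopen(
        server.url("/measurements")))
    print("measurements:",
          [(m["id"], m["type"]) for m in listing["data"]])

    url = server.url("/data?measurement=mean&chr=chr1"
                     "&start=20000&end=30000&bins=10")
    payload = json.load(urllib.request.urlopen(url))
    print("binned mean payload:")
    print(json.dumps(payload["data"], indent=2)[:600])
# 'values.mean' holds 10 coverage-weighted bin means of the lazily
# computed two-sample average; 'null' marks bins no sample covers.
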