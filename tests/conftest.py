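"""Shared synthetic-track fixtures.

All test data is generated at test time by the package's own seeded
generators; session scope keeps file writing off the hot path.
"""
import numpy as np
import pandas as pd
import pytest

from trackquery.core import GenomicRange
from trackquery.fixtures import (
    SyntheticTrackSpec,
    make_region_track,
    make_signal_track,
    make_tabular_track,
)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("tracks")


@pytest.fixture(scope="session")
def signal_track(fixture_dir):
    """Sparse bedGraph-style BigWig with zoom levels, two chromosomes."""
    spec = SyntheticTrackSpec(
        seed=42, chrom_sizes={"chr1": 100_000, "chr2": 50_000},
        model="random_intervals", n_intervals=400, zoom=True)
    return make_signal_track(spec, str(fixture_dir / "signal.bw"))


@pytest.fixture(scope="session")
def tiled_track(fixture_dir):
    """Fully covered fixed-step BigWig (every base has a value)."""
    spec = SyntheticTrackSpec(
        seed=7, chrom_sizes={"chr1": 100_000},
        model="tiled_fixed_step", step=100, zoom=True)
    return make_signal_track(spec, str(fixture_dir / "tiled.bw"))


@pytest.fixture(scope="session")
def region_track(fixture_dir):
    """Peaks-model BigBed with name and score columns."""
    spec = SyntheticTrackSpec(
        seed=9, chrom_sizes={"chr1": 100_000}, model="peaks",
        n_peaks=30)
    return make_region_track(spec, str(fixture_dir / "regions.bb"))


@pytest.fixture(scope="session")
def tabular_track(fixture_dir):
    """BGZF + Tabix bedGraph-like table, 0-based convention."""
    spec = SyntheticTrackSpec(
        seed=5, chrom_sizes={"chr1": 80_000, "chr2": 40_000},
        n_intervals=500)
    return make_tabular_track(spec, str(fixture_dir / "table.bed.gz"))


@pytest.fixture(scope="session")
def many_block_track(fixture_dir):
    """BigWig with several hundred data blocks for minimal-fetch tests."""
    spec = SyntheticTrackSpec(
        seed=13, chrom_sizes={"chr1": 400_000},
        model="tiled_fixed_step", step=50, zoom=True,
        items_per_slot=16, rtree_block_size=8)
    return make_signal_track(spec, str(fixture_dir / "manyblocks.bw"))


def brute_force_overlap(truth: pd.DataFrame, rng: GenomicRange
                        ) -> pd.DataFrame:
    """Full-scan overlap filter of a ground-truth frame (the oracle)."""
    mask = ((truth["chrom"] == rng.chrom) & (truth["start"] < rng.end)
            & (truth["end"] > rng.start))
    return truth.loc[mask].reset_index(drop=True)


def frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    """Exact equality of interval frames (float32 values bit-equal)."""
    if len(a) != len(b) or list(a.columns) != list(b.columns):
        return False
    for col in a.columns:
        av, bv = a[col].to_numpy(), b[col].to_numpy()
        if av.dtype.kind == "f" or bv.dtype.kind == "f":
            af = av.astype(np.float32)
            bf = bv.astype(np.float32)
            both_nan = np.isnan(af) & np.isnan(bf)
            if not np.all((af == bf) | both_nan):
                return False
        elif not np.array_equal(av, bv):
            return False
    return True
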