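"""Plain-text readers and writers for the pipeline's tabular formats.

Matrices travel as TSV with features in rows and a header of sample ids;
intervals as BED; bin-count tracks as TSV (chrom, start, end, ip, input).
"""
from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from .chip_enrichment import BinTrack
from .types import FeatureMatrix, SampleSeries


def write_matrix(matrix: FeatureMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.6g")


def read_matrix(path, value_kind: str,
                intervals: pd.DataFrame | None = None) -> FeatureMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureMatrix(values=values, value_kind=value_kind,
                         intervals=intervals)


def write_series(series: SampleSeries, path) -> None:
    series.to_frame().to_csv(path, sep="\t", index=False)


def read_series(path) -> SampleSeries:
    return SampleSeries.from_frame(pd.read_csv(path, sep="\t"))


def write_intervals_bed(intervals: pd.DataFrame, path,
                        name_from_index: bool = True) -> None:
    """Write a BED6 file from an interval frame (chrom, start, end[, strand])."""
    out = pd.DataFrame(
        {
            "chrom": intervals["chrom"],
            "start": intervals["start"],
            "end": intervals["end"],
            "name": intervals.index if name_from_index
            else intervals.get("name", "."),
            "score": 0,
            "strand": intervals.get("strand", "."),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_sites_bed(sites: pd.DataFrame, path) -> None:
    """Binding sites as BED with the TF name in the name column."""
    out = sites[["chrom", "start", "end", "tf"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_sites_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "tf"])
    return df


def write_track(track: BinTrack, path) -> None:
    track.bins.to_csv(path, sep="\t", index=False)


def read_track(path, condition: str, replicate: str) -> BinTrack:
    bins = pd.read_csv(path, sep="\t")
    return BinTrack(condition=condition, replicate=replicate, bins=bins)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def line_count(path) -> int:
    with open(path) as fh:
        return sum(1 for _ in fh)
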