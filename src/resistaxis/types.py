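"""Shared data containers for the resistance-series analyses.

All genomic coordinates are 0-based, half-open (BED convention). A gene's
transcription start site (TSS) is a single 0-based position; for minus-strand
genes it is the last base of the gene body interval.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALUE_KINDS = frozenset({"log2_expression", "methylation_fraction", "vaf"})
#: kinds whose values must lie in the unit interval
_BOUNDED_KINDS = frozenset({"methylation_fraction", "vaf"})


@dataclass
class SampleSeries:
    """Ordered cell-line series with a resistance covariate.

    Parameters
    ----------
    sample_ids:
        Sample names ordered from least to most resistant
        (e.g. Parental, R100, R500, R1000, R4000).
    resistance_rank:
        Integer ranks 0..n-1; a permutation aligned with ``sample_ids``.
    ec50:
        Half-maximal effective drug concentration per sample, in nM;
        must increase strictly with rank.
    """

    sample_ids: list[str]
    resistance_rank: np.ndarray
    ec50: np.ndarray

    def __post_init__(self) -> None:
        self.resistance_rank = np.asarray(self.resistance_rank, dtype=int)
        self.ec50 = np.asarray(self.ec50, dtype=float)
        n = len(self.sample_ids)
        if len(self.resistance_rank) != n or len(self.ec50) != n:
            raise ValueError("sample_ids, resistance_rank and ec50 must align")
        if sorted(self.resistance_rank) != list(range(n)):
            raise ValueError("resistance_rank must be a permutation of 0..n-1")
        order = np.argsort(self.resistance_rank)
        if np.any(np.diff(self.ec50[order]) <= 0):
            raise ValueError("ec50 must strictly increase with resistance rank")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def covariate(self, which: str = "rank") -> np.ndarray:
        """Return the resistance covariate (``rank`` or ``ec50``)."""
        if which == "rank":
            return self.resistance_rank.astype(float)
        if which == "ec50":
            return self.ec50
        raise ValueError(f"unknown covariate {which!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "resistance_rank": self.resistance_rank,
                "ec50_nM": self.ec50,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleSeries":
        return cls(
            sample_ids=list(df["sample_id"]),
            resistance_rank=df["resistance_rank"].to_numpy(),
            ec50=df["ec50_nM"].to_numpy(),
        )


@dataclass
class FeatureMatrix:
    """Features x samples numeric matrix with optional genomic intervals.

    ``values`` rows are features, columns are sample ids in series order.
    ``intervals``, when present, is indexed by feature id with columns
    chrom, start, end, strand. NaN cells mark missing measurements
    (e.g. zero-depth VAF cells).
    """

    values: pd.DataFrame
    value_kind: str
    intervals: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {sorted(VALUE_KINDS)}")
        if self.value_kind in _BOUNDED_KINDS:
            vals = self.values.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError(f"{self.value_kind} values must lie in [0, 1]")
        if self.intervals is not None:
            missing = self.values.index.difference(self.intervals.index)
            if len(missing):
                raise ValueError(f"{len(missing)} features lack intervals")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def aligned_to(self, series: SampleSeries) -> "FeatureMatrix":
        """Reorder columns to match a sample series, erroring on absences."""
        missing = [s for s in series.sample_ids if s not in self.values.columns]
        if missing:
            raise ValueError(f"matrix lacks sample columns {missing}")
        return FeatureMatrix(
            self.values[series.sample_ids], self.value_kind, self.intervals
        )


@dataclass
class GeneAnnotation:
    """Gene models: body interval, strand and TSS per gene.

    ``frame`` is indexed by gene id with columns chrom, start, end, strand,
    tss. The TSS must fall inside (or at the edge of) the gene body.
    """

    frame: pd.DataFrame

    REQUIRED = ("chrom", "start", "end", "strand", "tss")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"annotation missing column {col!r}")
        df = self.frame
        if not set(df["strand"]).issubset({"+", "-"}):
            raise ValueError("strand must be '+' or '-'")
        bad = (df["tss"] < df["start"]) | (df["tss"] > df["end"] - 1)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} genes have TSS outside the gene body"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    def __len__(self) -> int:
        return len(self.frame)

    def promoter_windows(self, window: int = 5000) -> pd.DataFrame:
        """Strand-aware upstream promoter windows, half-open.

        For a plus-strand gene the promoter is [tss-window, tss); for a
        minus-strand gene it is [tss+1, tss+1+window). Windows running past
        the chromosome start are clipped with a warning.
        """
        df = self.frame
        plus = df["strand"] == "+"
        start = np.where(plus, df["tss"] - window, df["tss"] + 1)
        end = np.where(plus, df["tss"], df["tss"] + 1 + window)
        clipped = start < 0
        if clipped.any():
            warnings.warn(
                f"{int(clipped.sum())} promoter windows clipped at chromosome start",
                stacklevel=2,
            )
            start = np.maximum(start, 0)
        return pd.DataFrame(
            {"chrom": df["chrom"], "start": start, "end": end},
            index=df.index,
        )

    @classmethod
    def from_bed(cls, path) -> "GeneAnnotation":
        """Read a BED6+1 annotation (name=gene id, extra column = TSS)."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "gene_id", "score", "strand", "tss"],
        )
        return cls(df.set_index("gene_id")[list(cls.REQUIRED)])

    def to_bed(self, path) -> None:
        df = self.frame
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "gene_id": df.index,
                "score": 0,
                "strand": df["strand"],
                "tss": df["tss"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)
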