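"""Strandable genomic interval sets with per-region attributes.

A :class:`RegionSet` is a thin wrapper over a pandas frame with at least
``chrom``, ``start``, ``end`` columns (0-based half-open), an optional
``strand`` column in {``+``, ``-``, ``.``}, and arbitrary further attribute
columns (expression, class labels, occupancy, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinnedGenome

__all__ = ["RegionSet"]

_CORE = ["chrom", "start", "end"]


@dataclass
class RegionSet:
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CORE if c not in self.df.columns]
        if missing:
            raise ValueError(f"RegionSet frame missing columns {missing}")
        df = self.df.reset_index(drop=True).copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]]
            raise ValueError(f"{len(bad)} region(s) with start >= end")
        self.df = df

    # -- construction ----------------------------------------------------

    @classmethod
    def from_arrays(cls, chrom, start, end, strand=None, **attrs) -> "RegionSet":
        data = {"chrom": chrom, "start": start, "end": end}
        if strand is not None:
            data["strand"] = strand
        data.update(attrs)
        return cls(pd.DataFrame(data))

    # -- basics ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def stranded(self) -> bool:
        return "strand" in self.df.columns and self.df["strand"].isin(["+", "-"]).all()

    def sort(self) -> "RegionSet":
        return RegionSet(self.df.sort_values(["chrom", "start", "end"], kind="stable"))

    def subset(self, mask) -> "RegionSet":
        return RegionSet(self.df[np.asarray(mask)])

    def validate(self, genome: BinnedGenome) -> "RegionSet":
        """Check all intervals lie within their chromosome."""
        for chrom, grp in self.df.groupby("chrom", sort=False):
            length = genome.length(str(chrom))
            if (grp["end"] > length).any() or (grp["start"] < 0).any():
                raise ValueError(f"region outside chromosome {chrom} (length {length})")
        return self

    # -- anchors ---------------------------------------------------------

    def midpoints(self) -> np.ndarray:
        return ((self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2).astype(np.int64)

    def tss(self) -> np.ndarray:
        """Transcription start site per region: 5' end on the region's strand.

        Unstranded regions fall back to their midpoint with a warning.
        """
        if "strand" not in self.df.columns:
            warnings.warn("unstranded regions: using midpoints as anchors")
            return self.midpoints()
        strand = self.df["strand"].to_numpy()
        pos = np.where(strand == "-", self.df["end"].to_numpy() - 1, self.df["start"].to_numpy())
        unk = ~np.isin(strand, ["+", "-"])
        if unk.any():
            warnings.warn(f"{int(unk.sum())} unstranded region(s): using midpoints")
            pos = np.where(unk, self.midpoints(), pos)
        return pos.astype(np.int64)

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def with_attr(self, name: str, values) -> "RegionSet":
        df = self.df.copy()
        df[name] = values
        return RegionSet(df)
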