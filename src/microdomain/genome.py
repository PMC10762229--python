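"""Genome coordinate lattice shared by all matrices and tracks.

A :class:`BinnedGenome` fixes chromosome names/lengths and a bin size, and
every contact matrix, signal track, and region set in this package is
expressed on that lattice. Bins are 0-based, half-open, tile each chromosome
exactly, and the last bin of a chromosome may be shorter than ``bin_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BinnedGenome"]


@dataclass(frozen=True)
class BinnedGenome:
    """Chromosome names/lengths plus a fixed bin size.

    Parameters
    ----------
    chrom_names
        Ordered chromosome identifiers.
    chrom_lengths
        Chromosome lengths in base pairs, aligned with ``chrom_names``.
    bin_size
        Bin width in base pairs.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int
    # cumulative bin index of each chromosome's first bin, plus total
    bin_offsets: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", tuple(int(l) for l in self.chrom_lengths))
        nb = np.cumsum([0] + [self.n_bins(c) for c in self.chrom_names])
        object.__setattr__(self, "bin_offsets", tuple(int(x) for x in nb))

    @classmethod
    def from_dict(cls, chromsizes: dict[str, int], bin_size: int) -> "BinnedGenome":
        return cls(tuple(chromsizes), tuple(chromsizes.values()), bin_size)

    # -- lookups ---------------------------------------------------------

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_index(chrom)]

    def n_bins(self, chrom: str) -> int:
        """Number of bins on ``chrom`` (ceil(length / bin_size))."""
        return -(-self.length(chrom) // self.bin_size)

    @property
    def n_bins_total(self) -> int:
        return self.bin_offsets[-1]

    def bin_index(self, chrom: str, pos: int) -> int:
        """Chromosome-local bin index of base-pair position ``pos``."""
        if not 0 <= pos < self.length(chrom):
            raise ValueError(f"position {pos} outside {chrom} (length {self.length(chrom)})")
        return pos // self.bin_size

    def bins_table(self) -> pd.DataFrame:
        """All bin intervals as a (chrom, start, end) frame."""
        rows = []
        for chrom, length in zip(self.chrom_names, self.chrom_lengths):
            starts = np.arange(0, length, self.bin_size)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def with_bin_size(self, bin_size: int) -> "BinnedGenome":
        return BinnedGenome(self.chrom_names, self.chrom_lengths, bin_size)
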