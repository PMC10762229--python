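"""Per-bin scalar signal tracks (insulation scores, ChIP coverage, ...)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinnedGenome

__all__ = ["SignalTrack"]


@dataclass
class SignalTrack:
    """One scalar value per genome bin, NaN where undefined.

    ``meta`` carries free-form provenance (e.g. the insulation window).
    """

    genome: BinnedGenome
    values: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.genome.chrom_names:
            if chrom not in self.values:
                raise ValueError(f"track missing chromosome {chrom}")
            v = np.asarray(self.values[chrom], dtype=float)
            if v.shape != (self.genome.n_bins(chrom),):
                raise ValueError(
                    f"track on {chrom} has {v.shape[0]} bins, expected {self.genome.n_bins(chrom)}"
                )
            self.values[chrom] = v

    @classmethod
    def zeros(cls, genome: BinnedGenome, **meta) -> "SignalTrack":
        return cls(genome, {c: np.zeros(genome.n_bins(c)) for c in genome.chrom_names}, meta)

    @classmethod
    def from_flat(cls, genome: BinnedGenome, flat: np.ndarray, **meta) -> "SignalTrack":
        flat = np.asarray(flat, dtype=float)
        vals = {}
        for i, chrom in enumerate(genome.chrom_names):
            vals[chrom] = flat[genome.bin_offsets[i] : genome.bin_offsets[i + 1]]
        return cls(genome, vals, meta)

    def flat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.genome.chrom_names])

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.values[chrom]

    def to_frame(self) -> pd.DataFrame:
        """bedGraph-style (chrom, start, end, value) frame, one row per bin."""
        out = self.genome.bins_table()
        out["value"] = self.flat()
        return out
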