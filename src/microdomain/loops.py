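"""Looping potential of a ChIP-seq factor from its peak-pair pileup.

All intra-chromosomal peak pairs within a separation window (50 kb by
default, matching the short range of plant enhancer-promoter loops) are
enumerated; the O/E windows centered on each pair pixel are averaged and
normalized to a separation-preserving shifted background. A factor whose
peaks loop shows a central enrichment decaying toward the window edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact import ContactMatrix, oe_matrix
from .pileups import PileupResult, _nanmean_stack, _window
from .regions import RegionSet

__all__ = ["PeakPairSet", "enumerate_peak_pairs", "pair_pileup", "central_enrichment"]


@dataclass
class PeakPairSet:
    """Intra-chromosomal peak-position pairs with their separations."""

    pairs: pd.DataFrame  # chrom, pos_a, pos_b (pos_a < pos_b), separation
    min_sep: int
    max_sep: int
    source_factor: str = ""

    def __len__(self) -> int:
        return len(self.pairs)


def _anchor_points(peaks: RegionSet) -> np.ndarray:
    if "summit" in peaks.df.columns:
        return peaks.df["summit"].to_numpy(np.int64)
    return peaks.midpoints()


def enumerate_peak_pairs(
    peaks: RegionSet,
    max_sep: int = 50_000,
    min_sep: int = 8_000,
    source_factor: str = "",
) -> PeakPairSet:
    """All unordered same-chromosome peak pairs with separation in bounds.

    Peaks anchor at their narrowPeak summit when present, else midpoint.
    The default lower bound keeps pair windows off the diagonal (twice the
    default pileup half-window).
    """
    if min_sep >= max_sep:
        raise ValueError(f"min_sep {min_sep} must be < max_sep {max_sep}")
    pts = _anchor_points(peaks)
    chroms = peaks.df["chrom"].to_numpy(str)
    rows = []
    for chrom in pd.unique(chroms):
        p = np.sort(pts[chroms == chrom])
        # two-pointer sweep over the sorted positions
        hi_idx = np.searchsorted(p, p + max_sep, side="right")
        lo_idx = np.searchsorted(p, p + min_sep, side="left")
        for i in range(p.size):
            for j in range(lo_idx[i], hi_idx[i]):
                if j <= i:
                    continue
                rows.append((chrom, int(p[i]), int(p[j])))
    df = pd.DataFrame(rows, columns=["chrom", "pos_a", "pos_b"])
    if len(df):
        df["separation"] = df["pos_b"] - df["pos_a"]
        df = df[(df["separation"] >= min_sep) & (df["separation"] <= max_sep)]
        df = df.sort_values(["chrom", "pos_a", "pos_b"]).reset_index(drop=True)
    else:
        df["separation"] = pd.Series([], dtype=np.int64)
    return PeakPairSet(pairs=df, min_sep=min_sep, max_sep=max_sep, source_factor=source_factor)


def pair_pileup(
    m: ContactMatrix,
    pairs: PeakPairSet,
    half_window: int = 4_000,
    n_shuffle: int = 10,
    seed: int = 0,
    max_shift: int = 100_000,
) -> PileupResult:
    """Average O/E windows centered on each pair pixel.

    The window is ``2 * half_window`` on a side (8 kb -> 41 x 41 pixels at
    200 bp). Pixels falling below the main diagonal are NaN-clipped.
    Background windows shift both anchors of a pair by one shared random
    offset (separation preserved), ``n_shuffle`` draws per pair.
    """
    if len(pairs) == 0:
        raise ValueError("empty pair set")
    bs = m.genome.bin_size
    if half_window % bs != 0:
        raise ValueError(f"half_window {half_window} not a multiple of bin_size {bs}")
    half = half_window // bs
    size = 2 * half + 1
    oe = oe_matrix(m)
    rng = np.random.default_rng(seed)
    fg = (np.zeros((size, size)), np.zeros((size, size)))
    bg = (np.zeros((size, size)), np.zeros((size, size)))
    shift_bins = max(max_shift // bs, 2 * half + 1)
    for chrom, grp in pairs.pairs.groupby("chrom", sort=False):
        chrom = str(chrom)
        S = oe.sym(chrom)
        n = m.genome.n_bins(chrom)
        mask = m.mask[chrom]

        def _clipped(bi, bj):
            win = _window(S, n, mask, bi, bj, half)
            # absolute (row, col) = (bi - half + r, bj - half + c); clip row > col
            below = (bi - half + np.arange(size))[:, None] > (bj - half + np.arange(size))[None, :]
            win[below] = np.nan
            return win

        for _, row in grp.iterrows():
            bi, bj = int(row["pos_a"]) // bs, int(row["pos_b"]) // bs
            win = _clipped(bi, bj)
            good = np.isfinite(win)
            fg[0][good] += win[good]
            fg[1][good] += 1
            sep = bj - bi
            lo = max(half, 0)
            hi = n - half - sep
            if hi <= lo:
                continue
            for _ in range(n_shuffle):
                off = int(rng.integers(-shift_bins, shift_bins + 1))
                sb = bi + off
                if sb < lo or sb >= hi:
                    sb = int(rng.integers(lo, hi))
                win = _clipped(sb, sb + sep)
                good = np.isfinite(win)
                bg[0][good] += win[good]
                bg[1][good] += 1
    return PileupResult.from_grids(_nanmean_stack(*fg), _nanmean_stack(*bg), len(pairs))


def central_enrichment(p, center_px: int = 3, corner_px: int = 6) -> float:
    """Mean of the central block over the mean of the four corner blocks.

    ``p`` is a PileupResult (its enrichment grid is scored) or a grid.
    """
    grid = p.enrichment if isinstance(p, PileupResult) else np.asarray(p, float)
    size = grid.shape[0]
    if size % 2 == 0:
        raise ValueError("grid size must be odd")
    if size < center_px + 2 * corner_px:
        raise ValueError("grid too small for the requested center/corner blocks")
    c = size // 2
    h = center_px // 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        center = np.nanmean(grid[c - h : c + h + 1, c - h : c + h + 1])
        corners = [
            grid[:corner_px, :corner_px],
            grid[:corner_px, -corner_px:],
            grid[-corner_px:, :corner_px],
            grid[-corner_px:, -corner_px:],
        ]
        corner = np.nanmean(np.concatenate([x.ravel() for x in corners]))
    if not np.isfinite(corner) or corner == 0:
        return float("nan")
    return float(center / corner)
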