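"""Independent brute-force oracles used to pin the sparse-path results.

Everything here is written directly from the definitions (dense arrays,
explicit loops) and never calls the code paths it checks.
"""

from __future__ import annotations

import numpy as np


def dense_expected(dense: np.ndarray) -> np.ndarray:
    """Per-diagonal mean of a dense symmetric matrix."""
    n = dense.shape[0]
    return np.array([np.diagonal(dense, offset=d).mean() for d in range(n)])


def dense_oe(dense: np.ndarray) -> np.ndarray:
    n = dense.shape[0]
    exp = dense_expected(dense)
    out = np.zeros_like(dense, dtype=float)
    for i in range(n):
        for j in range(n):
            e = exp[abs(i - j)]
            out[i, j] = dense[i, j] / e if e > 0 else np.nan
    return out


def dense_insulation(dense: np.ndarray, k: int) -> np.ndarray:
    """Diamond-mean insulation score by direct summation."""
    n = dense.shape[0]
    raw = np.full(n, np.nan)
    for i in range(k, n - k):
        raw[i] = dense[i - k : i, i + 1 : i + k + 1].mean()
    score = np.full(n, np.nan)
    mean_raw = np.nanmean(raw)
    ok = np.isfinite(raw)
    score[ok] = np.log2(raw[ok] / mean_raw)
    return score


def brute_prominences(score: np.ndarray):
    """Topographic prominence of every strict local minimum.

    Walk outward from each minimum until a strictly lower sample (or the
    track end) is met; the barrier on each side is the maximum in that
    window and the prominence is min(left, right barrier) - value.
    """
    n = score.size
    minima = []
    i = 1
    while i < n - 1:
        v = score[i]
        if not np.isfinite(v):
            i += 1
            continue
        j = i
        while j + 1 < n and score[j + 1] == v:
            j += 1
        if j + 1 < n and np.isfinite(score[i - 1]) and score[i - 1] > v and np.isfinite(score[j + 1]) and score[j + 1] > v:
            minima.append((i + j) // 2)
        i = j + 1
    proms = []
    for mpos in minima:
        v = score[mpos]
        left_max = -np.inf
        j = mpos - 1
        while j >= 0 and np.isfinite(score[j]) and score[j] >= v:
            left_max = max(left_max, score[j])
            j -= 1
        right_max = -np.inf
        j = mpos + 1
        while j < n and np.isfinite(score[j]) and score[j] >= v:
            right_max = max(right_max, score[j])
            j += 1
        proms.append(min(left_max, right_max) - v)
    return np.array(minima, dtype=int), np.array(proms)


def dense_centered_pileup(dense_oe_mat: np.ndarray, centers, half: int) -> np.ndarray:
    """NaN-mean of OE windows centered on diagonal pixels."""
    n = dense_oe_mat.shape[0]
    size = 2 * half + 1
    stack = []
    for c in centers:
        win = np.full((size, size), np.nan)
        rlo, rhi = max(c - half, 0), min(c + half + 1, n)
        win[rlo - (c - half) : rhi - (c - half), rlo - (c - half) : rhi - (c - half)] = dense_oe_mat[
            rlo:rhi, rlo:rhi
        ]
        stack.append(win)
    return np.nanmean(np.stack(stack), axis=0)


def dense_rescaled_block(block: np.ndarray, out_size: int) -> np.ndarray:
    """Block-average resize; partition follows bin-midpoint assignment."""
    n = block.shape[0]
    edges = np.linspace(0, n, out_size + 1)
    idx = np.clip(np.searchsorted(edges, np.arange(n) + 0.5) - 1, 0, out_size - 1)
    out = np.full((out_size, out_size), np.nan)
    for u in range(out_size):
        for v in range(out_size):
            sub = block[np.ix_(idx == u, idx == v)]
            if np.isfinite(sub).any():
                out[u, v] = np.nanmean(sub)
    return out


def dense_pair_window(dense_oe_mat: np.ndarray, bi: int, bj: int, half: int) -> np.ndarray:
    """OE window at an off-diagonal pixel, NaN below the diagonal."""
    n = dense_oe_mat.shape[0]
    size = 2 * half + 1
    win = np.full((size, size), np.nan)
    for r in range(size):
        for c in range(size):
            i, j = bi - half + r, bj - half + c
            if 0 <= i < n and 0 <= j < n and i <= j:
                win[r, c] = dense_oe_mat[i, j]
    return win


def dense_gene_z(dense_balanced: np.ndarray, b0: int, b1: int) -> float:
    """Mean per-diagonal z over the gene-body upper triangle."""
    n = dense_balanced.shape[0]
    zs = []
    for d in range(1, b1 - b0):
        diag = np.diagonal(dense_balanced, offset=d)
        mu, sd = diag.mean(), diag.std()
        if sd == 0:
            continue
        vals = np.array([dense_balanced[i, i + d] for i in range(b0, b1 - d)])
        zs.extend((vals - mu) / sd)
    return float(np.mean(zs))


def quadratic_overlap(a_df, b_df) -> int:
    """O(|a|*|b|) overlap count."""
    n = 0
    for _, ra in a_df.iterrows():
        for _, rb in b_df.iterrows():
            if ra["chrom"] == rb["chrom"] and ra["start"] < rb["end"] and rb["start"] < ra["end"]:
                n += 1
                break
    return n


def per_base_track_mean(intervals, length: int, bin_size: int) -> np.ndarray:
    """Expand a signal to per-base resolution, then average per bin."""
    base = np.zeros(length)
    for _, row in intervals.iterrows():
        base[max(0, row["start"]) : min(length, row["end"])] = row["value"]
    n_bins = -(-length // bin_size)
    out = np.empty(n_bins)
    for b in range(n_bins):
        out[b] = base[b * bin_size : min((b + 1) * bin_size, length)].mean()
    return out
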