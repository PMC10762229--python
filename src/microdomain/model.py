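"""Linking 1D chromatin tracks to 3D features.

Covers per-bin weighted-mean quantification of bedGraph-style signal, the
boundary-strength generalized linear model (Gaussian identity link over
standardized track predictors), selection of Pol-II-perturbed genes, the
gene-body contact z-score, and the occupancy-vs-contact fold-change
regression used to quantify how transcription loss loosens gene domains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .contact import ContactMatrix
from .genome import BinnedGenome
from .regions import RegionSet
from .tracks import SignalTrack

__all__ = [
    "track_weighted_mean",
    "DesignMatrix",
    "ModelFit",
    "fit_boundary_glm",
    "select_perturbed_genes",
    "gene_contact_zscore",
    "gene_contact_scores",
    "perturbation_regression",
]


def _resolve_last_writer(s: np.ndarray, e: np.ndarray, v: np.ndarray):
    """Flatten overlapping intervals: the record latest in file order owns
    each base. Returns disjoint (start, end, value) arrays."""
    edges = np.unique(np.concatenate([s, e]))
    seg_s, seg_e = edges[:-1], edges[1:]
    out_s, out_e, out_v = [], [], []
    for a, b in zip(seg_s, seg_e):
        covering = np.flatnonzero((s <= a) & (e >= b))
        if covering.size:
            out_s.append(a)
            out_e.append(b)
            out_v.append(v[covering[-1]])
    return np.array(out_s, np.int64), np.array(out_e, np.int64), np.array(out_v)


def track_weighted_mean(
    intervals: pd.DataFrame, genome: BinnedGenome, skip_uncovered: bool = False
) -> SignalTrack:
    """Overlap-weighted mean signal per genome bin.

    ``intervals`` is a bedGraph-style (chrom, start, end, value) frame.
    Uncovered bases contribute value 0 with their length (coverage
    semantics) unless ``skip_uncovered``, in which case the mean is over
    covered bases only (NaN where nothing covers the bin). Intervals
    extending past the chromosome end are clipped with a warning.
    """
    bs = genome.bin_size
    sums = {c: np.zeros(genome.n_bins(c)) for c in genome.chrom_names}
    cov = {c: np.zeros(genome.n_bins(c)) for c in genome.chrom_names}
    clipped = 0
    for chrom, grp in intervals.groupby("chrom", sort=False):
        chrom = str(chrom)
        L = genome.length(chrom)
        s = np.clip(grp["start"].to_numpy(np.int64), 0, L)
        e = np.clip(grp["end"].to_numpy(np.int64), 0, L)
        clipped += int(((grp["start"] < 0) | (grp["end"] > L)).sum())
        v = grp["value"].to_numpy(float)
        order = np.argsort(s, kind="stable")
        if s.size > 1 and (e[order][:-1] > s[order][1:]).any():
            warnings.warn(f"overlapping intervals on {chrom}: last record wins per base")
            s, e, v = _resolve_last_writer(s, e, v)
        keep = e > s
        s, e, v = s[keep], e[keep], v[keep]
        for si, ei, vi in zip(s, e, v):
            b0, b1 = si // bs, (ei - 1) // bs
            if b0 == b1:
                sums[chrom][b0] += vi * (ei - si)
                cov[chrom][b0] += ei - si
                continue
            left = (b0 + 1) * bs - si
            sums[chrom][b0] += vi * left
            cov[chrom][b0] += left
            right = ei - b1 * bs
            sums[chrom][b1] += vi * right
            cov[chrom][b1] += right
            if b1 > b0 + 1:
                sums[chrom][b0 + 1 : b1] += vi * bs
                cov[chrom][b0 + 1 : b1] += bs
    if clipped:
        warnings.warn(f"clipped {clipped} interval(s) at chromosome ends")
    vals = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        starts = np.arange(n) * bs
        widths = np.minimum(starts + bs, genome.length(chrom)) - starts
        if skip_uncovered:
            with np.errstate(invalid="ignore", divide="ignore"):
                vals[chrom] = np.where(cov[chrom] > 0, sums[chrom] / cov[chrom], np.nan)
        else:
            vals[chrom] = sums[chrom] / widths
    return SignalTrack(genome, vals, {"kind": "weighted_mean"})


# -- GLM -------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Response plus standardized named predictors for the boundary GLM."""

    response: np.ndarray
    predictors: np.ndarray  # (n, p), each column mean 0 / SD 1
    names: list[str]
    means: np.ndarray
    sds: np.ndarray

    @property
    def n(self) -> int:
        return self.response.size

    @classmethod
    def build(cls, response: np.ndarray, predictors: dict[str, np.ndarray]) -> "DesignMatrix":
        """Standardize predictors; constant columns are dropped with a warning.

        Rows with any non-finite value are removed.
        """
        y = np.asarray(response, float)
        names = list(predictors)
        X = np.column_stack([np.asarray(predictors[k], float) for k in names])
        ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        y, X = y[ok], X[ok]
        sds = X.std(axis=0)
        const = sds == 0
        if const.any():
            dropped = [n for n, c in zip(names, const) if c]
            warnings.warn(f"dropping constant predictor(s): {dropped}")
            X = X[:, ~const]
            names = [n for n, c in zip(names, const) if not c]
            sds = sds[~const]
        means = X.mean(axis=0)
        Xs = (X - means) / sds
        return cls(response=y, predictors=Xs, names=names, means=means, sds=sds)


@dataclass
class ModelFit:
    """Coefficient table and diagnostics of a Gaussian identity-link GLM."""

    coefficients: pd.DataFrame  # name, estimate, se, sign, p
    intercept: float
    r_squared: float
    deviance: float
    n: int
    family: str = "gaussian"
    link: str = "identity"
    meta: dict = field(default_factory=dict)

    def ranked(self) -> pd.DataFrame:
        return self.coefficients.reindex(
            self.coefficients["estimate"].abs().sort_values(ascending=False).index
        )


def fit_boundary_glm(design: DesignMatrix) -> ModelFit:
    """Fit the boundary-strength GLM (Gaussian family, identity link).

    Predictors must already be standardized (see DesignMatrix.build), so
    coefficient magnitudes are comparable and rank predictive factors.
    """
    p = design.predictors.shape[1]
    if design.n <= 10 * p:
        raise ValueError(f"need n > 10 * predictors; got n={design.n}, p={p}")
    X = sm.add_constant(design.predictors)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(design.predictors, rowvar=False)
        np.fill_diagonal(corr, 0)
        worst = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            "rank-deficient design; most collinear columns: "
            f"{design.names[worst[0]]}, {design.names[worst[1]]}"
        )
    res = sm.GLM(design.response, X, family=sm.families.Gaussian()).fit()
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    coef = pd.DataFrame(
        {
            "name": design.names,
            "estimate": params[1:],
            "se": bse[1:],
            "sign": np.sign(params[1:]).astype(int),
            "p": pvals[1:],
        }
    )
    y = design.response
    r2 = 1.0 - res.deviance / float(((y - y.mean()) ** 2).sum())
    return ModelFit(
        coefficients=coef,
        intercept=float(params[0]),
        r_squared=float(r2),
        deviance=float(res.deviance),
        n=design.n,
    )


# -- perturbed-gene selection ----------------------------------------------


def _gene_body_means(genes: RegionSet, track: SignalTrack) -> np.ndarray:
    """Overlap-weighted mean track value across each gene body."""
    bs = track.genome.bin_size
    out = np.empty(len(genes))
    for k, row in enumerate(genes.df.itertuples(index=False)):
        v = track[str(row.chrom)]
        s, e = int(row.start), int(row.end)
        b0, b1 = s // bs, (e - 1) // bs
        bins = np.arange(b0, b1 + 1)
        w = np.minimum((bins + 1) * bs, e) - np.maximum(bins * bs, s)
        out[k] = float(np.sum(v[b0 : b1 + 1] * w) / w.sum())
    return out


def select_perturbed_genes(
    genes: RegionSet,
    occ_wt: SignalTrack,
    occ_mut: SignalTrack,
    len_range: tuple[int, int] = (2000, 3000),
    top_frac: float = 0.10,
    exclude: set | None = None,
) -> RegionSet:
    """Select genes whose Pol II occupancy drops in the perturbation.

    Keeps genes that (i) have length within ``len_range`` (medium-length
    genes, avoiding length confounds), (ii) rank in the top ``top_frac`` of
    ALL genes by WT gene-body occupancy, and (iii) show lower occupancy in
    the mutant than in WT. ``exclude`` removes named genes (e.g. a
    solvent-control-affected list). Returns an empty set with a warning
    when nothing qualifies.
    """
    wt = _gene_body_means(genes, occ_wt)
    mut = _gene_body_means(genes, occ_mut)
    lengths = genes.lengths()
    cutoff = np.quantile(wt, 1 - top_frac)
    keep = (lengths >= len_range[0]) & (lengths <= len_range[1]) & (wt >= cutoff) & (mut < wt)
    if exclude and "name" in genes.df.columns:
        keep &= ~genes.df["name"].isin(exclude).to_numpy()
    if not keep.any():
        warnings.warn("no gene passes the perturbation selection")
    out = genes.subset(keep)
    out.df["occ_wt"] = wt[keep]
    out.df["occ_mut"] = mut[keep]
    return out


# -- gene-body contact z-score ----------------------------------------------


def _diagonal_stats(m: ContactMatrix, chrom: str, max_offset: int):
    """Mean and SD of balanced values over unmasked pixels per offset."""
    coo = m.pixels[chrom]
    vals = m._values(chrom, balanced=not m.is_oe)
    off = coo.col - coo.row
    sel = off <= max_offset
    off, vals = off[sel], vals[sel]
    mask = m.mask[chrom]
    n = mask.size
    counts = np.array(
        [np.count_nonzero(mask[: n - d] & mask[d:]) if d else mask.sum() for d in range(max_offset + 1)],
        dtype=float,
    )
    s1 = np.bincount(off, weights=vals, minlength=max_offset + 1)[: max_offset + 1]
    s2 = np.bincount(off, weights=vals**2, minlength=max_offset + 1)[: max_offset + 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, s1 / counts, np.nan)
        var = np.where(counts > 1, s2 / counts - mean**2, np.nan)
    return mean, np.sqrt(np.maximum(var, 0))


def gene_contact_zscore(m: ContactMatrix, gene, _stats_cache: dict | None = None) -> float:
    """Mean per-offset z-score of gene-body contacts.

    Every pixel in the gene-body upper triangle (diagonal excluded) is
    z-scored against the chromosome-wide distribution of balanced values
    at the same offset; the gene score is the mean z. Scale-free: global
    rescaling of the matrix cancels in the z-scores.
    """
    if not m.balanced:
        raise ValueError("gene_contact_zscore requires a balanced matrix")
    chrom, start, end = str(gene[0]), int(gene[1]), int(gene[2])
    bs = m.genome.bin_size
    b0, b1 = start // bs, -(-end // bs)
    span = b1 - b0
    if span < 2:
        raise ValueError("gene must span at least 2 bins")
    if _stats_cache is not None and chrom in _stats_cache and _stats_cache[chrom][0].size >= span:
        mean, sd = _stats_cache[chrom]
    else:
        mean, sd = _diagonal_stats(m, chrom, span - 1)
        if _stats_cache is not None:
            _stats_cache[chrom] = (mean, sd)
    S = m.sym(chrom, balanced=not m.is_oe)
    block = S[b0:b1, b0:b1].toarray()
    zs = []
    for d in range(1, span):
        vals = np.diagonal(block, offset=d)
        if d < mean.size and np.isfinite(mean[d]) and sd[d] > 0:
            zs.append((vals - mean[d]) / sd[d])
    if not zs:
        return np.nan
    return float(np.concatenate(zs).mean())


def gene_contact_scores(
    m_wt: ContactMatrix,
    m_mut: ContactMatrix,
    genes: RegionSet,
    occ_wt: SignalTrack,
    occ_mut: SignalTrack,
) -> pd.DataFrame:
    """Per-gene occupancy and contact fold changes between conditions.

    log2 occupancy fold change uses a pseudocount equal to the 5th
    percentile of the genome-wide positive WT track values (so it stays
    small relative to the high-occupancy genes under study); contact fold
    change is the log2 ratio of gene-body z-scores and is defined only
    when both are positive.
    """
    wt_occ = _gene_body_means(genes, occ_wt)
    mut_occ = _gene_body_means(genes, occ_mut)
    flat = occ_wt.flat()
    pos = flat[flat > 0]
    pc = float(np.percentile(pos, 5)) if pos.size else 0.0
    # prefill per-chromosome diagonal stats to the largest gene span
    cache_wt: dict = {}
    cache_mut: dict = {}
    bs = m_wt.genome.bin_size
    for chrom, grp in genes.df.groupby("chrom", sort=False):
        max_span = int((-(-grp["end"] // bs) - grp["start"] // bs).max())
        cache_wt[str(chrom)] = _diagonal_stats(m_wt, str(chrom), max_span)
        cache_mut[str(chrom)] = _diagonal_stats(m_mut, str(chrom), max_span)
    rows = []
    for k, row in enumerate(genes.df.itertuples(index=False)):
        region = (row.chrom, row.start, row.end)
        z_wt = gene_contact_zscore(m_wt, region, cache_wt)
        z_mut = gene_contact_zscore(m_mut, region, cache_mut)
        l2occ = np.log2((mut_occ[k] + pc) / (wt_occ[k] + pc))
        l2c = np.log2(z_mut / z_wt) if (z_wt > 0 and z_mut > 0) else np.nan
        rows.append(
            {
                "gene": getattr(row, "name", str(k)),
                "length": row.end - row.start,
                "occupancy_wt": wt_occ[k],
                "occupancy_mut": mut_occ[k],
                "log2fc_occ": l2occ,
                "contact_wt": z_wt,
                "contact_mut": z_mut,
                "log2fc_contact": l2c,
            }
        )
    return pd.DataFrame(rows)


def perturbation_regression(scores: pd.DataFrame) -> dict:
    """OLS of contact log2 fold change on occupancy log2 fold change."""
    from scipy import stats

    ok = np.isfinite(scores["log2fc_occ"]) & np.isfinite(scores["log2fc_contact"])
    x = scores.loc[ok, "log2fc_occ"].to_numpy(float)
    y = scores.loc[ok, "log2fc_contact"].to_numpy(float)
    if x.size < 3:
        raise ValueError("need at least 3 genes with defined fold changes")
    if np.allclose(x.std(), 0):
        raise ValueError("zero variance in occupancy fold change")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p": float(res.pvalue),
        "n": int(x.size),
    }
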