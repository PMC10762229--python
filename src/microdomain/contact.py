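"""Contact-matrix data model and matrix-level operations.

A :class:`ContactMatrix` stores per-chromosome intra-chromosomal (cis)
contact counts as sparse upper-triangle matrices on a fixed
:class:`~microdomain.genome.BinnedGenome` lattice, together with optional
iterative-correction balancing weights and a per-bin validity mask.

Operations cover binning contact records, coarsening to larger bins,
ICE balancing, per-diagonal expected values and observed/expected
normalization, distance-decay fitting, binomial downsampling, and
log-ratio comparison of two maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .genome import BinnedGenome

__all__ = [
    "ContactMatrix",
    "DecayProfile",
    "bin_contacts",
    "cis_fraction",
    "coarsen",
    "balance_ice",
    "expected_profile",
    "observed_over_expected",
    "contact_decay",
    "downsample",
    "relative_difference",
]


@dataclass
class ContactMatrix:
    """Per-chromosome sparse symmetric binned contact counts.

    ``pixels[chrom]`` is a COO matrix holding each unordered pair once with
    ``row <= col``; symmetry is implicit. ``weights`` are per-bin balancing
    factors (NaN on masked bins); ``mask`` flags valid bins. ``n_inter``
    counts inter-chromosomal records that were seen but not stored.
    """

    genome: BinnedGenome
    pixels: dict[str, sparse.coo_matrix]
    weights: dict[str, np.ndarray] | None = None
    mask: dict[str, np.ndarray] | None = None
    n_inter: int = 0
    is_oe: bool = False
    balance_info: dict | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for chrom in self.genome.chrom_names:
            n = self.genome.n_bins(chrom)
            if chrom not in self.pixels:
                self.pixels[chrom] = sparse.coo_matrix((n, n))
            coo = sparse.coo_matrix(self.pixels[chrom])
            if coo.shape != (n, n):
                raise ValueError(f"pixel matrix on {chrom} has shape {coo.shape}, expected {(n, n)}")
            if np.any(coo.row > coo.col):
                raise ValueError("pixels must be upper-triangle (bin_i <= bin_j)")
            coo.sum_duplicates()
            self.pixels[chrom] = coo
        if self.mask is None:
            self.mask = {c: np.ones(self.genome.n_bins(c), bool) for c in self.genome.chrom_names}

    # -- basics ----------------------------------------------------------

    @property
    def bin_size(self) -> int:
        return self.genome.bin_size

    @property
    def balanced(self) -> bool:
        return self.weights is not None or self.is_oe

    @property
    def total_contacts(self) -> float:
        return float(sum(self.pixels[c].data.sum() for c in self.genome.chrom_names))

    def copy(self, **updates) -> "ContactMatrix":
        kw = dict(
            genome=self.genome,
            pixels={c: p.copy() for c, p in self.pixels.items()},
            weights=None if self.weights is None else {c: w.copy() for c, w in self.weights.items()},
            mask={c: m.copy() for c, m in self.mask.items()},
            n_inter=self.n_inter,
            is_oe=self.is_oe,
            balance_info=self.balance_info,
        )
        kw.update(updates)
        return ContactMatrix(**kw)

    # -- value access ----------------------------------------------------

    def _values(self, chrom: str, balanced: bool) -> np.ndarray:
        """Pixel values, balanced (w_i * c * w_j, masked -> 0) on request."""
        coo = self.pixels[chrom]
        if not balanced or self.is_oe:
            return coo.data
        if self.weights is None:
            raise ValueError("matrix is not balanced; run balance_ice first")
        w = np.nan_to_num(self.weights[chrom], nan=0.0)
        return coo.data * w[coo.row] * w[coo.col]

    def sym(self, chrom: str, balanced: bool = False) -> sparse.csr_matrix:
        """Symmetrized CSR view (diagonal stored once)."""
        key = ("sym", chrom, balanced)
        if key not in self._cache:
            coo = self.pixels[chrom]
            data = self._values(chrom, balanced)
            off = coo.row != coo.col
            row = np.concatenate([coo.row, coo.col[off]])
            col = np.concatenate([coo.col, coo.row[off]])
            dat = np.concatenate([data, data[off]])
            self._cache[key] = sparse.csr_matrix((dat, (row, col)), shape=coo.shape)
        return self._cache[key]

    def dense(self, chrom: str, balanced: bool = False) -> np.ndarray:
        """Dense symmetric array (small matrices / tests only)."""
        return self.sym(chrom, balanced=balanced).toarray()

    def band(self, chrom: str, max_offset: int, balanced: bool = True) -> np.ndarray:
        """Band view B[i, o] = value(i, i + o) for o in 0..max_offset.

        Entries beyond the chromosome end are NaN; entries touching masked
        bins are NaN.
        """
        n = self.genome.n_bins(chrom)
        coo = self.pixels[chrom]
        data = self._values(chrom, balanced)
        B = np.zeros((n, max_offset + 1))
        off = coo.col - coo.row
        sel = off <= max_offset
        B[coo.row[sel], off[sel]] = data[sel]
        m = self.mask[chrom]
        for o in range(max_offset + 1):
            if o > 0:
                B[n - o :, o] = np.nan
            valid = m[: n - o] & m[o:] if o > 0 else m
            B[: n - o if o else n, o][~valid] = np.nan
        return B


@dataclass
class DecayProfile:
    """Distance-dependent contact decay P(s) with a power-law fit.

    ``alpha_hat`` is the negative slope of the log-log least-squares line
    inside ``fit_range`` (so P(s) ~ s**-alpha_hat).
    """

    distances: np.ndarray
    mean_contact: np.ndarray
    alpha_hat: float
    fit_range: tuple[float, float]
    n_pixels: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"distance": self.distances, "mean_contact": self.mean_contact, "n_pixels": self.n_pixels}
        )


# -- binning -------------------------------------------------------------


def bin_contacts(pairs, genome: BinnedGenome, intra_only: bool = True) -> ContactMatrix:
    """Bin a stream of contact records onto the genome lattice.

    ``pairs`` is a (chrom1, pos1, chrom2, pos2) frame or an iterable of such
    frames. Records on unknown chromosomes or with out-of-range positions
    are rejected with a diagnostic; inter-chromosomal records are counted in
    ``n_inter`` and stored only if ``intra_only`` is False (storage of trans
    pixels is not supported — they are dropped from the matrix either way,
    this package analyses cis maps).
    """
    if isinstance(pairs, pd.DataFrame):
        pairs = [pairs]
    acc_i: dict[str, list] = {c: [] for c in genome.chrom_names}
    acc_j: dict[str, list] = {c: [] for c in genome.chrom_names}
    n_inter = 0
    n_rejected = 0
    lengths = dict(zip(genome.chrom_names, genome.chrom_lengths))
    for chunk in pairs:
        c1 = chunk["chrom1"].to_numpy(str)
        c2 = chunk["chrom2"].to_numpy(str)
        p1 = chunk["pos1"].to_numpy(np.int64)
        p2 = chunk["pos2"].to_numpy(np.int64)
        len1 = np.array([lengths.get(c, -1) for c in c1])
        len2 = np.array([lengths.get(c, -1) for c in c2])
        ok = (len1 > 0) & (len2 > 0) & (p1 >= 0) & (p2 >= 0) & (p1 < len1) & (p2 < len2)
        n_rejected += int((~ok).sum())
        inter = ok & (c1 != c2)
        n_inter += int(inter.sum())
        cis = ok & ~inter
        b1 = p1[cis] // genome.bin_size
        b2 = p2[cis] // genome.bin_size
        lo = np.minimum(b1, b2)
        hi = np.maximum(b1, b2)
        for chrom in np.unique(c1[cis]):
            sel = c1[cis] == chrom
            acc_i[chrom].append(lo[sel])
            acc_j[chrom].append(hi[sel])
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} contact record(s) outside the genome")
    pixels = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        if acc_i[chrom]:
            i = np.concatenate(acc_i[chrom])
            j = np.concatenate(acc_j[chrom])
            coo = sparse.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
            coo.sum_duplicates()
        else:
            coo = sparse.coo_matrix((n, n))
        pixels[chrom] = coo
    return ContactMatrix(genome, pixels, n_inter=n_inter)


def cis_fraction(pairs) -> float:
    """Fraction of records that are intra-chromosomal (library QC; good
    libraries exceed ~80%)."""
    if isinstance(pairs, pd.DataFrame):
        pairs = [pairs]
    n_cis = 0
    n_all = 0
    for chunk in pairs:
        n_all += len(chunk)
        n_cis += int((chunk["chrom1"].to_numpy(str) == chunk["chrom2"].to_numpy(str)).sum())
    if n_all == 0:
        raise ValueError("empty contact stream")
    return n_cis / n_all


# -- resolution ----------------------------------------------------------


def coarsen(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum factor x factor blocks into larger bins; totals are conserved.

    Balancing weights are invalidated (re-balance at the new resolution).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return m.copy(weights=None, balance_info=None)
    genome = m.genome.with_bin_size(m.genome.bin_size * factor)
    pixels = {}
    for chrom in genome.chrom_names:
        coo = m.pixels[chrom]
        n = genome.n_bins(chrom)
        i = coo.row // factor
        j = coo.col // factor
        out = sparse.coo_matrix((coo.data.copy(), (i, j)), shape=(n, n))
        out.sum_duplicates()
        pixels[chrom] = out
    return ContactMatrix(genome, pixels, n_inter=m.n_inter)


# -- balancing -----------------------------------------------------------


def balance_ice(
    m: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    min_coverage_frac: float = 0.02,
) -> ContactMatrix:
    """Iterative-correction balancing (equal weighted marginals).

    Bins whose raw marginal is below ``min_coverage_frac`` times the mean
    nonzero marginal are masked. Weights are scaled to mean 1 over unmasked
    bins. Non-convergence within ``max_iter`` is flagged in
    ``balance_info`` rather than raised.
    """
    out = m.copy()
    weights = {}
    info = {"converged": True, "n_iter": 0, "cv": {}}
    for chrom in m.genome.chrom_names:
        n = m.genome.n_bins(chrom)
        S = out.sym(chrom)
        marg = np.asarray(S.sum(axis=1)).ravel()
        mean_marg = marg[marg > 0].mean() if (marg > 0).any() else 0.0
        valid = out.mask[chrom] & (marg >= min_coverage_frac * mean_marg) & (marg > 0)
        if valid.sum() == 0:
            raise ValueError(f"all bins masked on {chrom}; cannot balance")
        if valid.sum() < 2:
            raise ValueError(f"fewer than 2 unmasked bins on {chrom} after coverage masking")
        w = np.where(valid, 1.0, 0.0)
        cv = np.inf
        it = 0
        for it in range(1, max_iter + 1):
            s = w * (S @ w)
            sv = s[valid]
            mean_s = sv.mean()
            cv = sv.std() / mean_s
            if cv < tol:
                break
            # square-root damped update: stable on banded/truncated maps
            adj = np.ones(n)
            adj[valid] = np.sqrt(sv / mean_s)
            w = w / adj
        converged = cv < tol
        if not converged:
            warnings.warn(f"balancing on {chrom} did not converge (CV={cv:.3g})")
        # rescale so weighted values keep the original scale: mean weight 1
        w[valid] /= w[valid].mean()
        wout = np.full(n, np.nan)
        wout[valid] = w[valid]
        weights[chrom] = wout
        out.mask[chrom] = valid
        info["converged"] = bool(info["converged"] and converged)
        info["n_iter"] = max(info["n_iter"], int(it))
        info["cv"][chrom] = float(cv)
    out.weights = weights
    out.balance_info = info
    out._cache.clear()
    return out


# -- expected / OE -------------------------------------------------------


def _valid_pair_counts(mask: np.ndarray) -> np.ndarray:
    """Number of unmasked (i, i+d) pairs for each offset d."""
    n = mask.size
    counts = np.empty(n, dtype=np.int64)
    counts[0] = mask.sum()
    for d in range(1, n):
        counts[d] = np.count_nonzero(mask[: n - d] & mask[d:])
    return counts


def expected_profile(m: ContactMatrix) -> dict[str, np.ndarray]:
    """Per-chromosome mean balanced value over unmasked pixels per diagonal.

    Offsets with zero unmasked pixel pairs are NaN (undefined, not 0).
    """
    if not m.balanced:
        raise ValueError("expected_profile requires a balanced matrix")
    out = {}
    for chrom in m.genome.chrom_names:
        n = m.genome.n_bins(chrom)
        coo = m.pixels[chrom]
        vals = m._values(chrom, balanced=True)
        off = coo.col - coo.row
        sums = np.bincount(off, weights=vals, minlength=n)
        counts = _valid_pair_counts(m.mask[chrom])
        with np.errstate(invalid="ignore", divide="ignore"):
            exp = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out[chrom] = exp
    return out


def observed_over_expected(m: ContactMatrix, expected: dict[str, np.ndarray] | None = None) -> ContactMatrix:
    """Divide each balanced pixel by the expected value at its offset.

    Pixels on diagonals with undefined expected are dropped. A uniform
    matrix maps to O/E = 1 everywhere.
    """
    if not m.balanced:
        raise ValueError("observed_over_expected requires a balanced matrix")
    if expected is None:
        expected = expected_profile(m)
    pixels = {}
    for chrom in m.genome.chrom_names:
        coo = m.pixels[chrom]
        vals = m._values(chrom, balanced=True)
        off = coo.col - coo.row
        exp = expected[chrom][off]
        if np.any((exp == 0) & (vals > 0)):
            raise ValueError(f"expected 0 with observed > 0 on {chrom}: inconsistent state")
        keep = np.isfinite(exp) & (exp > 0)
        pixels[chrom] = sparse.coo_matrix(
            (vals[keep] / exp[keep], (coo.row[keep], coo.col[keep])), shape=coo.shape
        )
    return ContactMatrix(
        m.genome, pixels, weights=None, mask={c: v.copy() for c, v in m.mask.items()}, is_oe=True
    )


def oe_matrix(m: ContactMatrix) -> ContactMatrix:
    """Cached observed/expected view of a balanced matrix."""
    if m.is_oe:
        return m
    if "oe" not in m._cache:
        m._cache["oe"] = observed_over_expected(m)
    return m._cache["oe"]


# -- distance decay ------------------------------------------------------


def contact_decay(
    m: ContactMatrix,
    log_bins_per_decade: int = 8,
    fit_range: tuple[float, float] | None = None,
    min_offset: int = 2,
    per_read: bool = False,
) -> DecayProfile:
    """Mean balanced contact per pixel vs genomic distance, log-binned.

    The power-law exponent ``alpha_hat`` is the negative least-squares
    slope of log(mean) on log(distance) within ``fit_range`` (bp). Offsets
    below ``min_offset`` bins are excluded (self-ligation dominated).
    With ``per_read`` the curve is renormalized to sum 1 (a contact
    probability); the exponent is unaffected.
    """
    if not m.balanced:
        raise ValueError("contact_decay requires a balanced matrix")
    bs = m.genome.bin_size
    max_off = max(m.genome.n_bins(c) for c in m.genome.chrom_names) - 1
    sums = np.zeros(max_off + 1)
    counts = np.zeros(max_off + 1, dtype=np.int64)
    for chrom in m.genome.chrom_names:
        coo = m.pixels[chrom]
        vals = m._values(chrom, balanced=True)
        off = coo.col - coo.row
        sums[: m.genome.n_bins(chrom)] += np.bincount(
            off, weights=vals, minlength=m.genome.n_bins(chrom)
        )
        counts[: m.genome.n_bins(chrom)] += _valid_pair_counts(m.mask[chrom])
    offs = np.arange(min_offset, max_off + 1)
    dist = offs * bs
    lo, hi = dist[0], dist[-1]
    n_edges = int(np.ceil(np.log10(hi / lo) * log_bins_per_decade)) + 1
    edges = np.geomspace(lo, hi * (1 + 1e-9), max(n_edges, 2))
    idx = np.digitize(dist, edges) - 1
    nb = edges.size - 1
    bin_sum = np.bincount(idx, weights=sums[offs], minlength=nb)[:nb]
    bin_cnt = np.bincount(idx, weights=counts[offs].astype(float), minlength=nb)[:nb]
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = bin_cnt > 0
    centers, bin_sum, bin_cnt = centers[keep], bin_sum[keep], bin_cnt[keep]
    mean_contact = bin_sum / bin_cnt
    if per_read:
        mean_contact = mean_contact / bin_sum.sum()
    if fit_range is None:
        fit_range = (centers[0], centers[-1])
    infit = (centers >= fit_range[0]) & (centers <= fit_range[1]) & (mean_contact > 0)
    if infit.sum() < 3:
        raise ValueError(f"fewer than 3 distance bins inside fit_range {fit_range}")
    slope, _ = np.polyfit(np.log10(centers[infit]), np.log10(mean_contact[infit]), 1)
    return DecayProfile(
        distances=centers,
        mean_contact=mean_contact,
        alpha_hat=float(-slope),
        fit_range=tuple(fit_range),
        n_pixels=bin_cnt,
    )


# -- depth manipulation --------------------------------------------------


def downsample(m: ContactMatrix, target_total: int, seed: int) -> ContactMatrix:
    """Binomially thin counts to an expected total of ``target_total``.

    Each contact is retained independently with probability
    target_total / total_contacts; with probability-1 retention the matrix
    is returned unchanged.
    """
    total = m.total_contacts
    if target_total > total:
        raise ValueError(f"target_total {target_total} exceeds total_contacts {total}")
    if target_total == total:
        return m.copy()
    p = target_total / total
    rng = np.random.default_rng(seed)
    pixels = {}
    for chrom in m.genome.chrom_names:
        coo = m.pixels[chrom]
        counts = coo.data
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("downsample requires integer raw counts")
        kept = rng.binomial(np.round(counts).astype(np.int64), p).astype(float)
        nz = kept > 0
        pixels[chrom] = sparse.coo_matrix(
            (kept[nz], (coo.row[nz], coo.col[nz])), shape=coo.shape
        )
    return ContactMatrix(m.genome, pixels, n_inter=m.n_inter)


# -- map comparison ------------------------------------------------------


def relative_difference(
    a: ContactMatrix, b: ContactMatrix, pseudocount: float | None = None
) -> dict[str, sparse.coo_matrix]:
    """Signed per-pixel log2 ratio of two depth-normalized maps.

    Both maps are scaled to the same total before the ratio, mirroring the
    equal-valid-count comparison maps the relative-difference heatmaps use.
    The default pseudocount is the 1st percentile of the pooled nonzero
    scaled pixels. The result is antisymmetric under argument swap.
    """
    if a.genome != b.genome:
        raise ValueError("matrices must share genome and bin size")
    ta, tb = a.total_contacts, b.total_contacts
    if ta == 0 or tb == 0:
        raise ValueError("cannot compare an empty matrix")
    t = 0.5 * (ta + tb)
    sa, sb = t / ta, t / tb
    use_bal_a = a.weights is not None
    use_bal_b = b.weights is not None
    if pseudocount is None:
        pooled = np.concatenate(
            [a._values(c, use_bal_a) * sa for c in a.genome.chrom_names]
            + [b._values(c, use_bal_b) * sb for c in b.genome.chrom_names]
        )
        pooled = pooled[pooled > 0]
        pseudocount = float(np.percentile(pooled, 1)) if pooled.size else 0.0
    out = {}
    for chrom in a.genome.chrom_names:
        A = a.sym(chrom, balanced=use_bal_a) * sa
        B = b.sym(chrom, balanced=use_bal_b) * sb
        union = (A + B).tocoo()
        upper = union.row <= union.col
        r, c = union.row[upper], union.col[upper]
        va = np.asarray(A[r, c]).ravel()
        vb = np.asarray(B[r, c]).ravel()
        with np.errstate(divide="ignore"):
            lr = np.log2(va + pseudocount) - np.log2(vb + pseudocount)
        out[chrom] = sparse.coo_matrix((lr, (r, c)), shape=A.shape)
    return out
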