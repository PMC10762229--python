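"""Fixed benchmark configurations with exported ground truth.

These builders pin the study conditions under which every estimator in the
package is validated: a boundary/decay/looping benchmark map (one 5-Mb
chromosome at 200-bp bins, 5e6 contacts, alpha = 0.8, 80 graded domain
junctions of which 20 are strong boundaries, four looping factors with dot
multipliers 1/2/3/5 plus a non-looping random factor, 20 stripes), an
SE-pattern benchmark (50 planted loops, stripes, and domains each), a
WT/perturbed map pair with tunable occupancy-contact coupling, and a
boundary-GLM track benchmark. All are deterministic given a seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import contact as ct
from .regions import RegionSet
from .simulate import (
    GroundTruth,
    SimulationConfig,
    boundary_strength_field,
    simulate_contact_map,
    simulate_genome_annotation,
    simulate_perturbed_pair,
    simulate_tracks,
)

__all__ = [
    "boundary_benchmark",
    "se_benchmark",
    "perturbation_benchmark",
    "glm_benchmark",
    "glm_population_coefficients",
]

LOOP_GAMMAS = (1.0, 2.0, 3.0, 5.0)


def _cluster_peaks(rng, n_bins, bin_size, n_clusters, cluster_size=3):
    """Clustered peak positions (bp) yielding pairs in the 8-50 kb band:
    intra-cluster spacings are drawn in [9 kb, 24 kb] so every
    intra-cluster pair lands inside the enumeration bounds."""
    peaks = []
    for _ in range(n_clusters):
        start = int(rng.integers(60_000, n_bins * bin_size - 120_000))
        pos = start
        members = [pos]
        for _ in range(cluster_size - 1):
            pos += int(rng.integers(9_000, 24_000))
            members.append(pos)
        peaks.extend(members)
    return np.array(sorted(peaks))


def boundary_benchmark(seed: int) -> dict:
    """The default 5-Mb benchmark map with boundaries, dots, and stripes."""
    cfg = SimulationConfig(seed=seed)
    genome, truth = simulate_genome_annotation(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    chrom = genome.chrom_names[0]
    n_bins = genome.n_bins(chrom)
    bs = cfg.bin_size
    # looping factors: clustered peaks; dots planted at every enumerated pair
    from .loops import enumerate_peak_pairs

    peak_sets: dict[str, RegionSet] = {}
    for gamma in LOOP_GAMMAS:
        pts = _cluster_peaks(rng, n_bins, bs, n_clusters=45)
        peaks = RegionSet.from_arrays([chrom] * pts.size, pts, pts + 1)
        name = f"factor_g{gamma:g}"
        peak_sets[name] = peaks
        pairs = enumerate_peak_pairs(peaks, max_sep=50_000, min_sep=8_000, source_factor=name)
        if gamma > 1:
            truth.add_dots(
                chrom,
                pd.DataFrame(
                    {
                        "bin_i": pairs.pairs["pos_a"] // bs,
                        "bin_j": pairs.pairs["pos_b"] // bs,
                        "gamma": gamma,
                        "sd": cfg.dot_sd_bins,
                        "tag": name,
                    }
                ),
            )
    rnd = np.sort(rng.integers(60_000, n_bins * bs - 60_000, size=250))
    peak_sets["factor_random"] = RegionSet.from_arrays([chrom] * rnd.size, rnd, rnd + 1)
    # stripes
    n_stripes = 20
    anchors = rng.integers(2_000, n_bins - 2_000, size=n_stripes)
    extents = rng.integers(cfg.stripe_extent_bp[0] // bs, cfg.stripe_extent_bp[1] // bs + 1, n_stripes)
    orient = np.where(rng.random(n_stripes) < 0.5, "h", "v")
    truth.add_stripes(
        chrom,
        pd.DataFrame(
            {
                "anchor_bin": anchors,
                "extent_bins": extents,
                "mult": cfg.stripe_mult,
                "orientation": orient,
                "tag": "benchmark",
            }
        ),
    )
    m, _ = simulate_contact_map(cfg, truth)
    mb = ct.balance_ice(m)
    return {"cfg": cfg, "genome": genome, "truth": truth, "matrix": mb, "raw": m, "peaks": peak_sets}


# boundary calling settings matched to the planted domain scale
BOUNDARY_WINDOW = 20_000
KEEP_FRACTION = 0.25


def boundary_recovery(bench: dict, tol_bins: int = 2) -> dict:
    """Call boundaries on a benchmark map and score against the truth."""
    from .boundaries import call_boundaries, insulation_score

    ins = insulation_score(bench["matrix"], window=BOUNDARY_WINDOW)
    bset = call_boundaries(ins, keep_fraction=KEEP_FRACTION)
    chrom = bench["genome"].chrom_names[0]
    truth_bins = bench["truth"].strong_boundary_bins(chrom)
    called = (bset.regions.df["start"] // bench["cfg"].bin_size).to_numpy()
    if called.size:
        precision = float(np.mean([np.min(np.abs(truth_bins - c)) <= tol_bins for c in called]))
        recall = float(np.mean([np.min(np.abs(called - t)) <= tol_bins for t in truth_bins]))
    else:
        precision = recall = 0.0
    return {
        "boundaries": bset,
        "insulation": ins,
        "precision": precision,
        "recall": recall,
        "n_called": len(bset),
        "n_candidates": bset.n_candidates,
    }


def se_benchmark(seed: int, n_per_pattern: int = 50) -> dict:
    """SE-pattern map: planted loops, stripes, and domains with one target
    gene per SE."""
    patterns = ["loop", "stripe", "domain"]
    n_se = n_per_pattern * len(patterns)
    slot = 400  # bins per SE slot; windows (+-150 bins) stay separated
    n_bins = n_se * slot + 1_000
    cfg = SimulationConfig(
        seed=seed,
        chromsizes={"chrS": n_bins * 200},
        depth=1.2e7,
        n_junctions=0,
        n_strong=0,
        beta_domain=1.0,
        max_dist_bins=1_000,
    )
    genome = cfg.genome()
    truth = GroundTruth(genome=genome)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 88]))
    chrom = "chrS"
    labels = np.repeat(patterns, n_per_pattern)
    rng.shuffle(labels)
    se_rows, gene_rows, dot_rows, stripe_rows, dom_rows = [], [], [], [], []
    bs = cfg.bin_size
    for k, label in enumerate(labels):
        a = 500 + k * slot  # SE anchor bin
        gene_dist = int(rng.integers(25, 41))
        p = a + gene_dist  # promoter bin (gene on + strand)
        glen_bins = int(rng.integers(8, 13))
        se_rows.append(
            {"chrom": chrom, "start": (a - 5) * bs, "end": (a + 5) * bs, "name": f"SE{k:03d}", "pattern": label}
        )
        gene_rows.append(
            {"chrom": chrom, "start": p * bs, "end": (p + glen_bins) * bs, "name": f"tg{k:03d}", "strand": "+"}
        )
        if label == "loop":
            dot_rows.append({"bin_i": a, "bin_j": p, "gamma": 6.0, "sd": 1.5, "tag": f"SE{k:03d}"})
        elif label == "stripe":
            stripe_rows.append(
                {
                    "anchor_bin": a,
                    "extent_bins": int(rng.integers(80, 121)),
                    "mult": 4.0,
                    "orientation": "h",
                    "tag": f"SE{k:03d}",
                }
            )
        else:
            dom_rows.append({"start_bin": a, "end_bin": p + 1, "beta": 3.0, "gene": f"tg{k:03d}"})
    if dot_rows:
        truth.add_dots(chrom, pd.DataFrame(dot_rows))
    if stripe_rows:
        truth.add_stripes(chrom, pd.DataFrame(stripe_rows))
    if dom_rows:
        truth.add_extra_domains(chrom, pd.DataFrame(dom_rows))
    truth.ses = RegionSet(pd.DataFrame(se_rows))
    truth.genes = RegionSet(pd.DataFrame(gene_rows))
    m, _ = simulate_contact_map(cfg, truth)
    mb = ct.balance_ice(m)
    return {"cfg": cfg, "genome": genome, "truth": truth, "matrix": mb}


def perturbation_benchmark(seed: int, coupling: float, n_affected: int = 100, n_genes: int = 1000) -> dict:
    """Matched WT/perturbed maps plus occupancy tracks.

    The affected genes sit in the 2-3 kb length stratum and carry the top
    WT Pol II occupancy, so the standard selection rules recover them. Sizes
    (100 genes, 3.2e7 contacts) keep the regression's sampling error well
    inside the recovery tolerances; depth is cheap in the simulator, gene
    count is not.
    """
    cfg = SimulationConfig(
        seed=seed,
        chromsizes={"chrP": 6_000_000},
        depth=3.2e7,
        n_junctions=0,
        n_strong=0,
        beta_domain=1.0,
        n_genes=n_genes,
        frac_midlength=0.4,
        gene_beta=2.5,
    )
    genome, truth = simulate_genome_annotation(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    lengths = truth.genes.lengths()
    mid = np.flatnonzero((lengths >= 2_000) & (lengths <= 3_000))
    affected = np.sort(rng.choice(mid, size=min(n_affected, mid.size), replace=False))
    m_wt, m_mut, occ_wt, occ_mut = simulate_perturbed_pair(cfg, truth, coupling, affected=affected)
    return {
        "cfg": cfg,
        "genome": genome,
        "truth": truth,
        "wt": ct.balance_ice(m_wt),
        "mut": ct.balance_ice(m_mut),
        "occ_wt": occ_wt,
        "occ_mut": occ_mut,
        "affected": affected,
    }


GLM_LOADINGS = {
    "accessibility": 1.0,
    "active_mark_1": 0.8,
    "active_mark_2": 0.6,
    "repressive_mark_1": -0.9,
    "repressive_mark_2": -0.7,
}
GLM_SNR = 2.0


def glm_benchmark(seed: int) -> dict:
    """Tracks with signed loadings on the boundary-strength field plus a
    noisy response; returns the fitted inputs and the population truth."""
    cfg = SimulationConfig(
        seed=seed, chromsizes={"chrG": 2_000_000}, n_junctions=40, n_strong=10
    )
    genome, truth = simulate_genome_annotation(cfg)
    f = boundary_strength_field(truth, cfg).flat()
    sd_f = f.std()
    loadings = {}
    for name, a in GLM_LOADINGS.items():
        sigma = abs(a) * sd_f / GLM_SNR
        baseline = max(0.0, -a * f.max()) + 4 * sigma  # keep truncation rare
        loadings[name] = (a, sigma, baseline)
    tracks = simulate_tracks(truth, cfg, loadings)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 111]))
    response = f + rng.normal(0.0, sd_f, f.size)
    return {
        "cfg": cfg,
        "truth": truth,
        "field": f,
        "tracks": tracks,
        "loadings": loadings,
        "response": response,
    }


def glm_population_coefficients(loadings: dict, f: np.ndarray) -> dict[str, float]:
    """Population OLS coefficients (standardized-predictor scale) for the
    GLM benchmark: y = f + noise regressed on x_k = b_k + a_k f + e_k."""
    names = sorted(loadings)
    a = np.array([loadings[n][0] for n in names])
    sig = np.array([loadings[n][1] for n in names])
    var_f = f.var()
    cov = np.outer(a, a) * var_f + np.diag(sig**2)
    sd_x = np.sqrt(np.diag(cov))
    cov_std = cov / np.outer(sd_x, sd_x)
    cxy = a * var_f / sd_x
    beta = np.linalg.solve(cov_std, cxy)
    return dict(zip(names, beta))
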