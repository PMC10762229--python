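# microdomain

Nucleosome-resolution chromatin-contact analysis for plant (and other
compact) genomes: from a list of Micro-C/Hi-C contact pairs to insulation
boundaries, aggregate domain/loop pileups, super-enhancer contact
patterns, per-factor looping potential, and models linking 1D chromatin
tracks to 3D structure — plus a fully ground-truthed synthetic contact-map
generator so every estimator can be validated without sequencing data.

It is aimed at genomics analysts working with high-resolution (~200-bp
bin) contact maps, where domains are gene-sized, most regulatory loops
span less than 50 kb, and the interesting structure lives close to the
diagonal.

## What it computes

**Contact maps.** Binning of pairs-format contacts onto a fixed lattice,
coarsening, iterative-correction balancing (per-bin weights *w* with
*w_i c_ij w_j* having equal marginals), per-diagonal expected values and
observed/expected (O/E) normalization, distance-decay curves P(s) with a
power-law exponent fit (P(s) ~ s^-alpha), binomial downsampling, and
log2 relative-difference maps between conditions.

**Boundaries.** The insulation score of bin *i* at window *k* bins is

    IS(i) = log2( mean contact in [i-k, i-1] x [i+1, i+k] / chromosome mean )

Local minima of IS are candidate boundaries; each is ranked by its
topographic prominence (boundary strength), and the top quantile (25% by
default) is called. Downstream: boundary annotation against gene models
(promoter / gene body / downstream / intergenic with fold enrichment over
shuffles), overlap statistics, and a seeded permutation test of region-set
overlap with empirical p-values.

**Pileups.** Centered (TSS/boundary) and length-rescaled (gene body,
domain) aggregate O/E pileups with shuffled-anchor backgrounds; divergent/
convergent/tandem gene-pair classification; expression strata (class 1 =
silent, then equal-count quantiles); aggregate-difference maps between
conditions; and a classifier assigning each super-enhancer's contact
pattern to loop / stripe / domain / other.

**Looping potential.** All peak pairs of a ChIP-seq factor within 50 kb
are piled up off-diagonal (8-kb window); central enrichment over a
separation-preserving shifted background quantifies the factor's tendency
to sit at loop anchors.

**1D-3D models.** Per-bin weighted-mean quantification of bedGraph
signal, a Gaussian GLM ranking chromatin tracks as predictors of boundary
strength, selection of Pol-II-perturbed genes (top-occupancy, 2-3 kb,
occupancy drop), gene-body contact z-scores, and the regression of contact
log2 fold change on occupancy log2 fold change.

**Synthetic maps.** Poisson contact maps with planted coverage biases,
power-law decay, graded domain boundaries, dots, stripes, gene-body
domains, coupled ChIP-like tracks, and matched WT/perturbed map pairs —
all with exported ground truth (see `docs/methods.md`).

## Worked example

Simulate a small map, balance it, and call boundaries:

```bash
microdomain simulate --seed 3 --out sim --length 1000000 --depth 1000000 \
    --n-junctions 16 --n-strong 4 --n-genes 50
microdomain bin --pairs sim/pairs.tsv --chrom-sizes sim/chrom.sizes \
    --bin-size 200 --out-prefix raw
microdomain balance --matrix-prefix raw --chrom-sizes sim/chrom.sizes \
    --bin-size 200 --out-prefix bal
microdomain decay --matrix-prefix bal --chrom-sizes sim/chrom.sizes \
    --bin-size 200 --fit-range 20000:500000 --out decay.tsv
microdomain boundaries --matrix-prefix bal --chrom-sizes sim/chrom.sizes \
    --bin-size 200 --window 10000 --out-prefix calls
microdomain overlap-test --a calls.boundaries.bed --b sim/boundaries_truth.bed \
    --chrom-sizes sim/chrom.sizes --n-perm 999 --seed 3
```

which prints

```
simulated 1000523 contacts -> sim
binned 1000523 cis contacts (0 trans seen)
{"converged": true, "n_iter": 17}
alpha_hat	0.795866
7 boundaries from 28 candidates
{"n_perm": 999, "observed": 3, "p": 0.001, "perm_mean": 0.01001001001001001, "perm_sd": 0.09954802715076531, "z": 30.035652896080556}
```

Reading the output: the fitted decay exponent (0.796) recovers the planted
power law (0.8); 28 insulation minima pass the prominence floor and the
top 25% (7 calls) are kept; 3 of the calls land on the 4 planted strong
boundaries (the remainder are the strongest of the planted weak-grade
junctions), an overlap never reached in 999 random relocations (p = 0.001,
the smallest value the add-one permutation p can take).

The same operations are available as a library
(`microdomain.bin_contacts`, `balance_ice`, `insulation_score`,
`call_boundaries`, `pileup_centered`, `enumerate_peak_pairs`, ...), which
is the more convenient interface for anything beyond one-off runs; the
modeling steps (`fit_boundary_glm`, `gene_contact_scores`,
`perturbation_regression`) are library-first with thin CLI wrappers.

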