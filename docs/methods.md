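# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `microdomain`. It covers what each procedure assumes,
which parameters matter and why their defaults were chosen, and what the
synthetic benchmark does and does not establish about real data.

## Contact-matrix model

All analyses operate on per-chromosome intra-chromosomal (cis) contact
matrices binned on a fixed lattice (0-based, half-open bins; the last bin
of a chromosome may be short). Counts are stored sparsely once per
unordered bin pair; symmetry is implicit. Inter-chromosomal records are
counted for the cis/total quality statistic but never stored: every
analysis in this package is a cis analysis, and trans maps have a
different noise structure that none of the estimators here model.

**Balancing.** Iterative correction finds per-bin multiplicative weights
that equalize the weighted marginals (the standard matrix-scaling model of
coverage bias). Defaults: convergence when the coefficient of variation of
the marginals falls below `tol = 1e-5`; `max_iter = 200`; bins whose raw
marginal is below 2% of the mean nonzero marginal are masked (too little
coverage to estimate a weight). The update divides weights by the *square
root* of the normalized marginal: the full-step update converges faster on
dense complete matrices but two-cycles on banded or truncated maps, and
the damped step is robust on both. Weights are rescaled to mean 1 over
unmasked bins, so balanced values stay on the raw-count scale.
Non-convergence is reported in `balance_info`, not raised: a map balanced
to CV 1e-4 is still usable, and the caller decides.

**Expected and observed/expected.** The expected value at genomic
separation `d` is the mean balanced value over all unmasked pixels at that
separation, per chromosome. O/E divides each pixel by the expected value
at its offset; diagonals with no valid pixels are undefined and their
pixels are dropped (never treated as 0). By construction the per-diagonal
mean of O/E is 1, which is what makes pileups across genomic distances
comparable.

**Distance decay.** P(s) is the mean balanced contact per pixel in
geometric distance bins (8 per decade by default; the binning is a display
and fitting choice, not a model). The exponent is the negative slope of
the least-squares line on log-log axes inside a user-chosen fit range.
Separations below 2 bins are excluded: at nucleosome resolution the first
diagonals are dominated by self-ligation and unligated-end artifacts. The
default normalization is per-pixel (a contact *density*); a per-read
normalization (curve rescaled to sum 1, a contact *probability*) is
available via `per_read=True` and does not change the exponent. When
fitting the benchmark maps we fit at 100 kb-2 Mb, beyond the planted
domain scale (tens of kb), because domain and boundary structure distorts
the short-range slope; the same consideration applies to real maps.

**Downsampling** is binomial thinning per contact, the exact analogue of
subsampling valid pairs, and is seeded. **Relative difference** maps are
log2 ratios of depth-normalized (and, when available, balanced) pixels
over the union of nonzero pixels; the pseudocount defaults to the 1st
percentile of pooled nonzero values, computed symmetrically so the map is
exactly antisymmetric under argument swap.

## Insulation and boundary calling

The insulation score at bin `i` with window `w = k` bins is the mean
balanced contact in the `k x k` square of pixels connecting the `k` bins
left of `i` with the `k` bins right of `i` (the diamond crossing `i`;
pixels involving bin `i` itself are excluded), log2-normalized to the
chromosome mean so the chromosome mean of `2**score` is exactly 1. The
score is NaN where the diamond leaves the chromosome or touches more than
50% masked pixels. It is invariant under global rescaling of the matrix.

Boundaries are called on the score track as follows:

1. strict local minima are located (plateaus resolve to their center bin);
   minima within one window of a chromosome end are discarded as edge
   artifacts;
2. each minimum gets a **strength**: its topographic prominence on the
   negated track — walk outward until a lower minimum (or the track end)
   is reached on each side, take the highest score in each walk, and
   subtract the minimum's score from the smaller of the two barriers;
3. minima with prominence below `min_prominence` (default 0.1 log2 units)
   are dropped. This floor is essential for the "top fraction of locally
   lowest positions" rule to be meaningful: an unsmoothed insulation track
   has thousands of sub-noise ripples, and without a floor the calling
   quantile would be a quantile of noise. 0.1 log2 units is the
   conventional insulation boundary-strength threshold and sits far above
   the score noise at typical depths;
4. the top `keep_fraction` (default 0.25) of the remaining candidates,
   ranked by strength, are returned; the count is
   `ceil(keep_fraction * n_candidates)`, applied per chromosome by default
   (genome-wide ranking available via `scope="genome"`). Ties break toward
   the lower score, then the leftmost coordinate.

The window should match the scale of the domains of interest: the package
default is 10 bins (2 kb at 200-bp bins, the gene/nucleosome scale), while
the synthetic benchmark — whose planted domains are tens of kb — is called
at 20 kb. Flank intervals between consecutive kept boundaries are returned
as the inter-boundary domains.

## Aggregate pileups

Centered pileups stack O/E windows on anchor diagonal pixels (TSS for
stranded anchors, midpoint otherwise), NaN-padded at chromosome ends and
mirrored for minus-strand anchors. Rescaled pileups (aggregate domain
analysis) stretch each region's O/E submatrix — extended by
`flank_frac x length` on both sides — onto a fixed grid by NaN-aware block
averaging. Both report enrichment relative to a background built by the
same procedure on shuffled anchors (10 shuffle sets by default, seeded).
Piling up O/E rather than balanced counts removes distance decay before
averaging; the shuffled background additionally controls for residual
chromosome-level structure, so a featureless map scores 1 everywhere.
Off-diagonal peak-pair pileups clip the triangle below the main diagonal
to NaN and use a separation-preserving background: both anchors of a pair
are shifted by one shared random offset, so the background inherits the
foreground's distance distribution. The looping-potential summary is the
mean of the central 3x3 block of the enrichment grid divided by the mean
of the four 6x6 corner blocks.

The peak-pair search enumerates all same-chromosome pairs with separation
in [`min_sep`, `max_sep`]; `max_sep` defaults to 50 kb (short-range
enhancer-promoter loops; larger windows dilute the average with far-from-
diagonal noise) and `min_sep` to twice the pileup half-window so windows
never straddle the diagonal. Peaks anchor at their narrowPeak summit when
available, else the interval midpoint.

## Super-enhancer pattern classification

`se_pattern_score` automates a call that is inherently a by-eye judgment:
does the neighborhood of an SE show a dot to its target promoter, a band
anchored at the SE, a filled square, or nothing? Three template scores are
computed on the O/E window (+-30 kb) around the SE against a local
background that excludes the SE-promoter square:

* **stripe** — best mean over bands anchored at the SE, evaluated beyond
  the SE-promoter square plus a 5-bin margin, over candidate extents of
  20/40/60 bins in both directions;
* **domain** — mean O/E of the square spanning the SE anchor and the
  nearest promoter;
* **loop** — best 3x3 center over its surrounding annulus (radius 4-6) at
  candidate (SE, promoter) pixels.

Classification is a decision list in that order with thresholds 2.0 / 1.5
/ 1.5 x background, falling through to "other". The ordering is the load-
bearing choice: a band extending beyond the square is producible only by a
stripe and a filled square only by a domain, whereas the small donut
center is Poisson-noisy at realistic depth and fires on stripe and domain
pixels too; testing the most specific signature first is markedly more
robust than ranking the raw scores. The thresholds are package choices
calibrated on the synthetic patterns, not published constants, and should
be revisited for maps at very different depths.

## Track quantification and the boundary GLM

`track_weighted_mean` converts bedGraph-style interval signal to one value
per bin, weighting by overlap length. Uncovered bases count as zeros
(coverage semantics — in a whole-genome ChIP map, absence of signal is
informative); `skip_uncovered=True` averages covered bases only.
Overlapping input intervals are resolved per base by the latest record,
with a warning.

The boundary GLM regresses a response (per-bin insulation score by
default, or per-boundary strength) on standardized track means using a
Gaussian family with identity link — the family/link is reported in the
fit metadata since other choices are defensible. Standardization makes
coefficient magnitudes comparable, so predictors are ranked by
`|estimate|`; constant columns are dropped with a warning and
rank-deficient designs raise an error naming the most collinear pair.

## Gene-body contact z-score and perturbation regression

The contact intensity of one gene is scored as the mean z-score of its
gene-body pixels (upper triangle, diagonal excluded), where each pixel is
standardized against the chromosome-wide distribution of balanced values
at the same separation. The reference distribution is chromosome-wide
(not arm-wise); the score is scale-free. Genes must span at least 2 bins.

Perturbed-gene selection keeps genes of medium length (2-3 kb by default,
avoiding gene-length confounds), in the top 10% of all genes by WT
gene-body occupancy, with lower occupancy in the perturbed condition; an
optional exclusion list supports control-affected gene removal. The
perturbation regression is ordinary least squares of the per-gene log2
contact fold change (ratio of gene z-scores; defined only when both are
positive) on the log2 occupancy fold change. The occupancy pseudocount is
the 5th percentile of positive genome-wide WT track values — computed on
the whole track rather than the analyzed subset, whose occupancies are
high by construction.

## Synthetic data: what it emulates

The generator draws Poisson counts per pixel from

    lambda(i,j) = Z * b_i * b_j * (d * bin)^-alpha
                  * 2^-(sum of crossed junction depths)   [d <= 50 kb]
                  * beta_dom[same tiling domain] * beta_extra[planted square]
                  * dots * stripes

with lognormal per-bin coverage biases `b`, a power-law decay (alpha = 0.8
by default), a tiling of the chromosome into domains whose junctions carry
graded insulation attenuations, planted Gaussian dots (SD 1.5 bins) and
band stripes, and arbitrary planted squares (gene bodies, SE domains). `Z`
normalizes the expected total to the requested depth. One deliberate
departure from a fully multiplicative junction model: junction attenuation
applies only to pixels within 50 kb separation. An unbounded product over
the ~80 junctions of a 5-Mb chromosome would suppress megabase-range
contacts by many orders of magnitude and destroy the planted decay
exponent; insulation at boundaries is a short-range phenomenon in real
maps as well.

Defaults (the benchmark conditions): one 5-Mb chromosome at 200-bp bins
(25,000 bins), 5e6 contacts, bias sigma 0.2, 80 junctions of which 20 are
"strong" boundaries in four log2-depth grades (1, 4/3, 5/3, 2) against a
weak background grade (0.25-0.5), inside-domain multiplier 1.3, 50 planted
dots per looping factor at multipliers {1, 2, 3, 5} plus a 250-peak
non-looping factor, and 20 stripes of 2-10 kb. Annotations place
non-overlapping genes with a Markov strand chain whose stay probability
equals the target tandem fraction, a 2-3-kb length stratum, expression
with a silent class, and tRNA-like point features optionally planted at
boundaries. ChIP-like tracks are `baseline + a * field + noise` truncated
at 0, where the field is the nearest-junction depth under a 10-bin
Gaussian kernel; the baseline keeps negative loadings meaningful.

The WT/perturbed pair draws a per-gene occupancy drop `delta` and
multiplies the *excess* gene-body contact intensity (the planted
enrichment above background) by `(1 - delta)^c`, so the planted contact
log2 fold change is exactly `c` times the occupancy log2 fold change.
"Domain intensity" here means the excess, not the whole pixel value:
attenuating the excess is what makes the z-score-based fold change track
the planted coupling, since the z-score itself measures excess over the
chromosome background. The perturbation benchmark uses a 6-Mb chromosome,
1,000 genes, 100 affected, 3.2e7 contacts, and a gene-body multiplier of
2.5: with stronger multipliers or shallower maps, iterative correction
absorbs a visible share of the gene-body enrichment into bin weights
(gene bins have elevated marginals) and the measured fold change is
attenuated; at these settings the measured fold change tracks the planted
value within ~2%, and the regression's null sampling error is well inside
the recovery tolerances.

**What passing the benchmark does not show.** Poisson pixel noise
understates the overdispersion of real libraries (an optional Gamma
mixing parameter exists but the benchmark does not use it); biases are
multiplicative and bin-independent, unlike mappability and restriction
artifacts; there are no unmappable deserts, no trans contacts, no
ligation artifacts at the first diagonals, and boundary grades are
cleanly separated rather than continuous. Recovery rates on this
benchmark are therefore upper bounds on real-data performance, and the
boundary-calling and SE-classification thresholds in particular should be
re-examined on real maps.

## Numerical and degenerate-input conventions

Empty contact streams produce valid all-zero matrices; empty anchor or
pair sets raise. Diagonals with no valid pixels have undefined (NaN)
expected values, and pixels on them are dropped from O/E rather than set
to 0. Insulation near chromosome ends is NaN, and anchors whose windows
leave the chromosome are NaN-padded (centered pileups) or dropped with a
warning (flank overflows). The permutation test relocates each query
region uniformly within its own chromosome, length-preserved, without
exclusion constraints, and reports the add-one empirical p-value
`(1 + #{perm >= obs}) / (1 + n_perm)`, which is conservative under heavy
ties. All stochastic procedures take explicit seeds and are reproducible
bit-for-bit; identical simulation configs produce byte-identical outputs.

## Benchmark problem sizes

The validation suite runs, per seed: the 5-Mb default benchmark (boundary
recovery, decay fit, looping potential), a 1,000-bin bias-planted
balancing check, 300-bin dense-oracle equivalence checks at 1e-10, a
150-SE pattern benchmark on a 12-Mb chromosome at 1.2e7 contacts, two
WT/perturbed pairs (couplings 0.5 and 0), 100 seeded GLM replicates on a
2-Mb genome, and a permutation-calibration experiment of 200 replicates x
500 permutations with 2,000 query regions — sizes chosen so every
estimator's sampling error is small against its recovery tolerance while
the whole suite completes in minutes on one CPU.
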