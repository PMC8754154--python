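# Methods

This note documents the models behind `ttkinetics`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate conventions

All coordinates are 0-based half-open (BED convention) on every internal
surface; GTF input (1-based closed) is converted on read and back on
write. A single convention end to end removes the most common source of
off-by-one drift between stages. Coverage lives in `CoverageTrack`
objects: per-strand, per-chromosome vectors of non-negative per-bin
signal. Partial-bin overlap at interval edges is pro-rated linearly, which
makes interval densities (RPK, reads per kilobase) invariant to bin size
for uniform signal and additive over interval partitions.

## Transcription-unit annotation

Binned labeled-RNA counts (200-bp bins, replicates summed) are segmented
with a two-state HMM — inactive and active — with Poisson emissions.
Baum–Welch runs on scaled forward–backward recursions; the log-likelihood
is non-decreasing by construction and iteration stops when the improvement
falls below 1e-6 (default cap 100 iterations). Initialization is
data-driven (inactive rate from the 25th percentile of nonzero counts
scaled down, active from the 90th percentile; transition self-probability
0.99) and states are relabeled after fitting so state 1 always carries the
larger mean — this makes the fit reproducible and immune to label
switching without random restarts. An all-zero track yields a single
inactive state rather than an error.

Real genomic counts are overdispersed relative to Poisson; an optional
log-normal random effect on the emission rate is provided, approximated by
a 5-point Gauss–Hermite mixture whose rate multipliers have mean one
(`sigma=0` recovers the pure Poisson model exactly). The Poisson default
is sufficient for the synthetic tests; the overdispersed variant is for
real data.

Decoding is posterior thresholding at 0.5 (not Viterbi): maximal runs of
active-posterior bins become TU fragments, with a configurable minimum
length defaulting to one bin and no gap bridging — merging across gaps is
the job of the exon-join step, which collapses all fragments overlapping a
gene's exons into a single mRNA TU spanning from the first to the last
such fragment. Remaining fragments are classified by their 5′ end relative
to nearby genes (windows of 1 kb around TSS and TES, distances measured in
the host gene's orientation); a fragment qualifying for several genes goes
to the nearest TSS, with gene-id as a deterministic tie-break, so
classification is a total function.

## Spike-in normalization and RNA kinetics

Six spike-in species (two concentrations × labeling rates 100/10/0 %) are
added per cell equivalent (0.4 ng per 10⁶ cells, split by concentration)
before RNA extraction, so losses in biotinylation, purification and
library preparation cancel. Size factors are median-of-ratios: the
per-feature reference is the geometric mean across samples and the factor
is the median count/reference ratio over features positive in all samples
— computed over all spike-ins for the total library and over the four
labeled species for the labeled library. The contrast
log2(sf_labeled) − log2(sf_total) is a cell-level turnover summary.

The labeling-rate model is fitted as a full two-covariate regression —
ordinary least squares of log2(rate) on (log2 X_F, log2 X_L) over the
labeled species — rather than the algebraically sufficient log-ratio, so
the fit itself can absorb any systematic capture difference between the
two libraries; with noiseless counts
X_L = r·c·X_F the fit inverts to coefficients (−1, +1) identically, which
the tests assert to 1e-9. Five-fold cross-validation with ten reshuffles
is attached to the fitted model. The weight model uses all six species
with response log2(weight per cell); unlabeled species can carry zero
labeled counts, so a 0.5 pseudocount enters the labeled channel (and gene
counts get the same pseudocount at prediction time).

Half-life assumes exponential turnover at steady state: a pulse of length
t_label labels fraction θ = 1 − e^(−k·t_label) of the pool, so
k = −ln(1−θ)/t_label and t½ = ln 2/k; θ = 0.5 at a 5-minute pulse is
exactly a 5-minute half-life. θ̂ is clipped to (1e-4, 1−1e-4) — an
unclipped θ̂ ≥ 1 would give an infinite rate — and such genes are flagged
`fully_labeled` (their half-life is a lower bound). Copy number converts
mass with a mean ribonucleotide residue mass of 340 g/mol:
c = w·N_A/(L_eff·340). Synthesis rate is reported per minute,
s = θ̂·c/t_label; because "labeling rate × copy number" is itself a
meaningful quantity (labeled copies per cell), it is emitted unchanged as
`labeled_copies`. Note s = θ·c/t and the steady-state flux c·ln2/t½ differ
by the factor θ/(−ln(1−θ)), which is near 1 only for half-lives well above
t_label; with the default half-life distribution (median 60 min) the
median discrepancy is a few percent, and the consistency test bounds the
median deviation at 10%.

## Elongation velocity and pausing

LRNA density over a gene body is proportional to the rate at which
polymerases enter productive elongation; quantitatively scaled Pol II S5p
occupancy is proportional to initiation/velocity. Their ratio
v̂ = RPK_LRNA/RPK_S5p is therefore a relative elongation velocity,
comparable across genes and conditions provided both tracks are on
quantitative scales (spike-in factors for LRNA; the ChIP's own
quantitative scaling for S5p). The gene-body interval for v̂ runs from
TSS+500 to the TES, excluding the promoter-proximal pause region — the
same body definition the pausing index uses — and both assays must carry
at least 10 read equivalents over the body (configurable floor) or the
gene is reported missing rather than zero.

Absolute calibration uses a CDK9-inhibition time course: with initiation
blocked, the signal behind the last wave of polymerases clears, and the
cleared distance grows linearly with time. Per gene, OLS of distance on
time gives velocity (slope) and response delay (intercept); genes with
fewer than two usable points or non-positive slope are dropped and
counted. The wavefront edge is located at the first gene bin reaching half
the gene-body level and refined through the partially cleared boundary bin
by linear interpolation, so noiseless input recovers the cleared distance
— and hence the regression slope — exactly. The global scale is the
median of measured/v̂ over matched genes (median rather than regression:
robust to outliers, and a single multiplicative constant is all the model
calls for).

Pausing index is pause-interval density over TSS+500..+1500 body density;
flat occupancy gives PI = 1 by construction. Pausing time divides the
pause-interval length by the local velocity in bp/s (52 bp at
0.1486 kb/min → 21 s). Velocity profiles along genes (per-bin ratios
resized to a common length by monotone cubic interpolation and
log-transformed) are grouped by k-means with a fixed seed and 10 restarts;
groups are relabeled by ascending mean level so slow/medium/fast is
deterministic regardless of the seed.

## Termination-site calling

Each gene's potential termination window runs from its last exon end up to
15 kb downstream, clipped at the next downstream gene TSS on either strand
(configurable to same-strand; either-strand prevents bleed-through from
convergent genes) and at the chromosome end; windows shorter than 1 kb
exclude the gene. Within the window, coverage is re-binned to 50-bp scan
bins, log-transformed with a pseudocount of one read-equivalent (one read is
the natural unit; a `--no-log` variant is exposed), centered
to mean zero and cumulatively summed. The argmax of the cumulative sum —
earliest index on ties — is the split maximizing the before/after mean
contrast, a fact the tests verify against an exhaustive split-point search
on hundreds of random windows. An all-constant window returns the window
start, flagged. Change classes between conditions use the termination
distance (site − TES): below −500 bp shortening, above +500 bp extending,
otherwise unchanged.

A caveat the synthetic experiments quantify: on a smoothly decaying
(exponential) read-through profile the CUSUM maximum sits where log-signal
crosses the window mean, and the curve is nearly flat there, so the called
site carries positional jitter of several hundred bp at realistic depths
(per-gene SD ≈ 430 bp at the default simulation depth; replicate
averaging reduces it only partly). Site *shifts* of a kilobase and more
are detected reliably — nearly every gene whose decay length is halved is
classified shortening — but the ±500 bp "unchanged" band is close to the
jitter floor, so between-replicate reproducibility of the class label is
limited. `scripts/acceptance.py` reports both fractions as measured.

GC−AT contrast is the mean GC minus AT frequency in the ±100 bp flank of
the called site. Feature attribution for termination distance (or any
response) uses a multivariate regression through the origin on
standardized inputs — log1p-transformed, trimmed at the 99.5% quantile,
scaled to N(0,1) — where share_j = β_j·⟨x_j, y⟩/⟨y, y⟩ sums exactly to the
total R²; negative (suppressor) shares are reported as-is, and
near-collinear designs (condition number > 1e8) fall back to a tiny ridge
penalty (λ = 1e-6).

## QC and neighborhood correlation

4sU mispairs during reverse transcription, producing T→C conversions;
enrichment is the position-level conversion rate of the labeled over the
total library. Cross-contamination is the percentage of labeled-library
reads on unlabeled (r = 0) spike-ins. The spliced fraction is the per-gene
percentage of reads with an alignment gap. Neighborhood co-regulation is
the Pearson correlation of gene and neighbor log2 fold-changes within
distance bins (distance TSS-to-TSS in the gene's orientation), stratified
by relative strand; bins with fewer than 10 pairs or zero variance are
reported missing. Differential fold-changes are taken as input — the
package does not reimplement differential testing.

## The synthetic-data generator

The generator emulates the statistical structure of the real assays on a
toy genome so that each estimator has a recovery test with known truth:

- Geometry: 60 genes on 2 chromosomes, lengths log-normal (median 8 kb,
  log-SD 0.5, minimum 3 kb so pausing-index body intervals fit), laid
  head-to-tail with 25–40 kb intergenic gaps, never overlapping, snapped
  to bin boundaries. Exons cover the first and last quarters of each gene,
  so the last exon end coincides with the TES.
- Kinetic parameters per gene (log-normal draws): initiation rate
  (median 0.5/min), velocity (median 2 kb/min), half-life (median 60 min,
  clipped to 5–500 min), read-through decay length (median 2 kb). Copy
  number is I·t½/ln 2 — the steady-state identity holds exactly by
  construction. Dwell factor 4 over a 200-bp pause interval; labeling
  pulse 5 min.
- Signal model: LRNA per-bp weight is the labeled pool c·θ over the body
  (exactly ∝ I when half-life is held fixed, as in the velocity grid),
  with exponential post-TES decay; S5p is I/v, elevated by the dwell
  factor in the pause interval, same decay; FRNA is c over exons. Reads
  are Poisson per bin at ~2×10⁵ read pairs per library plus a 0.02
  reads/bin background. LRNA is drawn once at 50-bp resolution and summed
  to 200-bp bins, so the TU-calling and termination-scanning views are the
  same experiment. A handful of non-coding TUs (upstream-antisense,
  cis-antisense, intergenic; placed clear of termination windows) exercise
  the classifier.
- Spike-ins: counts proportional to species mass × (labeling fraction,
  with a 0.1% unlabeled→labeled contamination leak), Poisson noise.
  Gene-level count simulation shares the same reads-per-gram depth as the
  spike-ins in each library, which is precisely the condition under which
  the spike-in-trained models calibrate gene kinetics.
- CDK9-inhibition time course: body signal cleared over
  [TSS, TSS + v·(t − t₀)) with fractional clearing of the boundary bin;
  a noiseless mode returns expected values for exactness tests.
- Seeding: one seed fixes everything; an optional separate noise seed
  keeps gene placement fixed while re-drawing read noise, which is how
  replicate and two-condition experiments are simulated.

Not emulated: real sequence content (sequences are random with GC patches
only where a test needs them), fragment-length and GC biases, PCR
duplicates, splicing isoforms (a splice-gap flag is simulated only for the
QC module), overdispersion beyond Poisson, and overlapping genes.
Recovery results on these simulations therefore demonstrate correctness
of the estimators under the stated generative model, not performance on
real libraries — in particular, real overdispersion will widen all
recovery intervals.

## Problem sizes

Default runs use the 60-gene genome at 2×10⁵ read pairs per library;
acceptance computations use a 16-gene initiation × velocity grid for
velocity recovery, 500 random 300-bin windows for the change-point oracle,
5,000 bins for segmentation accuracy, and three averaged replicates per
condition for termination change classes. These sizes give stable
statistics while keeping a full run in seconds on one core.

## Known limitations

- The pausing model is a dwell-factor multiplier on occupancy, not a
  stochastic pause-release simulation; it reproduces density ratios, not
  pause-duration distributions.
- Velocity calibration transfers the wavefront scale by one global median;
  gene-specific calibration error from profile shape is not modeled.
- Termination-site jitter near the ±500 bp class boundary (above).
- The weight model extrapolates from six spike-in species spanning two
  concentrations; real concentration-dependent capture bias would fold
  into its intercept.
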