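# Methods

This note documents the models and procedures implemented in `crestkit`,
the defaults that matter, and the reasoning behind the design choices that
were genuinely open.

## Targets: the peak matrix

Inputs are a consensus peak set (BED), one coverage track per cell type
(bedGraph; piecewise-constant nonnegative runs), and a genome (FASTA).
Regions are re-centered to a fixed width (default 2,114 bp), shifted
minimally when they would overhang a chromosome end; chromosomes shorter
than the width yield a whole-chromosome region flagged `|short`. Peak
height is the max / mean / sum / ln(1+sum) of coverage over the central
window (default 1,000 bp) of each region. `logsum` uses ln(1+·) so the
transform is defined at zero signal. All coordinates are 0-based half-open;
one-hot channel order is A, C, G, T, with N (and out-of-bounds padding)
encoded as zero rows — models therefore see zero input where no sequence
exists, and short sequences can be centered into the model input with
`pad_to_input` (extra pad base on the right for odd remainders).

### Normalization

CPM normalization divides each track by its genome-wide integrated signal
(over all runs; configurable in principle to peak-restricted totals, but
whole-genome is the default because input tracks are usually already
peak-dominated). Depth normalization alone biases against cell types with
many peaks, so columns are rescaled by anchoring on constitutive peaks:
for each cell type, the top `top_frac` regions by height (ties at the
quantile boundary included, so the selection is deterministic) are
filtered by a Gini rule, and the scaling factor is
`reference / mean(constitutive heights)`. The reference is the mean of the
per-class constitutive means (configurable to `max`); the anchor choice
only fixes the global scale, the cross-class alignment is what matters.
After scaling, per-class constitutive means agree to machine precision by
construction.

The Gini index of a region's per-class height vector is
G = Σᵢⱼ|vᵢ−vⱼ|/(2n²v̄), computed via the sorted-rank identity (O(n log n))
and verified in tests against the O(n²) pairwise definition. G is
scale-invariant; an all-zero vector is defined to have G = 0 (no
specificity signal) with a warning rather than NaN. The constitutive
filter is G ≤ μ_G + σ_G, *inclusive* so that degenerate inputs with σ_G=0
(all regions equally nonspecific) still yield a constitutive set; the
comparison rule is a plain callable in `NormalizationConfig`, so stricter
variants (e.g. μ_G − σ_G) are one lambda away. Cell-type-specific regions
are flagged by the strict converse, G > μ_G + σ_G.

`top_frac` defaults to 0.01 as appropriate for real consensus-peak sets of
10⁵–10⁶ regions; on the 300-region synthetic system the tests use 0.1,
since 1% of 300 is a meaninglessly small candidate set.

### Topic mode

A regions × topics probability matrix can stand in for the peak matrix
(classification setting). Columns are binarized by Otsu's rule: the
threshold over the distinct observed values maximizing between-class
variance, mask = p > t. Constant columns get an empty mask with a warning.

### Splitting

Chromosome mode holds out whole chromosomes (defaults: chr8+chr10 for
validation, chr9+chr18 for test); fraction mode shuffles with a fixed seed,
remainder to train. Splits partition the regions; chromosome mode never
places one chromosome in two splits.

## Models

The `Predictor` contract is: batch of one-hot sequences → one score per
cell type, plus the gradient of a chosen class score with respect to the
input. Three architectures satisfy it:

* `linear` — score = Σ w⊙x + b, with closed-form predictions and
  gradients; the analytic reference in attribution and design tests.
* `simple_cnn` — conv stem, global pooling, dense head (topic
  classification default).
* `dilated_cnn` — conv stem (512 filters, kernel 17 by default) followed
  by residual blocks of batch-norm → GELU → dilated conv with dilation
  doubling per block, global average pooling, dropout and a dense head.
  Regression heads are softplus (nonnegative heights); classification
  heads sigmoid. The `tiny` preset (48 filters, kernel 13, 3 blocks,
  ~27k parameters, 500-bp input) is the test-suite default.

The network core — conv1d (im2col), batch normalization, dense, pooling,
dropout, Adam — is implemented in numpy with exact backpropagation.
Because the backward pass reaches the input tensor, the same machinery
that trains the model provides the input gradients that integrated
gradients needs; finite-difference tests pin both parameter and input
gradients.

### Loss

`cosine_logmse` (regression default): λ·mean(1 − cos(y, ŷ)) per region
plus entrywise mean ((ln(1+y) − ln(1+ŷ))²). The cosine distance is written
as 1 − cos so that lower is always better and the total decomposes as
total = λ·cosine + logmse exactly (asserted in tests). Rows where either
vector has zero norm contribute cosine term 1 with a warning. The dynamic
weight λ = clip(logmse, 0.1, 10), treated as a constant during
backpropagation, is a heuristic that emphasizes profile agreement while
magnitudes are still far off; it is flagged experimental and
configurable. ln(1+·) rather than ln(·) keeps the
log-MSE defined at zero heights. BCE (classification) and Poisson are
standard; cosine-only is available.

### Training

Adam at 10⁻³; LR divided by 4 after 5 epochs without validation
improvement (strict improvement, tolerance 10⁻⁶); early stop after 10;
best-validation weights restored. Default batch 256, fine-tuning batch 64
at a learning rate below the base model's (warned otherwise). Fine-tuning
operates on the regions flagged cell-type-specific and returns a copy, so
base/fine-tuned comparisons stay valid; because the initial weights are
the incumbent "best", the monitored specific-region validation loss can
never end above the base model's. Augmentation shifts the *interval* by a
uniform integer in ±3 bp before fetching (flanking genome enters the
view; chromosome edges pad with N) and reverse-complements with
probability 0.5; targets are unchanged. Training is bit-reproducible for
a fixed seed on a fixed platform.

## Attribution

Integrated gradients use 26 evenly spaced α including both endpoints with
trapezoid weights — with both endpoints in the path, the trapezoid rule is
the natural quadrature and is exact for linear models at any step count;
the scheme is configurable. The default baseline is the
zero (all-N) sequence. Expected IG averages IG maps over 25 baselines
obtained by uniformly permuting the input rows (composition-preserving),
deterministic given the seed. ISM substitutes every position by the three
alternative bases and reports score deltas; reference-base entries are 0
and N/pad positions are skipped with a warning. `summarize_ism` keeps the
signed maximal-magnitude delta per position.

Gene loci are scored by a 2,114-bp window sliding in 100-bp steps anchored
at the locus start, with a final right-anchored window covering any
remainder; each window's scalar prediction is assigned to its full extent
and overlapping positions are averaged. Assigning to the full extent
rather than the central kilobase is a documented choice (configurable in
effect by window/step). Exact-motif ablation replaces every occurrence of
given motif strings (both strands by default; overlaps masked as the span
union) by N runs, producing zero model input at those bases.

## Motif patterns

The pattern pipeline is a deliberately simple, fully specified stand-in
for the TF-MoDISco + Tomtom stack used on large real datasets — similarity
values are therefore in this package's own units (mean per-position
Pearson correlation × √overlap, overlap ≥ 4, both orientations), not
Tomtom −log₁₀ P, and thresholds were calibrated on the synthetic system.

Per contribution map, the per-position score is the attribution projected
on the observed base; spans where the 3-bp-smoothed |score| exceeds
`z_threshold` (default 2) standard deviations of the map's score
distribution become candidates (dilated by half the smoothing window to
undo edge erosion), selected greedily by descending |mean score| without
overlap and clipped to 4–25 bp. Seqlets with identical subsequences are
collapsed into initial patterns (PWM = one-hot frequencies with
pseudocount 10⁻³); shifted and near-identical instances are merged by
clustering: patterns with similarity above `sim_threshold` (default 2.5 ≈
seven perfectly matching columns) form a graph whose connected components
are clusters, represented by the highest-total-information member.
Low-threshold settings allow single-linkage chaining to bridge distinct
motifs through composite (multi-copy) patterns, which the 2.5 default
prevents on the synthetic system. Singleton clusters with mean per-column
information content below 0.2 bits are discarded; flanks below 0.05 bits
are trimmed first. Zero-variance PWM columns contribute correlation 0
rather than NaN.

Per cluster and cell type, importance is sign·ln(1+seqlet count)
(`seqlet_count_log`; plain counts available), the sign being the dominant
contribution sign of the cluster's seqlets in that class, resolved by
majority of summed |contribution| when mixed. The "top-N regions per cell
type" used to select maps ranks regions by the average of target
accessibility and model prediction for that class, optionally restricted
to specificity-flagged regions. TF matching correlates each cluster's
signed importance vector with candidate TFs' expression across cell types
(candidates from a motif→TF annotation table via PWM similarity to a motif
database) and keeps candidates with Pearson r above 0.2, ranked by r;
constant vectors are skipped with a notice.

## Enhancer design

Seed sequences are sampled independently per position from the positional
nucleotide frequencies of user-supplied genomic regions (N excluded from
denominators; all-N positions fall back to uniform). Two objectives share
one candidate-scoring interface with a direction flag:

* weighted difference (maximize): [X_ct(Sᵢ) − X_ct(Sᵢ₋₁)] −
  (1/N)·Σ_bg w_bg·[X_bg(Sᵢ) − X_bg(Sᵢ₋₁)], with N the *total* number of
  classes while the sum runs over the other classes — implemented exactly
  as defined, with `background_norm="n_background"` exposed for the 1/|B|
  variant; weights default to 1.
* L2 target (minimize): √Σ_ct (X_ct − t_ct)², over a chosen class subset.

Each in-silico-evolution iteration scores keep-original plus all 3L
single-base substitutions in one predictor batch against the frozen
predictions of the incoming sequence, and takes the best; ties resolve to
keep-original, then lowest (position, base). Keeping the original among
the candidates guarantees a monotone objective trajectory (recorded as
the L2 distance, or as cumulative gain for the incremental objective).
Motif embedding places user-given TFBS strings sequentially, evaluating
every non-overlapping offset on both strands and keeping the best; order
follows the user's list.

## The synthetic study system

`synth` generates the fixture every recovery test runs on: a 2×100-kb
random genome (GC 0.5), 300 non-overlapping 500-bp peaks, 3 cell types.
70% of peaks are "housekeeping": three copies of a shared GC-box-like
motif (GGGCGGGG), equal motif-driven height in every class. 30% are
cell-type-specific: 2–3 copies of the class's 8-bp motif (GATA-, ETS- and
E-box-like consensi) planted at non-overlapping positions inside the
central 60% of the peak, on either strand. Peak height is
offset_c + 1.0·(copies) + N(0, 0.05) for the owning class and offset_c
alone elsewhere, with small distinct per-class offsets (0.05/0.10/0.15)
emulating residual baseline differences that constitutive scaling must
absorb. Specific peaks a minority, near-closed off-target: this mirrors
real consensus-peak sets (where specific peaks are ~15–20%) and is what
makes Gini-based selection well-posed. A TF-expression table contains one
TF per motif, expressed at 1 in its class (housekeeping TF everywhere)
plus small noise, with a motif→TF annotation table.

The `linear_oracle` is the analytic stand-in for a trained model: class
score = offset_c + Σ over motifs, windows and strands of
(match fraction)²⁴, where the match fraction is linear in the one-hot
input. A purely linear PWM-sum predictor cannot concentrate attribution
on planted instances (every interior position receives identical per-base
weights), and a hard match threshold would leave greedy evolution without
a gradient; the steep power makes random background windows contribute
≈10⁻⁹ while every single-base improvement toward a motif strictly
increases the score, keeps gradients closed-form, and lets a perfect
match contribute exactly one effect unit, so oracle scores track planted
peak heights to ~0.1.

What the fixture does *not* emulate: read-level/fragment noise and Tn5
bias (inputs are already aggregated tracks), realistic genomic sequence
composition beyond GC content, soft motif instances (planting is
consensus-exact), correlated cell types, and batch effects. Passing
recovery tests therefore demonstrates correctness of the machinery —
normalization, selection, training dynamics, attribution, clustering,
design — under a known generative model, not performance on real data.

## Problem sizes and determinism

The test suite and the acceptance script train the tiny preset on the
300-peak fixture (40 epochs, batch 32, ≈4 minutes on one CPU), run design
with 20 seeds × 30 iterations on 200–300-bp sequences, and use 25 top
regions per class for motif recovery; these sizes were chosen so the full
pipeline exercises every stage at desk scale. All randomness flows through
explicit integer seeds (numpy Generator); fixture generation, training and
design are bit-reproducible for a fixed seed on a fixed platform.

## Known limitations

* Batch normalization uses running statistics in inference; extremely
  small training runs may leave them poorly calibrated.
* The pattern pipeline's single-linkage clustering can chain distinct
  motifs at permissive thresholds; average-linkage is not implemented.
* bigWig input is not read directly; convert to bedGraph upstream.
* The dynamic loss weight is a heuristic and remains experimental.
* Multi-label (dual-class) peaks are supported by the matrix
  representation but the default fixture plants single-class peaks only.
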