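# crestkit

Modeling, interpreting and designing cell-type-specific enhancers from
single-cell chromatin accessibility (scATAC-seq) pseudobulk data.

Enhancers drive cell-type-specific transcription through the combination and
arrangement of transcription-factor binding sites (TFBSs) they carry — their
*enhancer code*. Differential chromatin accessibility across cell types is
currently the most reliable genome-wide readout of that code. `crestkit` is a
toolkit for labs that have pseudobulk accessibility tracks over a consensus
peak set and want to (1) train multi-class sequence models that predict
per-cell-type peak heights from DNA sequence alone, (2) explain those
predictions at nucleotide resolution, (3) summarize recurring motifs into
per-cell-type enhancer-code tables matched to candidate TFs, and (4) design
synthetic enhancers with targeted cell-type activity.

## The model

Given a consensus peak set, per-cell-type coverage tracks are CPM-normalized
and aggregated over the central 1,000 bp of each (by default) 2,114-bp
region, giving a regions × cell types target matrix **Y**. Because depth
normalization alone biases against cell types with many peaks, columns are
rescaled by anchoring on *constitutive* peaks — highly accessible regions
(top 1% per cell type by default) with low across-class variability, Gini
index G ≤ μ_G + σ_G where

G(v) = Σᵢⱼ |vᵢ − vⱼ| / (2 n² v̄),

so that after scaling every cell type's constitutive-peak mean coincides.
Cell-type-specific peaks are flagged as G > μ_G + σ_G.

A dilated convolutional network f(x) maps the one-hot sequence x (A,C,G,T
channels; N → zero rows) to one nonnegative score per cell type. The default
regression loss per batch is

L = λ · mean(1 − cos(yᵢ, ŷᵢ)) + mean((ln(1+y) − ln(1+ŷ))²),

the cosine term capturing each region's cell-type *profile* and the log-MSE
its magnitude; λ optionally tracks the current log-MSE (detached, clipped to
[0.1, 10]). Training uses Adam at 10⁻³ with ±3-bp shift and
reverse-complement augmentation, learning-rate decay by 4× after 5 epochs
without validation improvement, early stopping after 10, best-validation
weights restored; a second fine-tuning pass runs on the cell-type-specific
peaks at a lowered learning rate (batch 64).

Predictions are explained by integrated gradients over 26 steps from a zero
baseline (IG_i(x) = (x_i − x'_i)·∫₀¹ ∂f(x'+α(x−x'))/∂x_i dα, trapezoid
rule), by expected IG over 25 composition-preserving permutation baselines,
or by in silico saturation mutagenesis. High-attribution seqlets are
clustered into PWM patterns (merged by alignment-maximized column
correlation × √overlap), scored per cell type as sign·ln(1+seqlet count),
and matched to TFs by Pearson correlation (threshold 0.2) between pattern
importance and TF expression across cell types. Enhancers are designed by in
silico evolution — all 3L single-base substitutions per iteration, keeping
the best under either the weighted target-vs-background gain or the
Euclidean distance to a target accessibility vector — or by sequential
optimal motif embedding.

## Worked example

Everything below runs on the built-in synthetic study system: a 2×100-kb
genome with 300 peaks across 3 cell types, class-specific 8-bp motifs
planted in the specific peaks and a shared motif in housekeeping peaks, and
an analytic oracle model with closed-form gradients.

```python
import numpy as np
from crestkit import synth, preprocessing as prep, interpretation, design

fx = synth.make_fixture(synth.SyntheticSpec(seed=3))

m = prep.compute_peak_matrix(fx.tracks, fx.regions, agg="mean", center_window=300)
prep.annotate_gini(m)
factors, _ = prep.constitutive_scaling_factors(m, prep.NormalizationConfig(top_frac=0.1))
m = prep.apply_scaling(m, factors)
flags = prep.select_specific_regions(m)
print("scaling factors:", np.round(factors, 4))
print("cell-type-specific peaks:", int(flags.sum()))
```

```
scaling factors: [1.0173 0.9985 0.9847]
cell-type-specific peaks: 90
```

The factors sit near 1 (the classes differ only by small baseline offsets)
and Gini selection recovers exactly the 90 planted specific peaks.
Attribution on a specific peak concentrates on the planted motif instances:

```python
from crestkit.genomic_io import one_hot_encode

oracle = fx.oracle
peak = next(p for p in fx.truth.peaks if p.kind == "specific")
x = one_hot_encode(fx.genome.fetch(peak.interval.chrom, peak.interval.start, peak.interval.end))
cm = interpretation.integrated_gradients(oracle, x, peak.class_index)
print("top attribution at offset", int(np.argmax(cm.per_position(x))))
print("planted motifs at", [p - peak.interval.start for p, _ in peak.motif_positions])
```

```
top attribution at offset 381
planted motifs at [103, 112, 375]
```

(the top-scoring nucleotide lies inside the planted instance at 375–383).
Thirty iterations of in silico evolution toward the target vector
(5.0, 0.10, 0.15) produce an enhancer predicted active only in ct0:

```python
freqs = design.position_frequencies(fx.genome, fx.regions)[100:400]
seeds = design.generate_seed_sequences(1, freqs, seed=9)
obj = design.DesignObjective("l2", classes=[0, 1, 2],
                             target_vector=np.array([5.0, 0.10, 0.15]))
(trace,) = design.run_ise(oracle, seeds, obj, iterations=30)
print("designed enhancer predictions:", np.round(trace.final.predictions, 2))
```

```
designed enhancer predictions: [5.05 0.1  0.15]
```

The same workflow is available from the shell:

```bash
crestkit simulate --seed 5 --out fix/
crestkit preprocess --peaks fix/peaks.bed --genome fix/genome.fa --tracks manifest.tsv \
    --width 500 --center 300 --split-mode fraction --seed 7 --out prep
crestkit train --matrix prep --genome fix/genome.fa --input-length 500 --seed 7 --out model.npz
crestkit finetune --model model.npz --matrix prep --genome fix/genome.fa --lr 1e-6 --out model_ft.npz
crestkit contribute --model model_ft.npz --genome fix/genome.fa --bed few.bed --class ct0 --out maps.npz
crestkit patterns --contribs ct0=maps.npz --genome fix/genome.fa --out pats
crestkit design --model model_ft.npz --genome fix/genome.fa --bed fix/peaks.bed \
    --objective l2 --target-json targets.json --n-seeds 200 --iterations 30 --out designs
```

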