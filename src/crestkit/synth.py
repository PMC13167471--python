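"""Self-contained synthetic fixtures with known ground truth.

Emulates the statistical structure of pseudobulk scATAC-seq data that the
rest of the package consumes: a small multi-chromosome genome; consensus
peaks; per-cell-type coverage tracks in which peak height is a monotone
function of planted class-specific motif content plus a class baseline
offset and Gaussian noise; shared "housekeeping" peaks (equal motif-driven
signal in every class) that exercise constitutive-peak normalization; and a
TF-expression table in which one synthetic TF per motif is expressed in its
class. Everything is deterministic given the spec seed.

The ``motif_response_oracle`` is an analytic stand-in for a trained model:
its class score is the class baseline plus a steep power of the PWM match
fraction of each planted motif, summed over all sequence windows on both
strands. Gradients are closed-form, so attribution,
design and motif-recovery pipelines can be validated against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import (
    BASES,
    CoverageTrack,
    GenomeSequence,
    GenomicInterval,
    one_hot_encode,
    reverse_complement,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "Fixture",
    "make_genome",
    "plant_peaks_and_tracks",
    "linear_oracle",
    "MotifResponseOracle",
    "expression_table",
    "make_fixture",
]

DEFAULT_CLASS_MOTIFS = ("GATAAGGC", "CCGGAAGT", "CACCTGTT")
DEFAULT_HOUSEKEEPING_MOTIF = "GGGCGGGG"


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study system.

    Defaults are the "tiny" fixture: 2 chromosomes x 100 kb, 3 cell types,
    300 peaks of 500 bp with 8-bp motifs, peak height = offset + 1.0 per
    planted motif copy with noise s.d. 0.05. As in real consensus-peak
    sets, cell-type-specific peaks are a minority (30%) and are nearly
    closed in off-target classes (baseline offsets are small relative to
    motif-driven signal).
    """

    seed: int
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_classes: int = 3
    n_peaks: int = 300
    peak_width: int = 500
    class_motifs: tuple[str, ...] = DEFAULT_CLASS_MOTIFS
    housekeeping_motif: str = DEFAULT_HOUSEKEEPING_MOTIF
    motifs_per_peak: tuple[int, int] = (2, 3)  # inclusive range
    housekeeping_motifs: int = 3
    housekeeping_frac: float = 0.7
    baseline_offsets: tuple[float, ...] = (0.05, 0.10, 0.15)
    motif_effect: float = 1.0
    noise_sd: float = 0.05
    gc_content: float = 0.5
    central_frac: float = 0.6  # motifs planted inside this central fraction
    expression_noise_sd: float = 0.02
    off_class_expression: float = 0.05

    def __post_init__(self) -> None:
        if len(self.class_motifs) < self.n_classes:
            raise ValueError("need one motif per class")
        if len(self.baseline_offsets) < self.n_classes:
            raise ValueError("need one baseline offset per class")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def class_names(self) -> list[str]:
        return [f"ct{i}" for i in range(self.n_classes)]

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class PlantedPeak:
    index: int
    interval: GenomicInterval
    kind: str  # "specific" | "housekeeping"
    class_index: int | None
    n_motifs: int
    motif_positions: list[tuple[int, str]]  # (genomic start, strand)
    signal: np.ndarray  # noise-free per-class signal


@dataclass
class GroundTruth:
    spec: SyntheticSpec
    peaks: list[PlantedPeak] = field(default_factory=list)

    @property
    def class_names(self) -> list[str]:
        return self.spec.class_names

    def specific_mask(self) -> np.ndarray:
        return np.array([p.kind == "specific" for p in self.peaks])

    def class_labels(self) -> np.ndarray:
        return np.array([-1 if p.class_index is None else p.class_index for p in self.peaks])

    def motif_pwm(self, class_index: int | None = None) -> np.ndarray:
        """One-hot PWM (rows sum to 1) of a planted consensus motif."""
        motif = (self.spec.housekeeping_motif if class_index is None
                 else self.spec.class_motifs[class_index])
        return one_hot_encode(motif)


def make_genome(spec: SyntheticSpec) -> tuple[GenomeSequence, GroundTruth]:
    """Random background genome at the requested GC content."""
    rng = np.random.default_rng(spec.seed)
    at = (1.0 - spec.gc_content) / 2
    gc = spec.gc_content / 2
    probs = [at, gc, gc, at]
    chroms = {}
    for name in spec.chrom_names:
        idx = rng.choice(4, size=spec.chrom_length, p=probs)
        chroms[name] = "".join(BASES[i] for i in idx)
    return GenomeSequence(chroms), GroundTruth(spec=spec)


def _plant_motif(chroms: dict[str, list[str]], chrom: str, pos: int, motif: str) -> None:
    seq = chroms[chrom]
    for i, ch in enumerate(motif):
        seq[pos + i] = ch


def plant_peaks_and_tracks(
    genome: GenomeSequence, spec: SyntheticSpec, truth: GroundTruth | None = None
) -> tuple[list[GenomicInterval], list[CoverageTrack], GroundTruth]:
    """Place peaks, plant motifs into the genome, emit per-class tracks.

    The genome is modified in place (motif instances overwrite background).
    Coverage is piecewise-constant over each peak: for the peak's class,
    offset + motif_effect * (number of planted copies) + noise; for other
    classes, offset + noise. Housekeeping peaks carry the shared motif and
    the same motif-driven height in every class.
    """
    truth = truth or GroundTruth(spec=spec)
    rng = np.random.default_rng(spec.seed + 1)
    n_per = spec.n_peaks // spec.n_chroms
    counts = [n_per] * spec.n_chroms
    counts[-1] += spec.n_peaks - n_per * spec.n_chroms
    slot_ok = all(spec.chrom_length // c >= spec.peak_width for c in counts if c)
    if not slot_ok:
        raise ValueError("peaks do not fit the chromosomes without overlap")

    # peak kinds: housekeeping + round-robin class assignment, shuffled
    n_hk = int(round(spec.housekeeping_frac * spec.n_peaks))
    kinds: list[int | None] = [None] * n_hk + [
        i % spec.n_classes for i in range(spec.n_peaks - n_hk)
    ]
    rng.shuffle(kinds)

    chrom_seqs = {name: list(genome._chroms[name]) for name in spec.chrom_names}
    regions: list[GenomicInterval] = []
    kmin, kmax = spec.motifs_per_peak
    peak_idx = 0
    for chrom, n_here in zip(spec.chrom_names, counts):
        slot = spec.chrom_length // max(n_here, 1)
        for j in range(n_here):
            jitter_max = slot - spec.peak_width
            start = j * slot + (int(rng.integers(0, jitter_max + 1)) if jitter_max > 0 else 0)
            iv = GenomicInterval(chrom, start, start + spec.peak_width, name=f"peak{peak_idx}")
            regions.append(iv)

            class_index = kinds[peak_idx]
            if class_index is None:
                motif = spec.housekeeping_motif
                k = spec.housekeeping_motifs
            else:
                motif = spec.class_motifs[class_index]
                k = int(rng.integers(kmin, kmax + 1))
            klen = len(motif)
            cw = int(spec.peak_width * spec.central_frac)
            lo = iv.center - cw // 2
            hi = iv.center + cw // 2 - klen
            placed: list[tuple[int, str]] = []
            attempts = 0
            while len(placed) < k:
                attempts += 1
                if attempts > 1000:
                    raise ValueError("infeasible motif packing inside the central window")
                pos = int(rng.integers(lo, hi + 1))
                if any(abs(pos - q) < klen for q, _ in placed):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                inst = motif if strand == "+" else _revcomp_str(motif)
                _plant_motif(chrom_seqs, chrom, pos, inst)
                placed.append((pos, strand))

            signal = np.array(spec.baseline_offsets[: spec.n_classes], dtype=np.float64)
            if class_index is None:
                signal = signal + spec.motif_effect * k
            else:
                signal[class_index] += spec.motif_effect * k
            truth.peaks.append(
                PlantedPeak(peak_idx, iv, "housekeeping" if class_index is None else "specific",
                            class_index, k, sorted(placed), signal)
            )
            peak_idx += 1

    genome._chroms.update({name: "".join(seq) for name, seq in chrom_seqs.items()})

    tracks = []
    for c, cname in enumerate(spec.class_names):
        entries = []
        for peak in truth.peaks:
            value = peak.signal[c] + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0)
            iv = peak.interval
            entries.append((iv.chrom, iv.start, iv.end, max(value, 0.0)))
        tracks.append(CoverageTrack.from_intervals(entries, class_label=cname))
    return regions, tracks, truth


def _revcomp_str(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


class MotifResponseOracle:
    """Analytic predictor with planted-motif responses and exact gradients.

    score_c(x) = offset_c + sum_m w_cm * effect * sum_{windows, strands}
                 match_fraction^power

    where match_fraction is the per-window agreement with motif m's
    consensus; a perfect match on one strand contributes exactly
    ``effect``. The steep power (24 by default) makes random background
    windows contribute almost nothing while every single-base improvement
    toward a motif strictly increases the score, so greedy evolution can
    climb. Per-window terms are linear in the one-hot input inside the
    power nonlinearity; gradients are closed-form and attribution mass
    concentrates on planted motif instances.
    """

    def __init__(self, motif_strings: list[str], weights: np.ndarray,
                 offsets: np.ndarray, class_names: list[str],
                 effect: float = 1.0, power: int = 24):
        self.motifs = [one_hot_encode(m) for m in motif_strings]
        self.motifs_rc = [reverse_complement(m) for m in self.motifs]
        self.weights = np.asarray(weights, dtype=np.float64)  # [n_motifs, n_classes]
        self.offsets = np.asarray(offsets, dtype=np.float64)
        self.class_names = list(class_names)
        self.effect = effect
        self.power = power
        self.input_length = None  # any length >= motif length

    def _window_scores(self, xb: np.ndarray, M: np.ndarray) -> np.ndarray:
        K = M.shape[0]
        nw = xb.shape[1] - K + 1
        if np.all(M.max(axis=1) == 1.0):  # consensus (one-hot) fast path
            bases = np.argmax(M, axis=1)
            mu = np.zeros((xb.shape[0], nw))
            for j in range(K):
                mu += xb[:, j : j + nw, bases[j]]
            return mu / K
        win = np.lib.stride_tricks.sliding_window_view(xb, K, axis=1)  # [B, nw, 4, K]
        return np.einsum("bnck,kc->bn", win, M, optimize=True) / K

    def _responses(self, xb: np.ndarray):
        """Per-motif responses and caches for the gradient."""
        out = []
        for M, Mrc in zip(self.motifs, self.motifs_rc):
            resp = 0.0
            caches = []
            for mat in (M, Mrc):
                mu = self._window_scores(xb, mat)
                resp = resp + (mu**self.power).sum(axis=1) * self.effect
                caches.append((mat, mu))
            out.append((resp, caches))
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        xb, squeeze = _as_batch(x)
        responses = self._responses(xb)
        scores = np.tile(self.offsets, (len(xb), 1))
        for m, (resp, _) in enumerate(responses):
            scores += resp[:, None] * self.weights[m][None, :]
        return scores[0] if squeeze else scores

    def input_gradient(self, x: np.ndarray, class_index: int) -> np.ndarray:
        xb, squeeze = _as_batch(x)
        B, L, _ = xb.shape
        grad = np.zeros_like(xb)
        responses = self._responses(xb)
        for m, (_, caches) in enumerate(responses):
            w = self.weights[m, class_index]
            if w == 0:
                continue
            for mat, mu in caches:
                K = mat.shape[0]
                coef = w * self.effect * self.power * mu ** (self.power - 1) / K
                nw = coef.shape[1]
                for j in range(K):
                    grad[:, j : j + nw, :] += coef[:, :, None] * mat[j][None, None, :]
        return grad[0] if squeeze else grad


def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        return x[None], True
    return x, False


def linear_oracle(spec: SyntheticSpec, include_housekeeping: bool = True) -> MotifResponseOracle:
    """Oracle predictor matched to the spec's planted motifs and offsets."""
    motif_strings = list(spec.class_motifs[: spec.n_classes])
    weights = np.eye(spec.n_classes)
    if include_housekeeping:
        motif_strings.append(spec.housekeeping_motif)
        weights = np.vstack([weights, np.ones(spec.n_classes)])
    return MotifResponseOracle(
        motif_strings, weights,
        np.asarray(spec.baseline_offsets[: spec.n_classes]),
        spec.class_names, effect=spec.motif_effect,
    )


def expression_table(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic TF expression (genes x classes) and motif -> TF annotation.

    One TF per class motif, expressed at 1 in its class and near 0
    elsewhere; the housekeeping TF is expressed everywhere.
    """
    rng = np.random.default_rng(spec.seed + 2)
    names = [f"TF_{c}" for c in spec.class_names] + ["TF_hk"]
    expr = np.full((len(names), spec.n_classes), spec.off_class_expression)
    for i in range(spec.n_classes):
        expr[i, i] = 1.0
    expr[-1, :] = 1.0
    if spec.expression_noise_sd > 0:
        expr = np.clip(expr + rng.normal(0, spec.expression_noise_sd, expr.shape), 0, None)
    table = pd.DataFrame(expr, index=names, columns=spec.class_names)
    annotation = pd.DataFrame({
        "motif_id": [f"motif_{c}" for c in spec.class_names] + ["motif_hk"],
        "tf_name": names,
    })
    return table, annotation


@dataclass
class Fixture:
    spec: SyntheticSpec
    genome: GenomeSequence
    regions: list[GenomicInterval]
    tracks: list[CoverageTrack]
    truth: GroundTruth
    expression: pd.DataFrame
    motif_annotation: pd.DataFrame

    @property
    def oracle(self) -> MotifResponseOracle:
        return linear_oracle(self.spec)

    def motif_db(self) -> dict[str, np.ndarray]:
        """Planted consensus PWMs keyed by motif id."""
        db = {f"motif_{c}": one_hot_encode(m)
              for c, m in zip(self.spec.class_names, self.spec.class_motifs)}
        db["motif_hk"] = one_hot_encode(self.spec.housekeeping_motif)
        return db


def make_fixture(spec: SyntheticSpec | None = None, seed: int | None = None) -> Fixture:
    """Generate the full fixture (genome, peaks, tracks, expression, truth)."""
    if spec is None:
        if seed is None:
            raise ValueError("provide a spec or a seed")
        spec = SyntheticSpec(seed=seed)
    genome, truth = make_genome(spec)
    regions, tracks, truth = plant_peaks_and_tracks(genome, spec, truth)
    expr, annot = expression_table(spec)
    return Fixture(spec, genome, regions, tracks, truth, expr, annot)
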