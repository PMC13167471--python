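"""Synthetic enhancer design by in silico evolution and motif embedding.

Seed sequences are sampled from the position-dependent nucleotide
frequencies of genomic regions (matching their positional GC structure),
then optimized against a Predictor under one of two objectives:

* weighted difference (maximize): the gain in the target-class score minus
  the weighted mean gain over the background classes,
  [X_ct(S_i) - X_ct(S_{i-1})] - (1/N) * sum_bg w_bg [X_bg(S_i) - X_bg(S_{i-1})],
  where N is the total number of classes and the sum runs over the other
  classes B;
* L2 target (minimize): the Euclidean distance between the predicted
  class vector and a user-specified target vector over classes of
  interest, sqrt(sum_ct (X_ct - t_ct)^2).

In silico evolution (ISE) evaluates all 3L single-base substitutions plus
keeping the sequence unchanged each iteration, so the objective trajectory
never worsens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np

from .genomic_io import (
    BASES,
    GenomeSequence,
    GenomicInterval,
    one_hot_encode,
    reverse_complement_str,
)

__all__ = [
    "DesignObjective",
    "DesignTrace",
    "position_frequencies",
    "generate_seed_sequences",
    "objective_weighted_diff",
    "objective_l2",
    "ise_step",
    "run_ise",
    "motif_embedding",
]


@dataclass
class DesignObjective:
    """Scoring rule for candidate sequences.

    ``weighted_diff`` maximizes the incremental target-vs-background gain
    (Eq. above); ``l2`` minimizes the distance to ``target_vector`` over
    ``classes`` (indices into the predictor's class list; all classes by
    default). ``background_weights`` maps class index -> weight (default 1
    for every non-target class).
    """

    kind: str  # "weighted_diff" | "l2"
    target_class: int | None = None
    background_weights: dict[int, float] = field(default_factory=dict)
    classes: Sequence[int] | None = None
    target_vector: np.ndarray | None = None
    background_norm: str = "n_classes"  # "n_classes" (as defined) or "n_background"

    def __post_init__(self) -> None:
        if self.kind not in ("weighted_diff", "l2"):
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.kind == "weighted_diff" and self.target_class is None:
            raise ValueError("weighted_diff requires a target class")
        if self.kind == "l2":
            if self.target_vector is None:
                raise ValueError("l2 requires a target vector")
            self.target_vector = np.asarray(self.target_vector, dtype=np.float64)
            if np.any(self.target_vector < 0):
                raise ValueError("target vector must be nonnegative")

    @property
    def direction(self) -> int:
        """+1 for maximize (weighted_diff), -1 for minimize (l2)."""
        return 1 if self.kind == "weighted_diff" else -1


def objective_weighted_diff(
    pred_new: np.ndarray, pred_old: np.ndarray, obj: DesignObjective
) -> float:
    """Incremental weighted-difference gain; higher is better."""
    pred_new = np.asarray(pred_new, dtype=np.float64)
    pred_old = np.asarray(pred_old, dtype=np.float64)
    if pred_new.shape[-1] != pred_old.shape[-1]:
        raise ValueError("prediction vectors must share classes")
    n = pred_new.shape[-1]
    ct = obj.target_class
    if ct is None or not (0 <= ct < n):
        raise ValueError(f"target class {ct} outside the {n} predicted classes")
    gain = pred_new[..., ct] - pred_old[..., ct]
    bg = [c for c in range(n) if c != ct]
    denom = n if obj.background_norm == "n_classes" else max(len(bg), 1)
    bg_term = sum(
        obj.background_weights.get(c, 1.0) * (pred_new[..., c] - pred_old[..., c])
        for c in bg
    )
    return gain - bg_term / denom


def objective_l2(pred: np.ndarray, obj: DesignObjective) -> float:
    """Euclidean distance to the target vector; lower is better."""
    pred = np.asarray(pred, dtype=np.float64)
    classes = list(obj.classes) if obj.classes is not None else list(range(pred.shape[-1]))
    t = obj.target_vector
    if t.shape[-1] != len(classes):
        raise ValueError("target vector length must match the classes of interest")
    diff = pred[..., classes] - t
    return np.sqrt((diff**2).sum(axis=-1))


def position_frequencies(
    genome: GenomeSequence, regions: Sequence[GenomicInterval]
) -> np.ndarray:
    """Per-position nucleotide fractions over equal-width regions.

    'N' bases are excluded from the denominators; positions observed only
    as N fall back to the uniform distribution with a warning.
    """
    widths = {iv.width for iv in regions}
    if len(widths) != 1:
        raise ValueError("regions must share a single width")
    L = widths.pop()
    counts = np.zeros((L, 4))
    for iv in regions:
        counts += one_hot_encode(genome.fetch(iv.chrom, iv.start, iv.end))
    totals = counts.sum(axis=1, keepdims=True)
    empty = totals[:, 0] == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} positions observed only as N; uniform fallback")
        counts[empty] = 0.25
        totals[empty] = 1.0
    return counts / totals


def generate_seed_sequences(n: int, freqs: np.ndarray, seed: int = 0) -> list[str]:
    """Sample sequences from a position-dependent nucleotide distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    freqs = np.asarray(freqs, dtype=np.float64)
    rng = np.random.default_rng(seed)
    L = freqs.shape[0]
    cum = np.cumsum(freqs, axis=1)
    cum /= cum[:, -1:]
    out = []
    for _ in range(n):
        u = rng.random(L)
        idx = (u[:, None] > cum).sum(axis=1)
        out.append("".join(BASES[i] for i in idx))
    return out


def _predict_seq_batch(p, seqs_onehot: np.ndarray) -> np.ndarray:
    if p.input_length is not None and seqs_onehot.shape[1] != p.input_length:
        pad = p.input_length - seqs_onehot.shape[1]
        if pad < 0:
            raise ValueError("sequence longer than the model input; crop first")
        left = pad // 2
        padded = np.zeros((seqs_onehot.shape[0], p.input_length, 4))
        padded[:, left : left + seqs_onehot.shape[1], :] = seqs_onehot
        seqs_onehot = padded
    return np.atleast_2d(p.predict(seqs_onehot))


@dataclass
class TraceEntry:
    iteration: int
    sequence: str
    objective: float
    predictions: np.ndarray
    mutation: tuple[int, str] | None = None  # (position, new base)


@dataclass
class DesignTrace:
    entries: list[TraceEntry] = field(default_factory=list)

    @property
    def objectives(self) -> np.ndarray:
        return np.array([e.objective for e in self.entries])

    @property
    def final(self) -> TraceEntry:
        return self.entries[-1]


def _candidate_batch(x0: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int] | None]]:
    """Keep-original plus all 3L single-base substitutions, in scan order."""
    L = x0.shape[0]
    muts: list[tuple[int, int] | None] = [None]
    batch = [x0]
    for i in range(L):
        ref = int(np.argmax(x0[i]))
        for b in range(4):
            if b == ref:
                continue
            m = x0.copy()
            m[i] = 0.0
            m[i, b] = 1.0
            batch.append(m)
            muts.append((i, b))
    return np.stack(batch), muts


def ise_step(
    p, s: str, obj: DesignObjective, prev_pred: np.ndarray | None = None
) -> tuple[str, TraceEntry]:
    """One evolution step: best of keep-original and all 3L substitutions.

    Candidates are scored against the frozen predictions of the incoming
    sequence (for the incremental objective); ties resolve to keep-original
    first, then to the lowest (position, base) in scan order.
    """
    x0 = one_hot_encode(s)
    if prev_pred is None:
        prev_pred = _predict_seq_batch(p, x0[None])[0]
    batch, muts = _candidate_batch(x0)
    preds = _predict_seq_batch(p, batch)
    if obj.kind == "weighted_diff":
        scores = objective_weighted_diff(preds, prev_pred, obj)
        best = int(np.argmax(scores))
    else:
        scores = objective_l2(preds, obj)
        best = int(np.argmin(scores))
    mut = muts[best]
    if mut is None:
        new_s = s
        mutation = None
    else:
        i, b = mut
        new_s = s[:i] + BASES[b] + s[i + 1 :]
        mutation = (i, BASES[b])
    entry = TraceEntry(-1, new_s, float(scores[best]), preds[best], mutation)
    return new_s, entry


def run_ise(
    p, seeds: Sequence[str], obj: DesignObjective, iterations: int = 30
) -> list[DesignTrace]:
    """Iterated ISE per seed; the recorded objective never worsens.

    For the L2 objective the recorded value is the distance itself
    (non-increasing); for the weighted difference it is the cumulative gain
    relative to the seed (non-decreasing).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    traces = []
    for seed_seq in seeds:
        x0 = one_hot_encode(seed_seq)
        pred0 = _predict_seq_batch(p, x0[None])[0]
        if obj.kind == "l2":
            start_obj = float(objective_l2(pred0, obj))
        else:
            start_obj = 0.0
        trace = DesignTrace([TraceEntry(0, seed_seq, start_obj, pred0, None)])
        s = seed_seq
        prev_pred = pred0
        running = start_obj
        for it in range(1, iterations + 1):
            s, entry = ise_step(p, s, obj, prev_pred=prev_pred)
            if obj.kind == "weighted_diff":
                running += entry.objective  # per-step gain, >= 0 via keep-original
                entry = TraceEntry(it, entry.sequence, running, entry.predictions,
                                   entry.mutation)
            else:
                entry.iteration = it
            prev_pred = entry.predictions
            trace.entries.append(entry)
        traces.append(trace)
    return traces


def motif_embedding(
    p, seed_seq: str, motifs: Sequence[str], obj: DesignObjective
) -> tuple[str, list[tuple[int, str, str]]]:
    """Sequentially place fixed TFBS strings at their optimal offsets.

    Motifs are placed in the given order; for each, every offset on either
    strand that does not overlap a previously placed motif is evaluated
    under the objective and the best is chosen. Returns the final sequence
    and placements as (offset, strand, motif) tuples.
    """
    s = seed_seq
    occupied: list[tuple[int, int]] = []
    placements: list[tuple[int, str, str]] = []
    for motif in motifs:
        k = len(motif)
        candidates = []
        for strand, inst in (("+", motif), ("-", reverse_complement_str(motif))):
            for off in range(0, len(s) - k + 1):
                if any(off < e and off + k > a for a, e in occupied):
                    continue
                candidates.append((off, strand, s[:off] + inst + s[off + k :]))
        if not candidates:
            raise ValueError(f"no legal placement for motif {motif!r}")
        batch = np.stack([one_hot_encode(c[2]) for c in candidates])
        preds = _predict_seq_batch(p, batch)
        if obj.kind == "weighted_diff":
            prev = _predict_seq_batch(p, one_hot_encode(s)[None])[0]
            scores = objective_weighted_diff(preds, prev, obj)
            best = int(np.argmax(scores))
        else:
            scores = objective_l2(preds, obj)
            best = int(np.argmin(scores))
        off, strand, new_s = candidates[best]
        s = new_s
        occupied.append((off, off + k))
        placements.append((off, strand, motif))
    return s, placements
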