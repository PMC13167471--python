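"""Seqlet extraction, pattern clustering and TF matching.

From per-nucleotide contribution maps, short high-|contribution| spans
(seqlets) are called, grouped into recurring patterns (PWMs with signed
per-class importance), merged by PWM similarity into clusters, and finally
matched to candidate transcription factors by correlating each pattern's
class-importance vector with TF expression across cell types.

This is a deliberately simple, fully specified pipeline standing in the
place a TF-MoDISco + Tomtom stack would occupy for large real datasets;
similarity thresholds are therefore in this package's own units
(mean column Pearson x sqrt(overlap)), not Tomtom -log10 P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .genomic_io import one_hot_decode
from .interpretation import ContributionMap

__all__ = [
    "Seqlet",
    "Pattern",
    "PatternCluster",
    "PatternMatrix",
    "extract_seqlets",
    "information_content",
    "pattern_from_seqlets",
    "trim_pattern",
    "pattern_similarity",
    "cluster_patterns",
    "pattern_class_matrix",
    "match_tfs",
    "annotate_pattern_candidates",
    "top_regions_for_class",
    "write_meme",
]

PSEUDOCOUNT = 1e-3


@dataclass
class Seqlet:
    """A short contiguous high-attribution span from one contribution map."""

    region_id: str
    start: int
    end: int
    class_index: int
    mean_contrib: float
    onehot: np.ndarray
    contrib: np.ndarray
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end - self.start < 4:
            raise ValueError("seqlets must span at least 4 bp")
        if self.contrib.shape != self.onehot.shape:
            raise ValueError("contribution submatrix must match the span")

    @property
    def sign(self) -> int:
        return 1 if self.mean_contrib >= 0 else -1

    @property
    def sequence(self) -> str:
        return one_hot_decode(self.onehot)


def extract_seqlets(
    cm: ContributionMap,
    x: np.ndarray,
    region_id: str = "",
    min_len: int = 4,
    max_len: int = 25,
    z_threshold: float = 2.0,
    smooth_window: int = 3,
) -> list[Seqlet]:
    """Call maximal |contribution| runs above a per-map z threshold.

    The per-position score is the contribution projected on the observed
    base; runs where the smoothed |score| exceeds ``z_threshold`` standard
    deviations of the map's score distribution become candidates, selected
    greedily by descending |mean score| without overlap, with spans clipped
    to [min_len, max_len].
    """
    x = np.asarray(x, dtype=np.float64)
    score = cm.per_position(x)
    L = score.size
    sd = score.std()
    if sd == 0:
        return []
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(score, kernel, mode="same")
    above = np.abs(smoothed) > z_threshold * sd

    spans: list[tuple[int, int]] = []
    i = 0
    while i < L:
        if above[i]:
            j = i
            while j < L and above[j]:
                j += 1
            spans.append((i, j))
            i = j
        else:
            i += 1

    candidates: list[tuple[float, int, int]] = []
    halo = smooth_window // 2  # undo edge erosion from smoothing
    for a, b in spans:
        a = max(0, a - halo)
        b = min(L, b + halo)
        if b - a > max_len:
            peak = a + int(np.argmax(np.abs(smoothed[a:b])))
            a = max(0, min(peak - max_len // 2, L - max_len))
            b = a + max_len
        if b - a < min_len:
            grow = min_len - (b - a)
            a = max(0, a - grow // 2)
            b = min(L, a + min_len)
            a = max(0, b - min_len)
        candidates.append((float(np.abs(score[a:b]).mean()), a, b))

    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(L, dtype=bool)
    seqlets = []
    for _, a, b in candidates:
        if taken[a:b].any():
            continue
        taken[a:b] = True
        seqlets.append(
            Seqlet(region_id, a, b, cm.class_index,
                   float(score[a:b].mean()), x[a:b].copy(), cm.values[a:b].copy())
        )
    seqlets.sort(key=lambda s: s.start)
    return seqlets


def information_content(pwm: np.ndarray) -> np.ndarray:
    """Per-position information content in bits: 2 + sum_b p log2 p.

    ``pwm`` has one row per position summing to 1 over the A,C,G,T
    channels; 0 log 0 is taken as 0. Uniform positions score 0 bits,
    deterministic positions 2 bits.
    """
    pwm = np.asarray(pwm, dtype=np.float64)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ValueError("PWM must be K x 4")
    if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("PWM positions must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pwm > 0, pwm * np.log2(pwm), 0.0)
    return 2.0 + plogp.sum(axis=1)


@dataclass
class Pattern:
    """A PWM with its member seqlets and signed per-class importance."""

    pwm: np.ndarray
    seqlets: list[Seqlet] = field(default_factory=list)
    name: str = ""

    @property
    def ic(self) -> np.ndarray:
        return information_content(self.pwm)

    @property
    def total_ic(self) -> float:
        return float(self.ic.sum())

    @property
    def sign(self) -> int:
        if not self.seqlets:
            return 1
        weight = sum(s.sign * abs(s.mean_contrib) for s in self.seqlets)
        return 1 if weight >= 0 else -1

    def class_counts(self, n_classes: int) -> np.ndarray:
        counts = np.zeros(n_classes)
        for s in self.seqlets:
            counts[s.class_index] += 1
        return counts

    def class_sign(self, class_index: int) -> int:
        """Dominant sign among this pattern's seqlets in one class.

        Majority by summed |contribution| of the member seqlets.
        """
        weight = sum(
            s.sign * abs(s.mean_contrib)
            for s in self.seqlets if s.class_index == class_index
        )
        return 1 if weight >= 0 else -1


def pattern_from_seqlets(seqlets: list[Seqlet], name: str = "") -> Pattern:
    """Build a PWM from equal-length seqlets (frequency + pseudocount)."""
    if not seqlets:
        raise ValueError("no seqlets")
    length = min(s.onehot.shape[0] for s in seqlets)
    counts = np.full((length, 4), PSEUDOCOUNT)
    for s in seqlets:
        counts += s.onehot[:length]
    return Pattern(counts / counts.sum(axis=1, keepdims=True), list(seqlets), name=name)


def seqlets_to_patterns(seqlets: list[Seqlet]) -> list[Pattern]:
    """Group seqlets by identical subsequence into initial patterns.

    Near-identical and shifted instances are merged downstream by
    :func:`cluster_patterns`; this grouping only collapses exact repeats.
    """
    by_seq: dict[str, list[Seqlet]] = {}
    for s in seqlets:
        by_seq.setdefault(s.sequence, []).append(s)
    return [
        pattern_from_seqlets(group, name=f"p{i}")
        for i, (_, group) in enumerate(sorted(by_seq.items()))
    ]


def trim_pattern(p: Pattern, trim_ic_threshold: float = 0.05) -> Pattern | None:
    """Strip low-information flanks; returns None if nothing remains."""
    ic = p.ic
    keep = np.flatnonzero(ic >= trim_ic_threshold)
    if keep.size == 0:
        warnings.warn(f"pattern {p.name!r} fully below trim threshold; dropped")
        return None
    a, b = int(keep[0]), int(keep[-1]) + 1
    return Pattern(p.pwm[a:b], p.seqlets, name=p.name)


def _revcomp_pwm(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1, ::-1]


def _standardize_rows(pwm: np.ndarray) -> np.ndarray:
    """Per-position z-scores over the 4 channels; zero-variance rows -> 0.

    With this, the Pearson correlation of two positions is the dot product
    of their z-rows divided by 4 (zero-variance positions scoring 0 by
    convention).
    """
    mean = pwm.mean(axis=1, keepdims=True)
    sd = pwm.std(axis=1, keepdims=True)
    out = np.zeros_like(pwm)
    np.divide(pwm - mean, sd, out=out, where=sd > 0)
    return out


def pattern_similarity(p: Pattern, q: Pattern, min_overlap: int = 4) -> float:
    """Alignment-maximized PWM similarity.

    Max over relative offsets (overlap >= ``min_overlap``) and over q's two
    orientations of (mean per-position Pearson correlation) x sqrt(overlap
    length). Symmetric in its arguments.
    """
    Za = _standardize_rows(np.asarray(p.pwm, dtype=np.float64))
    best = -np.inf
    la = len(Za)
    for Bpwm in (q.pwm, _revcomp_pwm(q.pwm)):
        Zb = _standardize_rows(np.asarray(Bpwm, dtype=np.float64))
        lb = len(Zb)
        # cross-correlate along positions: dots[d] = sum_i Za[i] . Zb[i - off]
        dots = sum(np.correlate(Za[:, c], Zb[:, c], mode="full") for c in range(4))
        # index d in [0, la+lb-2] corresponds to offset off = d - (lb - 1)
        for d in range(la + lb - 1):
            off = d - (lb - 1)
            ov = min(la, off + lb) - max(0, off)
            if ov < min_overlap:
                continue
            val = dots[d] / (4.0 * ov) * np.sqrt(ov)
            if val > best:
                best = float(val)
    return best


@dataclass
class PatternCluster:
    members: list[Pattern]
    representative: Pattern


def cluster_patterns(
    patterns: list[Pattern],
    sim_threshold: float = 2.5,
    discard_ic_threshold: float = 0.2,
) -> list[PatternCluster]:
    """Merge similar patterns into clusters (graph connected components).

    Patterns with pairwise similarity above ``sim_threshold`` share an
    edge; each connected component becomes one cluster represented by its
    highest-total-information member. Singleton clusters whose
    representative's mean per-position information content falls below
    ``discard_ic_threshold`` are discarded.
    """
    n = len(patterns)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if pattern_similarity(patterns[i], patterns[j]) > sim_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[Pattern]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(patterns[i])

    clusters = []
    for members in groups.values():
        rep = max(members, key=lambda p: p.total_ic)
        if len(members) == 1 and float(rep.ic.mean()) < discard_ic_threshold:
            continue
        members = sorted(members, key=lambda p: p.name)
        clusters.append(PatternCluster(members, rep))
    clusters.sort(key=lambda c: c.representative.name)
    return clusters


@dataclass
class PatternMatrix:
    """Clusters x classes signed importance with representative PWMs."""

    values: np.ndarray
    class_names: list[str]
    representatives: list[Pattern]

    def to_frame(self) -> pd.DataFrame:
        idx = [p.name or f"cluster_{i}" for i, p in enumerate(self.representatives)]
        return pd.DataFrame(self.values, index=idx, columns=self.class_names)


def pattern_class_matrix(
    clusters: list[PatternCluster],
    class_names: list[str],
    parameter: str = "seqlet_count_log",
) -> PatternMatrix:
    """Signed importance per (cluster, class) from member seqlet tallies.

    Importance is the seqlet count (``seqlet_count``) or sign * ln(1+count)
    (``seqlet_count_log``); the sign is the dominant contribution sign of
    the cluster's seqlets in that class.
    """
    if parameter not in ("seqlet_count", "seqlet_count_log"):
        raise ValueError(f"unknown pattern parameter {parameter!r}")
    n_classes = len(class_names)
    values = np.zeros((len(clusters), n_classes))
    for k, cluster in enumerate(clusters):
        merged = Pattern(cluster.representative.pwm,
                         [s for p in cluster.members for s in p.seqlets])
        counts = merged.class_counts(n_classes)
        for c in range(n_classes):
            if counts[c] == 0:
                continue
            sign = merged.class_sign(c)
            if parameter == "seqlet_count":
                values[k, c] = sign * counts[c]
            else:
                values[k, c] = sign * np.log1p(counts[c])
    return PatternMatrix(values, list(class_names), [c.representative for c in clusters])


def annotate_pattern_candidates(
    pm: PatternMatrix,
    motif_db: dict[str, np.ndarray],
    annotation: pd.DataFrame,
    min_similarity: float = 1.5,
) -> dict[int, list[str]]:
    """Candidate TFs per cluster via PWM similarity to a motif database.

    ``annotation`` maps motif_id -> tf_name (columns named exactly so).
    """
    tf_of = annotation.set_index("motif_id")["tf_name"]
    out: dict[int, list[str]] = {}
    for k, rep in enumerate(pm.representatives):
        cands = []
        for motif_id, pwm in motif_db.items():
            sim = pattern_similarity(rep, Pattern(np.asarray(pwm)))
            if sim >= min_similarity and motif_id in tf_of.index:
                cands.append((sim, tf_of[motif_id]))
        cands.sort(reverse=True)
        out[k] = [tf for _, tf in cands]
    return out


def match_tfs(
    pm: PatternMatrix,
    expr: pd.DataFrame,
    candidates: dict[int, list[str]],
    r_threshold: float = 0.2,
) -> dict[int, list[tuple[str, float]]]:
    """Correlate pattern importance vectors with TF expression profiles.

    For each cluster and each of its candidate TFs, the Pearson r between
    the cluster's signed importance vector over classes and the TF's expression
    vector is computed; TFs with r above ``r_threshold`` are kept, ranked
    by r. Constant vectors are skipped with a notice.
    """
    expr = expr[pm.class_names]
    results: dict[int, list[tuple[str, float]]] = {}
    for k in range(pm.values.shape[0]):
        importance = pm.values[k]
        kept = []
        for tf in candidates.get(k, []):
            if tf not in expr.index:
                continue
            e = expr.loc[tf].to_numpy(dtype=np.float64)
            if importance.std() == 0 or e.std() == 0:
                warnings.warn(f"constant vector for cluster {k}/{tf}; candidate skipped")
                continue
            r = float(pearsonr(importance, e).statistic)
            if r > r_threshold:
                kept.append((tf, r))
        kept.sort(key=lambda t: -t[1])
        results[k] = kept
    return results


def top_regions_for_class(
    values: np.ndarray,
    predictions: np.ndarray,
    class_index: int,
    n: int,
    specific_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of the top-n regions for one class.

    Regions are ranked by the average of target accessibility and model
    prediction score for the class, optionally restricted to regions
    flagged as cell-type specific.
    """
    score = 0.5 * (values[:, class_index] + predictions[:, class_index])
    if specific_mask is not None:
        score = np.where(specific_mask, score, -np.inf)
    order = np.argsort(-score)
    return order[:n]


def write_meme(pm: PatternMatrix, path: str) -> None:
    """Export representative PWMs in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for i, rep in enumerate(pm.representatives):
            name = rep.name or f"cluster_{i}"
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(rep.pwm)}\n")
            for row in rep.pwm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
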