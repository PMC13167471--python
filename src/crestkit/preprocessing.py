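"""Build, normalize, annotate and split the regions x classes target matrix.

The target of a multi-class accessibility model is a matrix of peak heights:
one row per consensus peak, one column per cell type (class). Raw pseudobulk
tracks differ in sequencing depth and global signal distribution, so columns
are aligned in two steps: CPM depth normalization of each track, then a
min-max-style rescaling anchored on *constitutive* peaks — highly accessible
regions with low across-class variability (low Gini index), whose true
accessibility can be assumed equal across cell types.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, GenomeSequence, GenomicInterval

__all__ = [
    "PeakMatrix",
    "NormalizationConfig",
    "TopicMatrix",
    "resize_regions",
    "compute_peak_matrix",
    "cpm_normalize",
    "gini_index",
    "constitutive_scaling_factors",
    "apply_scaling",
    "select_specific_regions",
    "split_regions",
    "binarize_otsu",
]


@dataclass
class PeakMatrix:
    """Regions x classes accessibility targets with per-region annotations.

    ``obs`` carries one row per region; recognised columns are ``gini``,
    ``split`` (train/val/test) and ``specific`` (cell-type-specific flag).
    """

    values: np.ndarray
    regions: list[GenomicInterval]
    class_names: list[str]
    obs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (regions x classes)")
        if self.values.shape != (len(self.regions), len(self.class_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.regions)} regions x {len(self.class_names)} classes"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("values must be finite and nonnegative")
        if self.obs.empty:
            self.obs = pd.DataFrame(index=range(len(self.regions)))
        elif len(self.obs) != len(self.regions):
            raise ValueError("one obs row per region required")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def split_mask(self, split: str) -> np.ndarray:
        if "split" not in self.obs:
            raise ValueError("regions are not split; call split_regions first")
        return (self.obs["split"] == split).to_numpy()

    def subset(self, mask: np.ndarray) -> "PeakMatrix":
        idx = np.flatnonzero(mask)
        return PeakMatrix(
            values=self.values[idx],
            regions=[self.regions[i] for i in idx],
            class_names=list(self.class_names),
            obs=self.obs.iloc[idx].reset_index(drop=True),
        )

    def to_anndata(self):
        """Export as an AnnData object (regions as obs, classes as var)."""
        import anndata as ad

        obs = self.obs.copy()
        obs.index = [str(iv) for iv in self.regions]
        obs["chrom"] = [iv.chrom for iv in self.regions]
        obs["start"] = [iv.start for iv in self.regions]
        obs["end"] = [iv.end for iv in self.regions]
        return ad.AnnData(X=self.values.copy(), obs=obs, var=pd.DataFrame(index=self.class_names))

    def save(self, prefix: str) -> None:
        """Serialize as TSV (values) plus a JSON sidecar (coords, metadata)."""
        df = pd.DataFrame(self.values, columns=self.class_names)
        df.to_csv(prefix + ".tsv", sep="\t", index=False, float_format="%.8g")
        side = {
            "class_names": self.class_names,
            "regions": [[iv.chrom, iv.start, iv.end, iv.name] for iv in self.regions],
            "obs": {c: self.obs[c].tolist() for c in self.obs.columns},
        }
        with open(prefix + ".json", "w") as fh:
            json.dump(side, fh)

    @classmethod
    def load(cls, prefix: str) -> "PeakMatrix":
        df = pd.read_csv(prefix + ".tsv", sep="\t")
        with open(prefix + ".json") as fh:
            side = json.load(fh)
        regions = [GenomicInterval(c, s, e, name=n) for c, s, e, n in side["regions"]]
        obs = pd.DataFrame(side.get("obs", {}), index=range(len(regions)))
        return cls(df.to_numpy(), regions, side["class_names"], obs)


def default_gini_rule(gini: np.ndarray) -> np.ndarray:
    """Constitutive filter: Gini at or below mean + 1 s.d. over all peaks.

    Inclusive comparison so that degenerate inputs (all regions equally
    nonspecific, s.d. 0) still yield a constitutive set.
    """
    return gini <= gini.mean() + gini.std()


@dataclass
class NormalizationConfig:
    """Constitutive-peak scaling configuration.

    top_frac
        Fraction of most accessible peaks per class considered as
        constitutive candidates (0.01 by default).
    gini_rule
        Predicate over the per-region Gini vector selecting low-variability
        regions among the candidates.
    reference
        Anchor for the common scale: ``"mean"`` (mean of per-class
        constitutive means, default) or ``"max"``.
    """

    top_frac: float = 0.01
    gini_rule: Callable[[np.ndarray], np.ndarray] = default_gini_rule
    reference: str = "mean"

    def __post_init__(self) -> None:
        if not (0 < self.top_frac <= 1):
            raise ValueError("top_frac must be in (0, 1]")


@dataclass
class TopicMatrix:
    """Regions x topics probabilities, optionally with a binarized mask."""

    probs: np.ndarray
    regions: list[GenomicInterval]
    topic_names: list[str]
    mask: np.ndarray | None = None
    obs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("topic probabilities must lie in [0, 1]")
        if self.mask is not None and self.mask.shape != self.probs.shape:
            raise ValueError("mask shape must match probabilities")
        if self.obs.empty:
            self.obs = pd.DataFrame(index=range(len(self.regions)))


def resize_regions(
    regions: Sequence[GenomicInterval], width: int, genome: GenomeSequence
) -> list[GenomicInterval]:
    """Re-center each region to ``width`` bp, staying within its chromosome.

    Regions that would overhang a chromosome end are shifted minimally to
    fit; if the chromosome itself is shorter than ``width`` the region spans
    the whole chromosome (flagged via the name suffix ``|short``).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    lengths = genome.chrom_lengths
    out = []
    for iv in regions:
        clen = lengths[iv.chrom]
        if clen < width:
            out.append(replace(iv, start=0, end=clen, name=(iv.name or "") + "|short"))
            continue
        start = iv.center - width // 2
        start = min(max(start, 0), clen - width)
        out.append(replace(iv, start=start, end=start + width))
    return out


def compute_peak_matrix(
    tracks: Sequence[CoverageTrack],
    regions: Sequence[GenomicInterval],
    agg: str = "mean",
    center_window: int = 1000,
) -> PeakMatrix:
    """Aggregate coverage per class over the central window of each region.

    Default window of 1,000 bp reflects that peak height is computed from
    the region center while the model sees the full (wider) sequence.
    """
    if agg not in ("max", "mean", "sum", "logsum"):
        raise ValueError(f"unknown aggregation {agg!r}")
    for iv in regions:
        if center_window > iv.width:
            raise ValueError(
                f"center_window {center_window} exceeds region width {iv.width} ({iv})"
            )
    values = np.zeros((len(regions), len(tracks)))
    for ci, track in enumerate(tracks):
        for ri, iv in enumerate(regions):
            mid = iv.center
            s = mid - center_window // 2
            e = s + center_window
            values[ri, ci] = track.aggregate(iv.chrom, s, e, how=agg)
    class_names = [t.class_label or f"class_{i}" for i, t in enumerate(tracks)]
    return PeakMatrix(values, list(regions), class_names)


def cpm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Scale a track to counts-per-million of its genome-wide total."""
    total = track.total()
    if total <= 0:
        raise ValueError("cannot CPM-normalize an all-zero track")
    return track.scale(1e6 / total)


def gini_index(v: np.ndarray) -> float:
    """Gini index of a nonnegative vector.

    G = sum_ij |v_i - v_j| / (2 n^2 mean(v)); 0 for perfectly even vectors,
    approaching (n-1)/n when one entry holds all the mass. Scale-invariant.
    An all-zero vector carries no specificity signal and scores 0.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if np.any(v < 0):
        raise ValueError("Gini index requires nonnegative values")
    total = v.sum()
    if total == 0:
        warnings.warn("all-zero vector; Gini defined as 0", stacklevel=2)
        return 0.0
    n = v.size
    vs = np.sort(v)
    # sorted-rank identity for the mean absolute difference
    coef = 2 * np.arange(1, n + 1) - n - 1
    return float((coef * vs).sum() / (n * total))


def constitutive_scaling_factors(
    m: PeakMatrix, cfg: NormalizationConfig | None = None
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-class scaling factors anchored on constitutive peaks.

    For each class the candidates are its ``top_frac`` most accessible
    regions (ties at the quantile boundary included); constitutive peaks are
    the candidates passing the Gini rule. The factor for class c is
    reference / mean(constitutive values of c), so that after scaling every
    class's constitutive mean equals the common reference.

    Returns (factors, constitutive index arrays per class).
    """
    cfg = cfg or NormalizationConfig()
    n_regions, n_classes = m.values.shape
    if n_regions == 0:
        raise ValueError("empty matrix")
    gini = (
        m.obs["gini"].to_numpy()
        if "gini" in m.obs
        else np.array([gini_index(row) for row in m.values])
    )
    passes = cfg.gini_rule(gini)
    n_top = max(1, int(np.ceil(cfg.top_frac * n_regions)))
    const_sets: list[np.ndarray] = []
    means = np.empty(n_classes)
    for c in range(n_classes):
        col = m.values[:, c]
        cutoff = np.sort(col)[::-1][n_top - 1]
        candidates = np.flatnonzero(col >= cutoff)  # ties included
        const = candidates[passes[candidates]]
        if const.size == 0:
            raise ValueError(
                f"no constitutive peaks for class {m.class_names[c]!r}; "
                "loosen the Gini rule or raise top_frac"
            )
        const_sets.append(const)
        means[c] = m.values[const, c].mean()
    reference = means.mean() if cfg.reference == "mean" else means.max()
    factors = reference / means
    return factors, const_sets


def apply_scaling(m: PeakMatrix, factors: np.ndarray) -> PeakMatrix:
    """Multiply each class column by its factor; annotations are preserved."""
    factors = np.asarray(factors, dtype=np.float64)
    if factors.shape != (len(m.class_names),):
        raise ValueError("one factor per class required")
    if np.any(factors <= 0) or not np.all(np.isfinite(factors)):
        raise ValueError("factors must be finite and positive")
    return PeakMatrix(m.values * factors[None, :], list(m.regions), list(m.class_names), m.obs.copy())


def annotate_gini(m: PeakMatrix) -> PeakMatrix:
    """Compute and store the per-region Gini index across classes."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m.obs["gini"] = [gini_index(row) for row in m.values]
    return m


def select_specific_regions(m: PeakMatrix) -> np.ndarray:
    """Flag cell-type-specific regions: Gini above mean + 1 s.d.

    Stores the boolean flag in ``obs['specific']`` and returns it.
    """
    if "gini" not in m.obs:
        annotate_gini(m)
    g = m.obs["gini"].to_numpy()
    flags = g > g.mean() + g.std()
    m.obs["specific"] = flags
    return flags


def split_regions(
    m: PeakMatrix,
    mode: str = "chromosome",
    val: Sequence[str] | float = ("chr8", "chr10"),
    test: Sequence[str] | float = ("chr9", "chr18"),
    seed: int = 0,
) -> PeakMatrix:
    """Assign regions to train/validation/test splits.

    ``chromosome`` mode holds out whole chromosomes (``val``/``test`` are
    chromosome name lists); ``fraction`` mode shuffles regions with the
    given seed (``val``/``test`` are fractions; the remainder trains).
    """
    n = m.n_regions
    split = np.array(["train"] * n, dtype=object)
    if mode == "chromosome":
        val_set, test_set = set(val), set(test)
        if val_set & test_set:
            raise ValueError(f"chromosomes in both val and test: {sorted(val_set & test_set)}")
        chroms = np.array([iv.chrom for iv in m.regions])
        present = set(chroms)
        for label, wanted in (("validation", val_set), ("test", test_set)):
            missing = wanted - present
            if missing:
                warnings.warn(f"{label} chromosomes absent from regions: {sorted(missing)}")
        split[np.isin(chroms, list(val_set))] = "val"
        split[np.isin(chroms, list(test_set))] = "test"
    elif mode == "fraction":
        f_val, f_test = float(val), float(test)
        if f_val < 0 or f_test < 0 or f_val + f_test > 1:
            raise ValueError("fractions must be nonnegative and sum to <= 1")
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        n_val = int(round(f_val * n))
        n_test = int(round(f_test * n))
        split[order[:n_val]] = "val"
        split[order[n_val : n_val + n_test]] = "test"
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    m.obs["split"] = split
    return m


def otsu_threshold(values: np.ndarray) -> float:
    """Threshold maximizing between-class variance over a 1-D sample.

    Candidates are the distinct observed values; the returned threshold
    separates the sample into (<= t) and (> t) groups.
    """
    values = np.asarray(values, dtype=np.float64)
    uniq = np.unique(values)
    if uniq.size < 2:
        raise ValueError("constant column has no threshold")
    best_t, best_var = uniq[0], -1.0
    n = values.size
    for t in uniq[:-1]:
        lo = values <= t
        w0 = lo.sum() / n
        w1 = 1 - w0
        mu0 = values[lo].mean()
        mu1 = values[~lo].mean()
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return float(best_t)


def binarize_otsu(t: TopicMatrix) -> TopicMatrix:
    """Binarize each topic column with Otsu's between-class-variance rule."""
    mask = np.zeros_like(t.probs, dtype=bool)
    for k in range(t.probs.shape[1]):
        col = t.probs[:, k]
        if np.unique(col).size < 2:
            warnings.warn(f"topic {t.topic_names[k]!r}: constant column, empty mask")
            continue
        mask[:, k] = col > otsu_threshold(col)
    return TopicMatrix(t.probs, t.regions, t.topic_names, mask=mask, obs=t.obs)
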