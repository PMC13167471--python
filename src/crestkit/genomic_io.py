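"""Genome sequences, regions and coverage tracks.

Conventions used throughout the package:

* all coordinates are 0-based, half-open (BED convention);
* one-hot channel order is A, C, G, T;
* soft-masked (lowercase) bases are treated as their uppercase equivalents;
* fetching outside chromosome bounds pads with ``N`` (zero rows after
  one-hot encoding) rather than raising, so that short or edge regions can
  be fed to fixed-input-length models.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "GenomeSequence",
    "CoverageTrack",
    "fetch_sequence",
    "one_hot_encode",
    "one_hot_decode",
    "reverse_complement",
    "read_regions",
    "read_coverage",
    "write_track",
    "write_fasta",
]

BASES = "ACGT"
_BASE_TO_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # display is 1-based inclusive
        return f"{self.chrom}:{self.start + 1}-{self.end}"


class GenomeSequence:
    """In-memory genome with interval fetch.

    Holds uppercase sequence strings per chromosome. Construct from a dict
    (synthetic genomes) or from a FASTA file via :meth:`from_fasta`.
    """

    def __init__(self, chroms: Mapping[str, str]):
        self._chroms = {name: seq.upper() for name, seq in chroms.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chroms)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._chroms.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Fetch ``[start, end)``; out-of-bounds portions are 'N'-filled."""
        if chrom not in self._chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if end <= start:
            raise ValueError(f"end ({end}) must exceed start ({start})")
        seq = self._chroms[chrom]
        n = len(seq)
        lo, hi = max(start, 0), min(end, n)
        if hi <= lo:
            return "N" * (end - start)
        return "N" * (lo - start) + seq[lo:hi] + "N" * (end - hi)


def fetch_sequence(genome: GenomeSequence, iv: GenomicInterval) -> str:
    """Uppercase sequence of *iv*; clipped portions padded with 'N'."""
    return genome.fetch(iv.chrom, iv.start, iv.end)


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a DNA string as an L×4 {0,1} matrix (channels A,C,G,T).

    'N' (and 'n') become all-zero rows; any other character is rejected.
    """
    s = seq.upper()
    arr = np.zeros((len(s), 4), dtype=np.float64)
    bad = []
    for i, ch in enumerate(s):
        idx = _BASE_TO_IDX.get(ch)
        if idx is not None:
            arr[i, idx] = 1.0
        elif ch != "N":
            bad.append(i)
    if bad:
        shown = ", ".join(f"{i}:{seq[i]!r}" for i in bad[:10])
        raise ValueError(f"invalid characters at positions {shown}")
    return arr


def one_hot_decode(x: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; zero rows decode to 'N'."""
    x = np.asarray(x)
    out = []
    for row in x:
        if row.sum() == 0:
            out.append("N")
        else:
            out.append(BASES[int(np.argmax(row))])
    return "".join(out)


def reverse_complement(x: np.ndarray) -> np.ndarray:
    """Reverse-complement a one-hot matrix: flip rows, swap A<->T and C<->G."""
    return np.ascontiguousarray(x[::-1, ::-1])


def reverse_complement_str(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


def read_regions(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals, preserving file order and names."""
    regions: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end <= start")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            regions.append(GenomicInterval(fields[0], start, end, name=name, strand=strand))
    return regions


@dataclass
class CoverageTrack:
    """Piecewise-constant nonnegative coverage, stored as sorted runs.

    Per chromosome three parallel arrays (starts, ends, values) of
    non-overlapping sorted runs. Positions not covered by a run have value 0.
    """

    class_label: str = ""
    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, entries: Iterable[tuple[str, int, int, float]], class_label: str = ""
    ) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in entries:
            if value < 0:
                raise ValueError(f"negative coverage value {value} at {chrom}:{start}-{end}")
            if not np.isfinite(value):
                raise ValueError(f"non-finite coverage value at {chrom}:{start}-{end}")
            if end <= start:
                raise ValueError(f"empty run at {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        runs = {}
        for chrom, items in by_chrom.items():
            items.sort()
            starts = np.array([s for s, _, _ in items], dtype=np.int64)
            ends = np.array([e for _, e, _ in items], dtype=np.int64)
            values = np.array([v for _, _, v in items], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"overlapping runs on {chrom} near {starts[i + 1]} (previous run ends {ends[i]})"
                )
            runs[chrom] = (starts, ends, values)
        return cls(class_label=class_label, runs=runs)

    def total(self) -> float:
        """Signal integrated over the genome (sum of value x run width)."""
        return float(
            sum(((e - s) * v).sum() for s, e, v in self.runs.values())
        )

    def scale(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            class_label=self.class_label,
            runs={c: (s, e, v * factor) for c, (s, e, v) in self.runs.items()},
        )

    def _overlaps(self, chrom: str, start: int, end: int):
        if chrom not in self.runs:
            return None
        starts, ends, values = self.runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return None
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return s, e, values[lo:hi]

    def values_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base values over [start, end); gaps are 0."""
        out = np.zeros(end - start, dtype=np.float64)
        ov = self._overlaps(chrom, start, end)
        if ov is not None:
            s, e, v = ov
            for si, ei, vi in zip(s, e, v):
                out[si - start : ei - start] = vi
        return out

    def aggregate(self, chrom: str, start: int, end: int, how: str = "mean") -> float:
        """Aggregate per-base values over an interval; gaps count as 0."""
        ov = self._overlaps(chrom, start, end)
        width = end - start
        if ov is None:
            covered = 0
            total = 0.0
            vmax = 0.0
        else:
            s, e, v = ov
            lens = e - s
            covered = int(lens.sum())
            total = float((lens * v).sum())
            vmax = float(v.max())
        if how == "sum":
            return total
        if how == "mean":
            return total / width
        if how == "max":
            return vmax if covered >= width else max(vmax, 0.0)
        if how == "logsum":
            return float(np.log1p(total))
        raise ValueError(f"unknown aggregation {how!r}")


def read_coverage(path: str | os.PathLike, class_label: str = "") -> CoverageTrack:
    """Read a 4-column bedGraph file into a :class:`CoverageTrack`."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            try:
                entries.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed record") from exc
    return CoverageTrack.from_intervals(entries, class_label=class_label)


def write_track(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Write a track as bedGraph; round-trips through :func:`read_coverage`."""
    with open(path, "w") as fh:
        for chrom in sorted(track.runs):
            starts, ends, values = track.runs[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.8g}\n")


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
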