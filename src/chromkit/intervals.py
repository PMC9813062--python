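"""Genomic interval algebra and overlap statistics.

Implements the base-pair set operations (merge, intersect, union), the
Jaccard overlap index, multi-set Venn membership counting, seeded uniform
shuffling as an enrichment null, fold-enrichment against that null, and
distance-to-TSS classification.

Conventions follow BED: coordinates are 0-based, half-open, strand is one
of ``+``, ``-``, ``.``.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "IntervalSet",
    "OverlapStatistics",
    "EnrichmentResult",
    "BedParseError",
    "BoundsError",
    "UndefinedStatisticError",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "sort_merge",
    "intersect",
    "union",
    "jaccard",
    "jaccard_matrix",
    "multiway_membership",
    "multiway_membership_bp",
    "shuffle",
    "fold_enrichment",
    "classify_by_tss_distance",
    "fraction_of_regions_overlapped",
    "DEFAULT_TSS_BINS",
]


class BedParseError(ValueError):
    """A BED/bedGraph line could not be parsed."""


class BoundsError(ValueError):
    """An interval falls outside its declared chromosome."""


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined (e.g. Jaccard of two empty sets)."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and their lengths in base pairs."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes), tuple(int(v) for v in sizes.values()))

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """A collection of genomic intervals, optionally bound to a layout.

    The merged representation (sorted, disjoint, adjacency-merged, per
    chromosome) is computed lazily and cached; all base-pair statistics
    operate on it.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        layout: GenomeLayout | None = None,
        merged: bool = False,
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.layout = layout
        self.merged_flag = merged
        self._merged_arrays: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
        if layout is not None:
            for iv in self.intervals:
                if iv.chrom not in layout:
                    raise BoundsError(f"unknown chromosome {iv.chrom!r}")
                if iv.end > layout.sizes[iv.chrom]:
                    raise BoundsError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {layout.sizes[iv.chrom]}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, merged={self.merged_flag})"

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def merged_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) of the merged representation."""
        if self._merged_arrays is None:
            by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
            for iv in self.intervals:
                by_chrom[iv.chrom].append((iv.start, iv.end))
            out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom, pairs in by_chrom.items():
                pairs.sort()
                starts: list[int] = []
                ends: list[int] = []
                for s, e in pairs:
                    if ends and s <= ends[-1]:  # overlap or zero-gap adjacency
                        if e > ends[-1]:
                            ends[-1] = e
                    else:
                        starts.append(s)
                        ends.append(e)
                out[chrom] = (
                    np.asarray(starts, dtype=np.int64),
                    np.asarray(ends, dtype=np.int64),
                )
            self._merged_arrays = out
        return self._merged_arrays

    def total_bp(self) -> int:
        return int(
            sum((e - s).sum() for s, e in self.merged_arrays().values())
        )

    def overlaps_point(self, chrom: str, pos: int) -> bool:
        arrays = self.merged_arrays().get(chrom)
        if arrays is None:
            return False
        starts, ends = arrays
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]

    def overlap_bp_with(self, chrom: str, start: int, end: int) -> int:
        """Base pairs of [start, end) covered by this (merged) set."""
        arrays = self.merged_arrays().get(chrom)
        if arrays is None:
            return 0
        starts, ends = arrays
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return int(np.maximum(e - s, 0).sum())


@dataclass(frozen=True)
class OverlapStatistics:
    intersection_bp: int
    union_bp: int
    jaccard: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class EnrichmentResult:
    observed: float
    expected_mean: float
    expected_sd: float
    fold: float
    n_shuffles: int
    empirical_p: float
    seed: int
    infinite_fold: bool = False


# ---------------------------------------------------------------------------
# I/O


def read_chrom_sizes(path) -> GenomeLayout:
    """Two-column text file: chromosome name, length."""
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            names.append(parts[0])
            lengths.append(int(parts[1]))
    return GenomeLayout(tuple(names), tuple(lengths))


def read_bed(path, layout: GenomeLayout | None = None) -> IntervalSet:
    """Read BED3+ intervals; track/browser/comment lines are skipped.

    Raises :class:`BedParseError` (with the line number) on malformed
    coordinates and :class:`BoundsError` when intervals fall outside a
    supplied layout.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (
                not line.strip()
                or line.startswith(("track", "browser", "#"))
            ):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"line {lineno}: invalid interval {chrom}:{start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            intervals.append(
                GenomicInterval(chrom, start, end, name, score, strand)
            )
    return IntervalSet(intervals, layout=layout, merged=False)


def write_bed(iset: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in iset:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields += [
                    iv.name or ".",
                    "0" if iv.score is None else f"{iv.score:g}",
                    iv.strand,
                ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Set algebra


def sort_merge(iset: IntervalSet) -> IntervalSet:
    """Sorted, disjoint, adjacency-merged copy of *iset*. Idempotent."""
    merged = []
    arrays = iset.merged_arrays()
    for chrom in sorted(arrays):
        starts, ends = arrays[chrom]
        for s, e in zip(starts.tolist(), ends.tolist()):
            merged.append(GenomicInterval(chrom, s, e))
    return IntervalSet(merged, layout=iset.layout, merged=True)


def _pair_intersection(
    a: dict[str, tuple[np.ndarray, np.ndarray]],
    b: dict[str, tuple[np.ndarray, np.ndarray]],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in a.keys() & b.keys():
        s1, e1 = a[chrom]
        s2, e2 = b[chrom]
        starts: list[int] = []
        ends: list[int] = []
        i = j = 0
        while i < len(s1) and j < len(s2):
            lo = max(s1[i], s2[j])
            hi = min(e1[i], e2[j])
            if lo < hi:
                starts.append(int(lo))
                ends.append(int(hi))
            if e1[i] <= e2[j]:
                i += 1
            else:
                j += 1
        if starts:
            out[chrom] = (
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
            )
    return out


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-pair intersection of two sets (merged)."""
    inter = _pair_intersection(a.merged_arrays(), b.merged_arrays())
    ivs = [
        GenomicInterval(chrom, int(s), int(e))
        for chrom in sorted(inter)
        for s, e in zip(*inter[chrom])
    ]
    return IntervalSet(ivs, layout=a.layout or b.layout, merged=True)


def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return sort_merge(
        IntervalSet(
            list(a) + list(b), layout=a.layout or b.layout, merged=False
        )
    )


def jaccard(a: IntervalSet, b: IntervalSet) -> OverlapStatistics:
    """Jaccard index |A∩B| / |A∪B| in base pairs, on merged sets.

    Symmetric; raises :class:`UndefinedStatisticError` when both sets are
    empty (a 0/0 statistic, not zero).
    """
    bp_a = a.total_bp()
    bp_b = b.total_bp()
    if bp_a == 0 and bp_b == 0:
        raise UndefinedStatisticError("Jaccard of two empty sets is undefined")
    inter = _pair_intersection(a.merged_arrays(), b.merged_arrays())
    inter_bp = int(sum((e - s).sum() for s, e in inter.values()))
    union_bp = bp_a + bp_b - inter_bp
    return OverlapStatistics(
        intersection_bp=inter_bp,
        union_bp=union_bp,
        jaccard=inter_bp / union_bp,
        n_a=len(a),
        n_b=len(b),
    )


def jaccard_matrix(
    sets: Mapping[str, IntervalSet],
) -> "pd.DataFrame":  # noqa: F821 - imported lazily
    """Symmetric matrix of pairwise Jaccard indices.

    Empty-vs-empty pairs yield NaN with a warning rather than an error.
    """
    import warnings

    import pandas as pd

    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least two sets")
    mat = np.full((len(names), len(names)), np.nan)
    for i, ni in enumerate(names):
        for j in range(i, len(names)):
            nj = names[j]
            try:
                val = jaccard(sets[ni], sets[nj]).jaccard
            except UndefinedStatisticError:
                warnings.warn(
                    f"Jaccard({ni}, {nj}) undefined (both empty); NaN"
                )
                val = np.nan
            mat[i, j] = mat[j, i] = val
    return pd.DataFrame(mat, index=names, columns=names)


def multiway_membership(
    sets: Mapping[str, IntervalSet],
    unit: str | None = None,
) -> dict[frozenset[str], int]:
    """Venn-style membership counts of the *unit* set's intervals.

    Each interval of the unit set (default: the first set) is labelled with
    the signature of input sets it overlaps by at least 1 bp (the unit set
    itself always included).  Counts over signatures sum to the unit set's
    interval count.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least two sets")
    if unit is None:
        unit = names[0]
    if unit not in sets:
        raise KeyError(unit)
    counts: Counter[frozenset[str]] = Counter()
    others = {n: sets[n] for n in names}
    for iv in sets[unit]:
        sig = {unit}
        for n, oset in others.items():
            if n == unit:
                continue
            if oset.overlap_bp_with(iv.chrom, iv.start, iv.end) >= 1:
                sig.add(n)
        counts[frozenset(sig)] += 1
    return dict(counts)


def multiway_membership_bp(
    sets: Mapping[str, IntervalSet],
) -> dict[frozenset[str], int]:
    """Base-pair Venn: bp of genome covered by exactly each set signature."""
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least two sets")
    chroms = sorted({c for s in sets.values() for c in s.merged_arrays()})
    counts: Counter[frozenset[str]] = Counter()
    for chrom in chroms:
        bounds: set[int] = set()
        per_set = {}
        for n in names:
            arrays = sets[n].merged_arrays().get(chrom)
            if arrays is not None:
                bounds.update(arrays[0].tolist())
                bounds.update(arrays[1].tolist())
                per_set[n] = arrays
        edges = sorted(bounds)
        for lo, hi in zip(edges, edges[1:]):
            sig = frozenset(
                n
                for n, (s, e) in per_set.items()
                if _covers(s, e, lo)
            )
            if sig:
                counts[sig] += hi - lo
    return dict(counts)


def _covers(starts: np.ndarray, ends: np.ndarray, pos: int) -> bool:
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    return i >= 0 and pos < ends[i]


# ---------------------------------------------------------------------------
# Shuffle null and enrichment


def shuffle(iset: IntervalSet, layout: GenomeLayout, seed: int) -> IntervalSet:
    """Reposition every interval uniformly at random on its own chromosome.

    Interval count and the per-chromosome length multiset are conserved;
    shuffled intervals may overlap each other. Deterministic given *seed*.
    """
    rng = np.random.default_rng(seed)
    sizes = layout.sizes
    out: list[GenomicInterval] = []
    for iv in iset:
        if iv.chrom not in sizes:
            raise BoundsError(f"layout lacks chromosome {iv.chrom!r}")
        clen = sizes[iv.chrom]
        ilen = len(iv)
        if ilen > clen:
            raise BoundsError(
                f"interval of length {ilen} exceeds chromosome "
                f"{iv.chrom} ({clen} bp)"
            )
        start = int(rng.integers(0, clen - ilen + 1))
        out.append(
            GenomicInterval(iv.chrom, start, start + ilen, iv.name, iv.score, iv.strand)
        )
    return IntervalSet(out, layout=layout, merged=False)


_STATISTICS = ("overlap_bp", "jaccard", "peak_fraction")


def _enrichment_statistic(
    peaks: IntervalSet, target: IntervalSet, statistic: str
) -> float:
    if statistic == "overlap_bp":
        inter = _pair_intersection(peaks.merged_arrays(), target.merged_arrays())
        return float(sum((e - s).sum() for s, e in inter.values()))
    if statistic == "jaccard":
        return jaccard(peaks, target).jaccard
    if statistic == "peak_fraction":
        if len(peaks) == 0:
            return 0.0
        hit = sum(
            1
            for iv in peaks
            if target.overlap_bp_with(iv.chrom, iv.start, iv.end) >= 1
        )
        return hit / len(peaks)
    raise ValueError(f"unknown statistic {statistic!r}; one of {_STATISTICS}")


def fold_enrichment(
    peaks: IntervalSet,
    target: IntervalSet,
    layout: GenomeLayout,
    n_shuffles: int = 200,
    seed: int = 0,
    statistic: str = "jaccard",
) -> EnrichmentResult:
    """Observed statistic vs a uniform-shuffle null.

    ``fold = observed / mean(shuffled)``;
    ``empirical_p = (1 + #{shuffle >= observed}) / (n_shuffles + 1)``.
    A zero null mean yields an infinite-fold sentinel with a flag.
    """
    if n_shuffles < 10:
        raise ValueError("n_shuffles must be >= 10")
    observed = _enrichment_statistic(peaks, target, statistic)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_shuffles)
    null = np.array(
        [
            _enrichment_statistic(
                shuffle(peaks, layout, int(s)), target, statistic
            )
            for s in sub_seeds
        ]
    )
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n_shuffles > 1 else 0.0
    k = int((null >= observed).sum())
    p = (1 + k) / (n_shuffles + 1)
    if mean == 0:
        return EnrichmentResult(
            observed, 0.0, sd, math.inf, n_shuffles, p, seed, infinite_fold=True
        )
    return EnrichmentResult(observed, mean, sd, observed / mean, n_shuffles, p, seed)


# ---------------------------------------------------------------------------
# TSS distance classification

DEFAULT_TSS_BINS = (1_000, 3_000, 10_000, 100_000)


def _bin_labels(bins: Sequence[int]) -> list[str]:
    def fmt(x: int) -> str:
        return f"{x // 1000}kb" if x % 1000 == 0 else f"{x}bp"

    labels = [f"<{fmt(bins[0])}"]
    labels += [f"{fmt(a)}-{fmt(b)}" for a, b in zip(bins, bins[1:])]
    labels.append(f">{fmt(bins[-1])}")
    return labels


def classify_by_tss_distance(
    peaks: IntervalSet,
    tss: IntervalSet,
    bins: Sequence[int] = DEFAULT_TSS_BINS,
) -> dict[str, int]:
    """Count peaks per unsigned midpoint-to-nearest-TSS distance class.

    TSS anchors are single-base; nearest-anchor ties break toward the
    smaller coordinate. Peaks on chromosomes with no anchor fall in the
    open top class.
    """
    if len(tss) == 0:
        raise ValueError("empty TSS set")
    anchors: dict[str, np.ndarray] = {}
    for iv in tss:
        anchors.setdefault(iv.chrom, [])
    by_chrom: dict[str, list[int]] = {c: [] for c in anchors}
    for iv in tss:
        by_chrom[iv.chrom].append(iv.start)
    anchors = {c: np.asarray(sorted(v), dtype=np.int64) for c, v in by_chrom.items()}
    labels = _bin_labels(bins)
    counts = {lab: 0 for lab in labels}
    edges = np.asarray(bins, dtype=np.int64)
    for iv in peaks:
        pos_arr = anchors.get(iv.chrom)
        mid = iv.midpoint
        if pos_arr is None or len(pos_arr) == 0:
            counts[labels[-1]] += 1
            continue
        i = int(np.searchsorted(pos_arr, mid))
        best = math.inf
        # tie toward the smaller coordinate: check left neighbour first
        if i > 0:
            best = mid - int(pos_arr[i - 1])
        if i < len(pos_arr) and int(pos_arr[i]) - mid < best:
            best = int(pos_arr[i]) - mid
        if math.isinf(best):
            counts[labels[-1]] += 1
            continue
        k = int(np.searchsorted(edges, best, side="right"))
        counts[labels[k]] += 1
    return counts


def fraction_of_regions_overlapped(
    regions: IntervalSet,
    peaks: IntervalSet,
    min_overlap: int = 1,
) -> tuple[float, int, int]:
    """Fraction of region intervals overlapping any peak by >= min_overlap bp."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    n_hit = sum(
        1
        for iv in regions
        if peaks.overlap_bp_with(iv.chrom, iv.start, iv.end) >= min_overlap
    )
    return n_hit / len(regions), n_hit, len(regions)
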