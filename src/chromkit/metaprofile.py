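"""Anchor-centered coverage metaprofiles (TSS +/- window).

A :class:`CoverageTrack` holds bedGraph-style per-chromosome step
functions. :func:`signal_matrix` extracts an anchors x bins matrix around
single-base, stranded anchors (rows of minus-strand anchors are flipped so
downstream of the gene is always to the right), from which average
profiles, summit offsets and background-corrected matrices are derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .intervals import BedParseError, GenomeLayout, IntervalSet

__all__ = [
    "CoverageTrack",
    "SignalMatrix",
    "read_bedgraph",
    "write_bedgraph",
    "signal_matrix",
    "average_profile",
    "summit_offset",
    "background_correct",
]


class CoverageTrack:
    """Per-chromosome sorted, disjoint (start, end, value >= 0) runs.

    Uncovered bases have value 0.
    """

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.runs = {}
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(values < 0):
                raise ValueError(f"negative coverage on {chrom}")
            if np.any(starts >= ends):
                raise ValueError(f"empty run on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping runs on {chrom}")
            self.runs[chrom] = (starts, ends, values)
        # prefix integral of coverage up to each run start, for O(log n) queries
        self._cum = {
            chrom: np.concatenate(
                [[0.0], np.cumsum((e - s) * v)]
            )
            for chrom, (s, e, v) in self.runs.items()
        }

    @classmethod
    def from_runs(cls, runs: dict[str, list[tuple[int, int, float]]]) -> "CoverageTrack":
        return cls(
            {
                chrom: (
                    np.array([r[0] for r in rs]),
                    np.array([r[1] for r in rs]),
                    np.array([r[2] for r in rs]),
                )
                for chrom, rs in runs.items()
                if rs
            }
        )

    def total_mass(self) -> float:
        return float(
            sum(((e - s) * v).sum() for s, e, v in self.runs.values())
        )

    def covered_extent(self) -> int:
        """Total span from 0 to the last covered base, per chromosome."""
        return int(sum(e[-1] for _, e, _ in self.runs.values()))

    def mean_coverage(self, layout: GenomeLayout | None = None) -> float:
        """Genome-wide mean coverage; denominator is the layout's total bp
        when given, else the covered extent of the track."""
        denom = layout.total_bp if layout is not None else self.covered_extent()
        if denom == 0:
            return 0.0
        return self.total_mass() / denom

    def integral(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of coverage over [0, x) for each query coordinate."""
        if chrom not in self.runs:
            return np.zeros_like(np.asarray(x, dtype=np.float64))
        starts, ends, values = self.runs[chrom]
        cum = self._cum[chrom]
        xc = np.clip(np.asarray(x, dtype=np.float64), 0, None)
        k = np.searchsorted(starts, xc, side="right") - 1
        kc = np.clip(k, 0, None)
        inside = np.clip(xc - starts[kc], 0, ends[kc] - starts[kc]) * values[kc]
        return np.where(k >= 0, cum[kc] + inside, 0.0)

    def windowed_means(
        self, chrom: str, start: int, n_bins: int, bin_width: int
    ) -> np.ndarray:
        """Mean per-base coverage in n_bins consecutive bins from *start*."""
        edges = start + bin_width * np.arange(n_bins + 1)
        integ = self.integral(chrom, edges)
        return np.diff(integ) / bin_width


def read_bedgraph(path) -> CoverageTrack:
    """4-column bedGraph; overlapping runs or negative values are rejected."""
    runs: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: expected 4 fields")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: bad fields") from exc
            if value < 0:
                raise BedParseError(f"line {lineno}: negative value")
            if start >= end:
                raise BedParseError(f"line {lineno}: empty run")
            runs.setdefault(fields[0], []).append((start, end, value))
    try:
        return CoverageTrack.from_runs(runs)
    except ValueError as exc:
        raise BedParseError(str(exc)) from exc


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.runs):
            starts, ends, values = track.runs[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


@dataclass
class SignalMatrix:
    """Anchors x bins coverage matrix around stranded single-base anchors."""

    anchor_ids: list[str]
    window: int
    bin_width: int
    values: np.ndarray  # anchors x bins
    depth: float = 1.0  # mean genome-wide coverage of the source track
    truncated: list[bool] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return 2 * self.window // self.bin_width

    def bin_centers(self) -> np.ndarray:
        """Signed bp of each bin center relative to the anchor."""
        return -self.window + self.bin_width * (np.arange(self.n_bins) + 0.5)


def signal_matrix(
    track: CoverageTrack,
    anchors: IntervalSet,
    window: int = 2000,
    bin_width: int = 50,
    layout: GenomeLayout | None = None,
) -> SignalMatrix:
    """Coverage matrix around anchors, +/- *window* bp in *bin_width* bins.

    Bin value is mean per-base coverage. Rows of "-" strand anchors are
    reversed so gene-downstream is to the right. Windows truncated by the
    chromosome start are zero-padded and flagged; anchors on chromosomes
    absent from the track get zero rows with a warning.
    """
    if window % bin_width != 0:
        raise ValueError("window must be divisible by bin_width")
    n_bins = 2 * window // bin_width
    rows = []
    ids = []
    truncated = []
    for k, iv in enumerate(anchors):
        if len(iv) != 1:
            raise ValueError("anchors must be single-base intervals")
        pos = iv.start
        if iv.chrom not in track.runs:
            warnings.warn(f"anchor chromosome {iv.chrom!r} absent from track")
            row = np.zeros(n_bins)
            trunc = False
        else:
            start = pos - window
            row = track.windowed_means(iv.chrom, start, n_bins, bin_width)
            trunc = start < 0
            if layout is not None and pos + window > layout.sizes[iv.chrom]:
                trunc = True
        if iv.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(iv.name or f"anchor_{k}")
        truncated.append(trunc)
    values = np.vstack(rows) if rows else np.zeros((0, n_bins))
    return SignalMatrix(
        anchor_ids=ids,
        window=window,
        bin_width=bin_width,
        values=values,
        depth=track.mean_coverage(layout),
        truncated=truncated,
    )


def average_profile(matrix: SignalMatrix) -> np.ndarray:
    """Per-bin column means over anchors."""
    if matrix.values.shape[0] < 1:
        raise ValueError("need at least one anchor")
    return matrix.values.mean(axis=0)


def summit_offset(
    profile: np.ndarray, bin_width: int, window: int
) -> float:
    """Signed bp of the maximal bin's center relative to the anchor.

    Negative means upstream in gene orientation. Ties break toward 0.
    Raises on an all-zero profile (no summit).
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0 or np.all(profile == 0):
        raise ValueError("summit undefined for an all-zero profile")
    centers = -window + bin_width * (np.arange(profile.size) + 0.5)
    maxval = profile.max()
    tied = np.flatnonzero(profile == maxval)
    best = tied[np.argmin(np.abs(centers[tied]))]
    return float(centers[best])


def background_correct(
    signal: SignalMatrix,
    background: SignalMatrix,
    scale: bool = True,
    method: str = "subtract",
) -> SignalMatrix:
    """Background-corrected matrix: scaled signal minus scaled background.

    With ``scale=True`` each matrix is first divided by its source track's
    mean genome-wide coverage (depth), so tracks of different sequencing
    depth are comparable. ``method="subtract"`` clips at zero;
    ``method="log2_ratio"`` returns log2((s+1)/(b+1)) of the scaled values.
    """
    if signal.values.shape != background.values.shape:
        raise ValueError("signal and background shapes differ")
    if (signal.window, signal.bin_width) != (background.window, background.bin_width):
        raise ValueError("signal and background windows/bins differ")
    s = signal.values / signal.depth if scale and signal.depth > 0 else signal.values
    b = (
        background.values / background.depth
        if scale and background.depth > 0
        else background.values
    )
    if method == "subtract":
        out = np.clip(s - b, 0, None)
    elif method == "log2_ratio":
        out = np.log2((s + 1.0) / (b + 1.0))
    else:
        raise ValueError(f"unknown method {method!r}")
    return SignalMatrix(
        anchor_ids=list(signal.anchor_ids),
        window=signal.window,
        bin_width=signal.bin_width,
        values=out,
        depth=1.0,
        truncated=list(signal.truncated),
    )
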