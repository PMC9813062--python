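"""Overlap analysis of peak sets against a labelled chromatin-state segmentation.

A :class:`Segmentation` is a state-labelled interval set in the style of a
25-state chromHMM imputation (TssA, PromD1, EnhA1, ...). Operations here
turn peak sets into per-state Jaccard profiles, promoter:enhancer ratio
statistics, state-by-mark matrices, and intersection tracks of co-occurring
marks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import reduce
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    GenomeLayout,
    IntervalSet,
    UndefinedStatisticError,
    intersect,
    jaccard,
    sort_merge,
)

__all__ = [
    "ROADMAP_25_STATES",
    "DEFAULT_GROUPS",
    "Segmentation",
    "StateGrouping",
    "read_state_bed",
    "read_state_alphabet",
    "state_jaccard_profile",
    "group_ratio",
    "state_mark_profile",
    "intersection_track",
]

# The 25 imputed chromatin-state labels of the Roadmap 25-state model.
ROADMAP_25_STATES: tuple[str, ...] = (
    "TssA", "PromU", "PromD1", "PromD2",
    "Tx5'", "Tx", "Tx3'", "TxWk", "TxReg",
    "TxEnh5'", "TxEnh3'", "TxEnhW",
    "EnhA1", "EnhA2", "EnhAF", "EnhW1", "EnhW2", "EnhAc",
    "DNase", "ZNF/Rpts", "Het",
    "PromP", "PromBiv", "ReprPC", "Quies",
)

DEFAULT_GROUPS: dict[str, frozenset[str]] = {
    "all_promoters": frozenset(
        {"TssA", "PromD1", "PromD2", "PromU", "PromP", "PromBiv"}
    ),
    "all_enhancers": frozenset(
        {"EnhA1", "EnhA2", "EnhAF", "EnhW1", "EnhW2", "EnhAc",
         "TxEnh5'", "TxEnh3'", "TxEnhW"}
    ),
    "active_promoters": frozenset({"TssA", "PromD1", "PromD2", "PromU"}),
    "other_promoters": frozenset({"PromP", "PromBiv"}),
}


@dataclass
class StateGrouping:
    """Named groups of state labels (groups need not partition the alphabet)."""

    groups: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.groups[name]

    def __contains__(self, name: str) -> bool:
        return name in self.groups


class Segmentation:
    """A state-labelled partition-style interval set.

    Segments on one chromosome must be disjoint; the label alphabet is
    fixed and closed (unknown labels are rejected).
    """

    def __init__(
        self,
        segments: IntervalSet,
        alphabet: Iterable[str] = ROADMAP_25_STATES,
    ) -> None:
        self.alphabet: tuple[str, ...] = tuple(alphabet)
        alpha = set(self.alphabet)
        for iv in segments:
            if iv.name is None:
                raise ValueError("every segment needs a state label (name column)")
            if iv.name not in alpha:
                raise ValueError(f"state label {iv.name!r} not in alphabet")
        self.segments = segments
        self._check_disjoint()
        self._by_state: dict[str, IntervalSet] | None = None

    def _check_disjoint(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in self.segments:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            for (s1, e1), (s2, e2) in zip(pairs, pairs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping segments on {chrom}: "
                        f"[{s1},{e1}) and [{s2},{e2})"
                    )

    def by_state(self) -> dict[str, IntervalSet]:
        """State label -> merged IntervalSet of its segments (absent -> empty)."""
        if self._by_state is None:
            buckets: dict[str, list[GenomicInterval]] = {s: [] for s in self.alphabet}
            for iv in self.segments:
                buckets[iv.name].append(iv)
            self._by_state = {
                s: sort_merge(IntervalSet(ivs, layout=self.segments.layout))
                for s, ivs in buckets.items()
            }
        return self._by_state

    def total_bp(self) -> int:
        return self.segments.total_bp()


def read_state_alphabet(path) -> tuple[str, ...]:
    """One state label per line; blank lines and # comments skipped."""
    labels = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                labels.append(line)
    return tuple(labels)


def read_state_bed(
    path,
    alphabet: Iterable[str] = ROADMAP_25_STATES,
    layout: GenomeLayout | None = None,
) -> Segmentation:
    """chromHMM dense-BED dialect: BED4 with the state label in the name column."""
    from .intervals import read_bed

    return Segmentation(read_bed(path, layout=layout), alphabet=alphabet)


def state_jaccard_profile(
    peaks: IntervalSet, seg: Segmentation
) -> pd.Series:
    """Per-state Jaccard J(peaks, segments of state s), over the full alphabet.

    States absent from the segmentation contribute 0 (with a warning), not
    a missing value. An empty peak set raises, as Jaccard is undefined.
    """
    if peaks.total_bp() == 0:
        raise UndefinedStatisticError("empty peak set: per-state Jaccard undefined")
    values = {}
    for state, sset in seg.by_state().items():
        if sset.total_bp() == 0:
            warnings.warn(f"state {state!r} absent from segmentation; J=0")
            values[state] = 0.0
        else:
            values[state] = jaccard(peaks, sset).jaccard
    return pd.Series(values, name="jaccard").reindex(list(seg.alphabet))


def group_ratio(
    peaks: IntervalSet,
    seg: Segmentation,
    grouping: StateGrouping,
    numerator: str,
    denominator: str,
    pooled: bool = False,
) -> float:
    """Ratio of grouped Jaccard overlap, numerator group over denominator group.

    By default per-state Jaccards are summed within each group; with
    ``pooled=True`` each group's segments are pooled into one interval set
    before a single Jaccard is computed. A zero denominator yields ``inf``.
    """
    num_states = grouping[numerator]
    den_states = grouping[denominator]
    alpha = set(seg.alphabet)
    if not (num_states & alpha) or not (den_states & alpha):
        raise ValueError("numerator/denominator groups empty in the alphabet")
    if pooled:
        by_state = seg.by_state()
        def pooled_j(states: frozenset[str]) -> float:
            pooled_set = sort_merge(
                IntervalSet(
                    [iv for s in states if s in by_state for iv in by_state[s]]
                )
            )
            if pooled_set.total_bp() == 0:
                return 0.0
            return jaccard(peaks, pooled_set).jaccard
        num = pooled_j(num_states)
        den = pooled_j(den_states)
    else:
        profile = state_jaccard_profile(peaks, seg).fillna(0.0)
        num = float(profile[[s for s in profile.index if s in num_states]].sum())
        den = float(profile[[s for s in profile.index if s in den_states]].sum())
    if den == 0:
        return float("inf")
    return num / den


def state_mark_profile(
    seg: Segmentation, marks: Mapping[str, IntervalSet]
) -> pd.DataFrame:
    """State x mark matrix of Jaccard values.

    Empty marks give NaN columns (undefined statistic surfaced as missing).
    """
    if len(marks) < 1:
        raise ValueError("need at least one mark set")
    by_state = seg.by_state()
    mat = pd.DataFrame(
        np.nan, index=list(seg.alphabet), columns=list(marks), dtype=float
    )
    for mname, mset in marks.items():
        if mset.total_bp() == 0:
            warnings.warn(f"mark {mname!r} empty; column left as NaN")
            continue
        for state, sset in by_state.items():
            if sset.total_bp() == 0:
                mat.loc[state, mname] = 0.0
            else:
                mat.loc[state, mname] = jaccard(sset, mset).jaccard
    return mat


def intersection_track(marks: Mapping[str, IntervalSet]) -> IntervalSet:
    """Base-pair intersection of all (merged) mark sets; may be empty."""
    if len(marks) < 2:
        raise ValueError("need at least two mark sets")
    return reduce(intersect, marks.values())
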