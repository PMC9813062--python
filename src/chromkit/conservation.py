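"""Reference-anchored cross-species protein conservation profiling.

The pipeline mirrors standard practice for conservation logos: cluster
away redundant database entries, drop truncated proteins and duplicate
isoforms, then score each reference position of a multiple sequence
alignment by Shannon information content in bits,

    bits(pos) = log2(20) + sum_i p_i * log2(p_i)

where p_i is the frequency of amino acid i among the non-gap residues of
the alignment column (0 * log 0 := 0, X ignored). A fully conserved
column scores log2(20) ~ 4.32 bits; a uniform column scores 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import PairwiseAligner

__all__ = [
    "AMINO_ACIDS",
    "MAX_BITS",
    "SIMILARITY_GROUPS",
    "ProteinSequence",
    "Alignment",
    "ConservationProfile",
    "read_alignment_fasta",
    "cluster_representatives",
    "filter_by_length",
    "one_per_species",
    "conservation_bits",
    "pairwise_identity_similarity",
    "windowed_profile",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MAX_BITS = math.log2(20)

# Conservative substitution groups used for % similarity.
SIMILARITY_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("AGS"),
    frozenset("ILVM"),
    frozenset("FWY"),
    frozenset("KRH"),
    frozenset("DENQ"),
    frozenset("ST"),
    frozenset("C"),
    frozenset("P"),
)


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str
    species: str = ""
    paralogue: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")

    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def __len__(self) -> int:
        return len(self.ungapped())


@dataclass
class Alignment:
    """Equal-length gapped rows with a designated human reference row."""

    rows: list[ProteinSequence]
    reference_id: str

    def __post_init__(self) -> None:
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if self.reference_id not in {r.id for r in self.rows}:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")

    @property
    def column_count(self) -> int:
        return len(self.rows[0].residues)

    @property
    def reference(self) -> ProteinSequence:
        return next(r for r in self.rows if r.id == self.reference_id)


@dataclass
class ConservationProfile:
    """Per-reference-position amino-acid frequencies and bits."""

    positions: np.ndarray          # 1-based reference residue index
    ref_residues: list[str]
    frequencies: np.ndarray        # positions x 20
    n_eff: np.ndarray              # non-gap residues per column
    bits: np.ndarray
    low_support: np.ndarray        # n_eff below the support threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "ref_residue": self.ref_residues,
                "n_eff": self.n_eff,
                "bits": self.bits,
                "low_support": self.low_support,
            }
        )


def read_alignment_fasta(path, reference_id: str) -> Alignment:
    """Aligned multi-FASTA; header metadata parsed as ``id|species|paralogue``."""
    aln = AlignIO.read(path, "fasta")
    rows = []
    for rec in aln:
        parts = rec.description.split("|")
        rows.append(
            ProteinSequence(
                id=parts[0],
                residues=str(rec.seq).upper(),
                species=parts[1] if len(parts) > 1 else "",
                paralogue=parts[2] if len(parts) > 2 else "",
            )
        )
    return Alignment(rows=rows, reference_id=reference_id)


def _global_identity(a: str, b: str, aligner: PairwiseAligner) -> float:
    """Matches in an optimal global alignment over the shorter length.

    Scoring is match=1, mismatch=0, free gaps, so the alignment score is
    the maximal number of matched residues; dividing by the shorter
    ungapped length gives a CD-HIT-like global identity.
    """
    if not a or not b:
        return 0.0
    score = aligner.score(a, b)
    return float(score) / min(len(a), len(b))


def _make_identity_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner


def cluster_representatives(
    seqs: list[ProteinSequence], threshold: float = 0.8
) -> list[ProteinSequence]:
    """Greedy longest-first clustering at a global-identity threshold.

    Sequences are visited longest first; each joins the first existing
    representative to which its identity is >= *threshold*, otherwise it
    founds a new cluster. Returns the representatives.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    aligner = _make_identity_aligner()
    reps: list[ProteinSequence] = []
    for seq in sorted(seqs, key=lambda s: (-len(s), s.id)):
        for rep in reps:
            if _global_identity(seq.ungapped(), rep.ungapped(), aligner) >= threshold:
                break
        else:
            reps.append(seq)
    return reps


def filter_by_length(
    seqs: list[ProteinSequence],
    reference: ProteinSequence,
    min_frac: float = 0.9,
) -> list[ProteinSequence]:
    """Keep sequences with ungapped length >= min_frac x reference length
    (inclusive bound), dropping truncated proteins."""
    cutoff = min_frac * len(reference)
    return [s for s in seqs if len(s) >= cutoff]


def one_per_species(seqs: list[ProteinSequence]) -> list[ProteinSequence]:
    """Keep one sequence per (species, paralogue): the longest, ties by id."""
    best: dict[tuple[str, str], ProteinSequence] = {}
    for s in seqs:
        key = (s.species, s.paralogue)
        cur = best.get(key)
        if cur is None or len(s) > len(cur) or (len(s) == len(cur) and s.id < cur.id):
            best[key] = s
    return list(best.values())


def conservation_bits(
    aln: Alignment, min_seqs: int = 10
) -> ConservationProfile:
    """Shannon conservation in bits for every reference (non-gap) column.

    Columns are indexed by 1-based reference residue number; frequencies
    run over the 20 standard amino acids among non-gap residues (X and
    gaps excluded). Columns with fewer than *min_seqs* scored residues are
    flagged low-support but still reported.
    """
    if len(aln.rows) < 2:
        raise ValueError("need at least two rows")
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    ref = aln.reference.residues
    row_arrays = np.array([list(r.residues) for r in aln.rows])
    positions = []
    ref_residues = []
    freqs = []
    n_effs = []
    bits_list = []
    refpos = 0
    for col in range(aln.column_count):
        if ref[col] == "-":
            continue
        refpos += 1
        column = row_arrays[:, col]
        counts = np.zeros(20)
        for res in column:
            i = aa_index.get(res)
            if i is not None:
                counts[i] += 1
        n_eff = int(counts.sum())
        if n_eff > 0:
            p = counts / n_eff
            nz = p[p > 0]
            bits = MAX_BITS + float(np.sum(nz * np.log2(nz)))
            # clamp tiny negative float residue
            bits = min(max(bits, 0.0), MAX_BITS)
        else:
            p = counts
            bits = 0.0
        positions.append(refpos)
        ref_residues.append(ref[col])
        freqs.append(p)
        n_effs.append(n_eff)
        bits_list.append(bits)
    return ConservationProfile(
        positions=np.asarray(positions, dtype=np.int64),
        ref_residues=ref_residues,
        frequencies=np.asarray(freqs),
        n_eff=np.asarray(n_effs, dtype=np.int64),
        bits=np.asarray(bits_list),
        low_support=np.asarray(n_effs) < min_seqs,
    )


def pairwise_identity_similarity(
    a: ProteinSequence,
    b: ProteinSequence,
    aligned: bool = True,
    groups: tuple[frozenset[str], ...] = SIMILARITY_GROUPS,
) -> tuple[float, float]:
    """Percent identity and similarity between two sequences.

    For aligned input (equal lengths, gaps allowed) columns where both
    rows are gaps are ignored; identity counts exact residue matches and
    similarity additionally counts residue pairs sharing a conservative
    substitution group. Unaligned input is globally aligned first.
    """
    sa, sb = a.residues, b.residues
    if aligned:
        if len(sa) != len(sb):
            raise ValueError("aligned=True requires equal-length sequences")
    else:
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 2
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -0.5
        alignment = aligner.align(a.ungapped(), b.ungapped())[0]
        sa, sb = str(alignment[0]), str(alignment[1])
    n_cols = n_ident = n_sim = 0
    for x, y in zip(sa, sb):
        if x == "-" and y == "-":
            continue
        n_cols += 1
        if x == y and x != "-":
            n_ident += 1
            n_sim += 1
        elif x != "-" and y != "-" and any(
            x in g and y in g for g in groups
        ):
            n_sim += 1
    if n_cols == 0:
        return 0.0, 0.0
    return 100.0 * n_ident / n_cols, 100.0 * n_sim / n_cols


def windowed_profile(
    profile: ConservationProfile,
    annotations: "list",
) -> pd.Series:
    """Mean bits over each annotation's residue ranges (1-based inclusive).

    Annotations are objects with ``name`` and ``ranges`` attributes (see
    :class:`chromkit.mutations.RegionAnnotation`).
    """
    pos_to_idx = {int(p): i for i, p in enumerate(profile.positions)}
    out = {}
    for ann in annotations:
        idxs = []
        for start, end in ann.ranges:
            if start > end or start < 1 or end > int(profile.positions.max()):
                raise ValueError(
                    f"annotation {ann.name!r} range [{start},{end}] outside profile"
                )
            idxs.extend(
                pos_to_idx[p] for p in range(start, end + 1) if p in pos_to_idx
            )
        if not idxs:
            raise ValueError(f"annotation {ann.name!r} covers no profiled residue")
        out[ann.name] = float(profile.bits[idxs].mean())
    return pd.Series(out, name="mean_bits")
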