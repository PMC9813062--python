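"""Seeded generators for every input the analysis modules consume.

Each generator plants a known ground truth — state-preferential peaks, a
coverage summit at a fixed signed offset from TSS anchors, per-position
conservation targets, region/motif mutation-rate multipliers — so every
downstream statistic can be checked by parameter recovery rather than
against opaque fixtures.

All generators are deterministic given the spec seed; each draws from its
own independent stream so adding one generator never perturbs another.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .conservation import AMINO_ACIDS, MAX_BITS, Alignment, ProteinSequence
from .chromstate import ROADMAP_25_STATES, Segmentation
from .intervals import GenomeLayout, GenomicInterval, IntervalSet
from .metaprofile import CoverageTrack
from .mutations import MutationRecord, RegionAnnotation

__all__ = [
    "GenomeSpec",
    "SegmentationSpec",
    "PeakSpec",
    "CoverageSpec",
    "MsaSpec",
    "MutationSpec",
    "SyntheticSpec",
    "make_genome",
    "make_segmentation",
    "make_peaks",
    "make_tss",
    "make_coverage",
    "make_msa",
    "make_mutations",
    "default_phd_annotation",
    "write_all",
]


def _default_state_proportions() -> dict[str, float]:
    """Roadmap-like base-pair shares: mostly quiescent/weakly transcribed,
    small promoter and enhancer states."""
    props = {
        "TssA": 0.010, "PromU": 0.010, "PromD1": 0.008, "PromD2": 0.008,
        "Tx5'": 0.015, "Tx": 0.060, "Tx3'": 0.015, "TxWk": 0.100, "TxReg": 0.015,
        "TxEnh5'": 0.010, "TxEnh3'": 0.010, "TxEnhW": 0.010,
        "EnhA1": 0.015, "EnhA2": 0.015, "EnhAF": 0.010,
        "EnhW1": 0.015, "EnhW2": 0.015, "EnhAc": 0.010,
        "DNase": 0.020, "ZNF/Rpts": 0.010, "Het": 0.060,
        "PromP": 0.010, "PromBiv": 0.009, "ReprPC": 0.040,
    }
    props["Quies"] = 1.0 - sum(props.values())
    return props


@dataclass
class GenomeSpec:
    n_chroms: int = 2
    chrom_length: int = 1_000_000


@dataclass
class SegmentationSpec:
    proportions: dict[str, float] = field(default_factory=_default_state_proportions)
    mean_segment_length: int = 1_000


@dataclass
class PeakSpec:
    n: int = 1_000
    length_mean: int = 500
    length_sd: int = 150
    min_length: int = 50
    target_states: tuple[str, ...] = ("TssA", "PromD1")
    planted_fraction: float = 0.8


@dataclass
class CoverageSpec:
    n_anchors: int = 200
    offset_bp: int = -175         # summit upstream of the TSS, gene orientation
    amplitude: float = 10.0
    bump_sd: float = 75.0
    noise_frac: float = 0.1       # noise sigma as a fraction of amplitude
    window_bp: int = 2_500        # half-width of the simulated window per anchor
    step_bp: int = 10             # bedGraph run resolution


@dataclass
class MsaSpec:
    ref_length: int = 300
    n_rows: int = 200
    target_bits: tuple[float, ...] | None = None  # default: seeded uniform draw
    paralogue: str = "KMT2A"


@dataclass
class MutationSpec:
    gene: str = "KMT2C"
    protein_length: int = 4_000
    region_start: int = 901
    region_end: int = 1_100
    region_multiplier: float = 5.0
    motif_multiplier: float = 3.0
    n_records: int = 5_000
    unknown_fraction: float = 0.33
    wgs_fraction: float = 0.9
    missense_fraction: float = 0.7
    tissue_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "haematopoietic_and_lymphoid": 0.4,
            "large_intestine": 0.25,
            "lung": 0.2,
            "breast": 0.15,
        }
    )


@dataclass
class SyntheticSpec:
    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    segmentation: SegmentationSpec = field(default_factory=SegmentationSpec)
    peaks: PeakSpec = field(default_factory=PeakSpec)
    coverage: CoverageSpec = field(default_factory=CoverageSpec)
    msa: MsaSpec = field(default_factory=MsaSpec)
    mutations: MutationSpec = field(default_factory=MutationSpec)

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticSpec":
        kwargs = {"seed": int(data.get("seed", 0))}
        for name, sub in (
            ("genome", GenomeSpec),
            ("segmentation", SegmentationSpec),
            ("peaks", PeakSpec),
            ("coverage", CoverageSpec),
            ("msa", MsaSpec),
            ("mutations", MutationSpec),
        ):
            if name in data:
                kwargs[name] = sub(**data[name])
        return cls(**kwargs)


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec_seed, stream])


# ---------------------------------------------------------------------------
# Genome and segmentation


def make_genome(spec: SyntheticSpec) -> GenomeLayout:
    g = spec.genome
    if g.n_chroms < 1:
        raise ValueError("need at least one chromosome")
    names = tuple(f"chr{i + 1}" for i in range(g.n_chroms))
    return GenomeLayout(names, tuple([g.chrom_length] * g.n_chroms))


def make_segmentation(layout: GenomeLayout, spec: SyntheticSpec) -> Segmentation:
    """Partition every chromosome into state-labelled segments.

    Segment lengths are geometric with the stated mean (memoryless, HMM-
    like); states are assigned by largest base-pair deficit against the
    target proportions, then the segment order is shuffled, which pins the
    realized per-state shares to the targets far inside the 2% band.
    """
    seg_spec = spec.segmentation
    props = seg_spec.proportions
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("state proportions must sum to 1")
    states = list(props)
    alphabet = tuple(
        s for s in ROADMAP_25_STATES if s in props
    ) or tuple(states)
    rng = _rng(spec.seed, 1)
    segments: list[GenomicInterval] = []
    for chrom, clen in layout.sizes.items():
        if len(states) == 1:
            segments.append(GenomicInterval(chrom, 0, clen, states[0]))
            continue
        lengths: list[int] = []
        total = 0
        while total < clen:
            l = int(rng.geometric(1.0 / seg_spec.mean_segment_length))
            l = min(l, clen - total)
            lengths.append(l)
            total += l
        order = rng.permutation(len(lengths))
        assigned_bp = {s: 0.0 for s in states}
        labels: list[str | None] = [None] * len(lengths)
        target = {s: props[s] * clen for s in states}
        for i in order:
            deficits = {s: target[s] - assigned_bp[s] for s in states}
            best = max(deficits, key=lambda s: (deficits[s], s))
            labels[i] = best
            assigned_bp[best] += lengths[i]
        pos = 0
        for l, s in zip(lengths, labels):
            segments.append(GenomicInterval(chrom, pos, pos + l, s))
            pos += l
    return Segmentation(
        IntervalSet(segments, layout=layout), alphabet=alphabet
    )


# ---------------------------------------------------------------------------
# Peaks


def make_peaks(
    seg: Segmentation, spec: SyntheticSpec
) -> tuple[IntervalSet, np.ndarray]:
    """Peaks with a planted fraction of midpoints inside target states.

    Returns the peak set plus a boolean sidecar array marking which peaks
    were planted inside a target-state segment.
    """
    pk = spec.peaks
    layout = seg.segments.layout
    by_state = seg.by_state()
    missing = [s for s in pk.target_states if s not in by_state]
    if missing:
        raise ValueError(f"target states missing from segmentation: {missing}")
    target_ivs = [
        iv for s in pk.target_states for iv in by_state[s]
    ]
    if not target_ivs:
        raise ValueError("target states cover zero base pairs")
    other_ivs = [
        iv
        for s, iset in by_state.items()
        if s not in pk.target_states
        for iv in iset
    ]
    rng = _rng(spec.seed, 2)

    def sample_midpoint(ivs: list[GenomicInterval]) -> tuple[str, int]:
        weights = np.array([len(iv) for iv in ivs], dtype=float)
        iv = ivs[int(rng.choice(len(ivs), p=weights / weights.sum()))]
        return iv.chrom, int(rng.integers(iv.start, iv.end))

    sizes = layout.sizes if layout else {}
    peaks: list[GenomicInterval] = []
    planted = np.zeros(pk.n, dtype=bool)
    for i in range(pk.n):
        in_target = bool(rng.random() < pk.planted_fraction)
        planted[i] = in_target
        chrom, mid = sample_midpoint(target_ivs if in_target else other_ivs)
        length = max(pk.min_length, int(round(rng.normal(pk.length_mean, pk.length_sd))))
        start = mid - length // 2
        end = start + length
        clen = sizes.get(chrom, end)
        if start < 0:
            start, end = 0, length
        if end > clen:
            end, start = clen, clen - length
        peaks.append(GenomicInterval(chrom, start, end, f"peak_{i}"))
    return IntervalSet(peaks, layout=layout), planted


def make_tss(layout: GenomeLayout, spec: SyntheticSpec) -> IntervalSet:
    """Random stranded single-base TSS anchors, clear of chromosome ends."""
    cov = spec.coverage
    rng = _rng(spec.seed, 3)
    chroms = list(layout.chrom_names)
    anchors = []
    margin = cov.window_bp + 100
    for i in range(cov.n_anchors):
        chrom = chroms[int(rng.integers(len(chroms)))]
        clen = layout.sizes[chrom]
        pos = int(rng.integers(margin, clen - margin))
        strand = "+" if rng.random() < 0.5 else "-"
        anchors.append(GenomicInterval(chrom, pos, pos + 1, f"tss_{i}", None, strand))
    return IntervalSet(anchors, layout=layout)


# ---------------------------------------------------------------------------
# Coverage


def make_coverage(
    layout: GenomeLayout, anchors: IntervalSet, spec: SyntheticSpec
) -> CoverageTrack:
    """Gaussian coverage bump at a fixed signed offset from every anchor.

    The bump is centered ``offset_bp`` from the anchor in gene orientation
    (mirrored in genome coordinates for "-" anchors) with truncated-
    Gaussian noise added in ``step_bp`` runs; bases outside the anchor
    windows stay at zero.
    """
    cov = spec.coverage
    rng = _rng(spec.seed, 4)
    noise_sd = cov.noise_frac * cov.amplitude
    per_chrom_steps: dict[str, dict[int, float]] = {c: {} for c in layout.chrom_names}
    for iv in anchors:
        if len(iv) != 1:
            raise ValueError("anchors must be single-base")
        sign = 1 if iv.strand != "-" else -1
        center = iv.start + sign * cov.offset_bp
        clen = layout.sizes[iv.chrom]
        lo = max(0, iv.start - cov.window_bp)
        hi = min(clen, iv.start + cov.window_bp)
        steps = per_chrom_steps[iv.chrom]
        for s in range(lo - lo % cov.step_bp, hi, cov.step_bp):
            x = s + cov.step_bp / 2.0
            bump = cov.amplitude * math.exp(
                -((x - center) ** 2) / (2.0 * cov.bump_sd**2)
            )
            noise = max(0.0, float(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 0.0
            steps[s] = steps.get(s, 0.0) + bump + noise
    runs: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, steps in per_chrom_steps.items():
        if not steps:
            continue
        chrom_runs = []
        clen = layout.sizes[chrom]
        for s in sorted(steps):
            v = round(steps[s], 4)
            e = min(s + cov.step_bp, clen)
            if v > 0 and s < e:
                if chrom_runs and chrom_runs[-1][1] == s and chrom_runs[-1][2] == v:
                    chrom_runs[-1] = (chrom_runs[-1][0], e, v)
                else:
                    chrom_runs.append((s, e, v))
        runs[chrom] = chrom_runs
    return CoverageTrack.from_runs(runs)


# ---------------------------------------------------------------------------
# MSA


def consensus_probability(bits: float) -> float:
    """Consensus-residue probability whose two-level column (consensus +
    uniform remainder over the other 19) has the given conservation bits."""
    if bits < -1e-9 or bits > MAX_BITS + 1e-9:
        raise ValueError(f"bits target {bits} outside [0, log2(20)]")
    bits = min(max(bits, 0.0), MAX_BITS)

    def column_bits(q: float) -> float:
        if q >= 1.0:
            return MAX_BITS
        h = -q * math.log2(q) - (1 - q) * math.log2((1 - q) / 19.0)
        return MAX_BITS - h

    lo, hi = 1.0 / 20.0, 1.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if column_bits(mid) < bits:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def make_msa(spec: SyntheticSpec) -> tuple[Alignment, np.ndarray]:
    """Gapless MSA whose columns hit per-position conservation targets.

    Each column is a two-level mixture: the consensus residue with the
    probability solving the entropy equation for the target bits, the
    remaining mass uniform over the other 19 amino acids. The reference
    row is the consensus itself. Returns (alignment, target bits).
    """
    ms = spec.msa
    rng = _rng(spec.seed, 5)
    if ms.target_bits is None:
        targets = rng.uniform(0.0, MAX_BITS, size=ms.ref_length)
    else:
        targets = np.asarray(ms.target_bits, dtype=float)
        if len(targets) != ms.ref_length:
            raise ValueError("target_bits length != ref_length")
    aa = np.array(list(AMINO_ACIDS))
    consensus_idx = rng.integers(0, 20, size=ms.ref_length)
    qs = np.array([consensus_probability(b) for b in targets])
    columns = np.empty((ms.n_rows, ms.ref_length), dtype="<U1")
    for j in range(ms.ref_length):
        others = np.delete(np.arange(20), consensus_idx[j])
        take_consensus = rng.random(ms.n_rows) < qs[j]
        draw = rng.integers(0, 19, size=ms.n_rows)
        col_idx = np.where(take_consensus, consensus_idx[j], others[draw])
        columns[:, j] = aa[col_idx]
    ref_id = "REF_HUMAN"
    rows = [
        ProteinSequence(
            id=ref_id,
            residues="".join(aa[consensus_idx]),
            species="Homo sapiens",
            paralogue=ms.paralogue,
        )
    ]
    for i in range(ms.n_rows):
        rows.append(
            ProteinSequence(
                id=f"seq{i}",
                residues="".join(columns[i]),
                species=f"species_{i}",
                paralogue=ms.paralogue,
            )
        )
    return Alignment(rows=rows, reference_id=ref_id), targets


# ---------------------------------------------------------------------------
# Mutations

_MOTIF_SLOTS = ("C1", "C2", "C3", "C4", "H1", "C5", "C6", "C7/H2")
_SLOT_OFFSETS = (1, 4, 17, 20, 25, 45, 48, 51)  # within each ~65-residue PHD


def default_phd_annotation(spec: MutationSpec) -> RegionAnnotation:
    """A clustered-PHD annotation with three domains and C4HC2C/H slots."""
    slots: dict[str, list[int]] = {s: [] for s in _MOTIF_SLOTS}
    domain_starts = [spec.region_start + 67 * k for k in range(3)]
    for d0 in domain_starts:
        for slot, off in zip(_MOTIF_SLOTS, _SLOT_OFFSETS):
            slots[slot].append(d0 + off)
    return RegionAnnotation(
        name="PHD_cluster",
        gene=spec.gene,
        ranges=[(spec.region_start, spec.region_end)],
        motif_slots=slots,
    )


def make_mutations(
    spec: SyntheticSpec,
) -> tuple[list[MutationRecord], dict[str, str], RegionAnnotation]:
    """COSMIC-like mutation records with planted region/motif multipliers.

    Missense positions are drawn from per-residue weights: 1 outside the
    annotated region, x region_multiplier inside it, and an extra
    x motif_multiplier at motif-slot residues. A stated fraction of WGS
    records is marked 'unknown'; non-WGS records are 'targeted'.
    """
    mu = spec.mutations
    rng = _rng(spec.seed, 6)
    annotation = default_phd_annotation(mu)
    weights = np.ones(mu.protein_length)
    for s, e in annotation.ranges:
        weights[s - 1 : e] *= mu.region_multiplier
    for residues in annotation.motif_slots.values():
        for r in residues:
            weights[r - 1] *= mu.motif_multiplier
    weights /= weights.sum()
    tissues = list(mu.tissue_proportions)
    tprobs = np.array([mu.tissue_proportions[t] for t in tissues])
    tprobs = tprobs / tprobs.sum()
    other_consequences = ("nonsense", "frameshift", "inframe_indel", "synonymous")
    records: list[MutationRecord] = []
    samples: dict[str, str] = {}
    for i in range(mu.n_records):
        sample_id = f"S{i:06d}"
        tissue = tissues[int(rng.choice(len(tissues), p=tprobs))]
        samples[sample_id] = tissue
        is_wgs = bool(rng.random() < mu.wgs_fraction)
        if bool(rng.random() < mu.unknown_fraction):
            consequence = "unknown"
            position = None
        elif bool(rng.random() < mu.missense_fraction):
            consequence = "missense"
            position = int(rng.choice(mu.protein_length, p=weights)) + 1
        else:
            consequence = other_consequences[int(rng.integers(len(other_consequences)))]
            position = int(rng.integers(1, mu.protein_length + 1))
        records.append(
            MutationRecord(
                gene=mu.gene,
                sample_id=sample_id,
                consequence=consequence,
                screen_type="WGS" if is_wgs else "targeted",
                tissue=tissue,
                aa_position=position,
            )
        )
    return records, samples, annotation


# ---------------------------------------------------------------------------
# Writing everything out


def write_all(spec: SyntheticSpec, outdir) -> dict:
    """Generate every input and write it in the formats the analyses read.

    Produces genome.sizes, segmentation.bed, peaks.bed (+ truth sidecar),
    tss.bed, coverage.bedgraph, msa.fasta, mutations.tsv, samples.tsv,
    regions.tsv, motifs.tsv and a truth.json with the planted parameters.
    """
    from .intervals import write_bed
    from .metaprofile import write_bedgraph

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = make_genome(spec)
    with open(outdir / "genome.sizes", "w") as fh:
        for name, length in layout.sizes.items():
            fh.write(f"{name}\t{length}\n")
    seg = make_segmentation(layout, spec)
    with open(outdir / "segmentation.bed", "w") as fh:
        for iv in seg.segments:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
    with open(outdir / "states.txt", "w") as fh:
        fh.write("\n".join(seg.alphabet) + "\n")
    peaks, planted = make_peaks(seg, spec)
    write_bed(peaks, outdir / "peaks.bed")
    with open(outdir / "peaks_truth.tsv", "w") as fh:
        fh.write("peak\tplanted\n")
        for iv, flag in zip(peaks, planted):
            fh.write(f"{iv.name}\t{int(flag)}\n")
    tss = make_tss(layout, spec)
    write_bed(tss, outdir / "tss.bed")
    track = make_coverage(layout, tss, spec)
    write_bedgraph(track, outdir / "coverage.bedgraph")
    aln, targets = make_msa(spec)
    with open(outdir / "msa.fasta", "w") as fh:
        for row in aln.rows:
            fh.write(f">{row.id}|{row.species}|{row.paralogue}\n{row.residues}\n")
    records, samples, annotation = make_mutations(spec)
    with open(outdir / "mutations.tsv", "w") as fh:
        fh.write(
            "Gene name\tID_sample\tAA position\tMutation Description\t"
            "Screen type\tPrimary site\n"
        )
        inverse = {v: k for k, v in
                   {"Substitution - Missense": "missense",
                    "Substitution - Nonsense": "nonsense",
                    "Deletion - Frameshift": "frameshift",
                    "Deletion - In frame": "inframe_indel",
                    "Substitution - coding silent": "synonymous",
                    "Unknown": "unknown"}.items()}
        for r in records:
            pos = "" if r.aa_position is None else str(r.aa_position)
            fh.write(
                f"{r.gene}\t{r.sample_id}\t{pos}\t{inverse[r.consequence]}\t"
                f"{r.screen_type}\t{r.tissue}\n"
            )
    with open(outdir / "samples.tsv", "w") as fh:
        fh.write("ID_sample\tPrimary site\n")
        for sid, tissue in samples.items():
            fh.write(f"{sid}\t{tissue}\n")
    with open(outdir / "regions.tsv", "w") as fh:
        fh.write("gene\tname\tstart\tend\n")
        for s, e in annotation.ranges:
            fh.write(f"{annotation.gene}\t{annotation.name}\t{s}\t{e}\n")
    with open(outdir / "motifs.tsv", "w") as fh:
        fh.write("gene\tdomain\tslot\tresidue\n")
        for slot, residues in annotation.motif_slots.items():
            for r in residues:
                fh.write(f"{annotation.gene}\t{annotation.name}\t{slot}\t{r}\n")
    truth = {
        "seed": spec.seed,
        "peak_planted_fraction": spec.peaks.planted_fraction,
        "peak_target_states": list(spec.peaks.target_states),
        "coverage_offset_bp": spec.coverage.offset_bp,
        "msa_target_bits": [float(b) for b in targets],
        "mutation_region_multiplier": spec.mutations.region_multiplier,
        "mutation_unknown_fraction": spec.mutations.unknown_fraction,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
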