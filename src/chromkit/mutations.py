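"""Somatic-mutation table analysis for chromatin-reader domains.

Works on COSMIC-style exports: a per-sample mutation table (gene, sample,
amino-acid position, consequence, screen type) and a sample-features table
mapping samples to tissues. The analyses are the standard domain-level
summaries: whole-genome-screen filtering, per-region missense density
(mutations per residue), zinc-chelating-motif (C4HC2C/H) position
frequencies, tissue distribution, and an exact binomial test for
enrichment of missense mutations inside a region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "CONSEQUENCES",
    "DEFAULT_COSMIC_SCHEMA",
    "MutationRecord",
    "RegionAnnotation",
    "DensityReport",
    "load_mutation_table",
    "load_sample_table",
    "load_region_annotations",
    "load_motif_slots",
    "filter_known_wgs",
    "region_density",
    "motif_position_frequency",
    "tissue_distribution",
    "region_enrichment_test",
]

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "synonymous",
    "unknown",
)

# Column mapping + consequence vocabulary for COSMIC-style exports. The
# schema is external so the loader is not pinned to one release's headers.
DEFAULT_COSMIC_SCHEMA: dict = {
    "columns": {
        "gene": "Gene name",
        "sample_id": "ID_sample",
        "aa_position": "AA position",
        "consequence": "Mutation Description",
        "screen_type": "Screen type",
        "tissue": "Primary site",
    },
    "consequence_map": {
        "Substitution - Missense": "missense",
        "Substitution - Nonsense": "nonsense",
        "Substitution - coding silent": "synonymous",
        "Deletion - Frameshift": "frameshift",
        "Insertion - Frameshift": "frameshift",
        "Deletion - In frame": "inframe_indel",
        "Insertion - In frame": "inframe_indel",
        "Unknown": "unknown",
    },
    "wgs_values": {"WGS", "genome-wide screen", "y"},
}


@dataclass(frozen=True)
class MutationRecord:
    gene: str
    sample_id: str
    consequence: str
    screen_type: str
    tissue: str = ""
    aa_position: int | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"consequence {self.consequence!r} not in vocabulary")
        if self.aa_position is not None and self.aa_position < 1:
            raise ValueError("aa_position must be >= 1")


@dataclass
class RegionAnnotation:
    """Named residue ranges (1-based inclusive) plus optional motif slots.

    ``motif_slots`` maps a slot label (C1..C4, H1, C5, C6, C7/H2) to the
    list of residue positions filling that slot across the annotation's
    domains.
    """

    name: str
    gene: str
    ranges: list[tuple[int, int]]
    motif_slots: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spans = sorted(self.ranges)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping ranges in annotation {self.name!r}")
        for s, e in self.ranges:
            if s < 1 or s > e:
                raise ValueError(f"bad range ({s},{e}) in annotation {self.name!r}")
        for slot, residues in self.motif_slots.items():
            for r in residues:
                if not self.contains(r):
                    raise ValueError(
                        f"motif slot {slot!r} residue {r} outside annotation ranges"
                    )

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.ranges)

    @property
    def n_residues(self) -> int:
        return sum(e - s + 1 for s, e in self.ranges)


@dataclass(frozen=True)
class DensityReport:
    gene: str
    region: str
    n_missense: int
    n_residues: int

    @property
    def density(self) -> float:
        return self.n_missense / self.n_residues


# ---------------------------------------------------------------------------
# Loading


def load_mutation_table(path, schema: dict | None = None) -> list[MutationRecord]:
    """Read a delimited mutation table using a column-mapping schema.

    Consequence strings are normalized to the closed vocabulary; rows
    whose consequence is not in the schema's map are tagged ``unknown``.
    """
    schema = schema or DEFAULT_COSMIC_SCHEMA
    cols = schema["columns"]
    cmap = schema["consequence_map"]
    wgs_values = set(schema.get("wgs_values", {"WGS"}))
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise KeyError(f"mutation table lacks mapped columns: {missing}")
    records = []
    for _, row in df.iterrows():
        raw_pos = row[cols["aa_position"]]
        aa_position = None
        if pd.notna(raw_pos) and str(raw_pos).strip() not in ("", "."):
            aa_position = int(float(raw_pos))
        screen_raw = str(row[cols["screen_type"]]).strip()
        records.append(
            MutationRecord(
                gene=str(row[cols["gene"]]),
                sample_id=str(row[cols["sample_id"]]),
                consequence=cmap.get(str(row[cols["consequence"]]).strip(), "unknown"),
                screen_type="WGS" if screen_raw in wgs_values else "targeted",
                tissue=str(row[cols["tissue"]]) if cols.get("tissue") in df.columns else "",
                aa_position=aa_position,
            )
        )
    return records


def load_sample_table(path, sample_col: str = "ID_sample", tissue_col: str = "Primary site") -> dict[str, str]:
    df = pd.read_csv(path, sep=None, engine="python")
    return {str(s): str(t) for s, t in zip(df[sample_col], df[tissue_col])}


def load_region_annotations(path) -> list[RegionAnnotation]:
    """TSV with columns gene, name, start, end; rows of one (gene, name)
    combine into one multi-range annotation."""
    df = pd.read_csv(path, sep="\t")
    anns: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for _, row in df.iterrows():
        anns.setdefault((str(row["gene"]), str(row["name"])), []).append(
            (int(row["start"]), int(row["end"]))
        )
    return [
        RegionAnnotation(name=name, gene=gene, ranges=ranges)
        for (gene, name), ranges in anns.items()
    ]


def load_motif_slots(path, annotations: list[RegionAnnotation]) -> None:
    """TSV with columns gene, domain, slot, residue; attaches slots in place."""
    df = pd.read_csv(path, sep="\t")
    by_gene = {(a.gene, a.name): a for a in annotations}
    for _, row in df.iterrows():
        key = (str(row["gene"]), str(row["domain"]))
        if key not in by_gene:
            raise KeyError(f"no annotation for {key}")
        ann = by_gene[key]
        residue = int(row["residue"])
        if not ann.contains(residue):
            raise ValueError(
                f"slot residue {residue} outside annotation {ann.name!r}"
            )
        ann.motif_slots.setdefault(str(row["slot"]), []).append(residue)


# ---------------------------------------------------------------------------
# Analyses


def filter_known_wgs(
    records: list[MutationRecord],
) -> tuple[list[MutationRecord], float]:
    """Keep whole-genome-screen records with a known consequence.

    Returns the kept records and the fraction removed. Idempotent.
    """
    kept = [
        r for r in records if r.screen_type == "WGS" and r.consequence != "unknown"
    ]
    removed = 1.0 - len(kept) / len(records) if records else 0.0
    return kept, removed


def region_density(
    records: list[MutationRecord],
    regions: list[RegionAnnotation],
) -> list[DensityReport]:
    """Missense mutations per residue, per gene and region."""
    reports = []
    for region in regions:
        if region.n_residues == 0:
            raise ValueError(f"region {region.name!r} has zero residues")
        n = sum(
            1
            for r in records
            if r.gene == region.gene
            and r.consequence == "missense"
            and r.aa_position is not None
            and region.contains(r.aa_position)
        )
        reports.append(
            DensityReport(
                gene=region.gene,
                region=region.name,
                n_missense=n,
                n_residues=region.n_residues,
            )
        )
    return reports


def motif_position_frequency(
    records: list[MutationRecord],
    regions: list[RegionAnnotation],
) -> pd.DataFrame:
    """Missense counts per zinc-chelating motif slot, per gene plus overall.

    Slots (C1..C4, H1, C5, C6, C7/H2) aggregate across the PHD domains of
    each gene; the ``all`` row sums over genes.
    """
    slot_order: list[str] = []
    for region in regions:
        for slot in region.motif_slots:
            if slot not in slot_order:
                slot_order.append(slot)
    if not slot_order:
        raise ValueError("no motif slots defined on the annotations")
    genes = sorted({r.gene for r in regions})
    counts = pd.DataFrame(0, index=genes + ["all"], columns=slot_order)
    for region in regions:
        gene_records = [
            r
            for r in records
            if r.gene == region.gene
            and r.consequence == "missense"
            and r.aa_position is not None
        ]
        for slot, residues in region.motif_slots.items():
            residue_set = set(residues)
            n = sum(1 for r in gene_records if r.aa_position in residue_set)
            counts.loc[region.gene, slot] += n
            counts.loc["all", slot] += n
    return counts


def tissue_distribution(
    records: list[MutationRecord],
    samples: dict[str, str],
) -> pd.DataFrame:
    """Tissue x consequence contingency counts.

    Sample ids absent from the sample table are counted under the
    ``unassigned`` tissue.
    """
    rows = []
    for r in records:
        rows.append((samples.get(r.sample_id, "unassigned"), r.consequence))
    df = pd.DataFrame(rows, columns=["tissue", "consequence"])
    return (
        df.groupby(["tissue", "consequence"], sort=True)
        .size()
        .unstack(fill_value=0)
    )


def region_enrichment_test(
    records: list[MutationRecord],
    region: RegionAnnotation,
    protein_length: int,
    randomized: bool = False,
    rng=None,
) -> tuple[int, float, float]:
    """Exact two-sided binomial test of missense enrichment in a region.

    Under a uniform null, the count of missense mutations landing in the
    region is Binomial(n_total, region_residues / protein_length).
    Returns (observed, expected, p).

    The exact p-value of a discrete test is super-uniform (conservative)
    under the null; ``randomized=True`` smooths the tie mass with a
    uniform draw, giving a p-value that is exactly Uniform(0,1) under the
    null — the appropriate variant for calibration diagnostics.
    """
    if protein_length < region.n_residues:
        raise ValueError("protein shorter than region")
    missense = [
        r
        for r in records
        if r.gene == region.gene
        and r.consequence == "missense"
        and r.aa_position is not None
    ]
    n_total = len(missense)
    if n_total == 0:
        raise ValueError("no missense mutations: test undefined")
    observed = sum(1 for r in missense if region.contains(r.aa_position))
    p_null = region.n_residues / protein_length
    expected = n_total * p_null
    if p_null >= 1.0:
        return observed, expected, 1.0
    if randomized:
        import numpy as np
        from scipy.stats import binom

        rng = np.random.default_rng() if rng is None else rng
        pmf = binom.pmf(np.arange(n_total + 1), n_total, p_null)
        pk = pmf[observed]
        lower = pmf[pmf < pk * (1 - 1e-12)].sum()
        ties = pmf[np.abs(pmf - pk) <= pk * 1e-12].sum()
        return observed, expected, float(min(1.0, lower + rng.random() * ties))
    result = binomtest(observed, n_total, p_null, alternative="two-sided")
    return observed, expected, float(result.pvalue)
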