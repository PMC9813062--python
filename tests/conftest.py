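import numpy as np
import pytest

from chromkit.intervals import GenomeLayout, GenomicInterval, IntervalSet


@pytest.fixture
def toy_layout():
    return GenomeLayout(("chr1", "chr2"), (10_000, 8_000))


def base_mask(iset: IntervalSet, layout: GenomeLayout) -> dict[str, np.ndarray]:
    """Exhaustive per-base boolean mask of an interval set (oracle)."""
    masks = {c: np.zeros(l, dtype=bool) for c, l in layout.sizes.items()}
    for iv in iset:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def random_interval_set(
    rng: np.random.Generator,
    layout: GenomeLayout,
    n: int,
    max_len: int = 500,
) -> IntervalSet:
    ivs = []
    chroms = list(layout.chrom_names)
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        clen = layout.sizes[chrom]
        start = int(rng.integers(0, clen - 1))
        end = int(rng.integers(start + 1, min(start + max_len, clen) + 1))
        ivs.append(GenomicInterval(chrom, start, end))
    return IntervalSet(ivs, layout=layout)
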