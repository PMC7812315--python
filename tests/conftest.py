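import numpy as np
import pandas as pd
import pytest

from chromprime.intervals import GeneAnnotation, GenomicInterval, Peak, PeakSet


def make_peaks(rows, label="test"):
    """rows: (chrom, start, end[, summit[, name]]) tuples."""
    peaks = []
    for i, row in enumerate(rows):
        chrom, start, end = row[:3]
        summit = row[3] if len(row) > 3 else (start + end) // 2
        name = row[4] if len(row) > 4 else f"{label}_{i}"
        peaks.append(Peak(GenomicInterval(chrom, start, end), summit, name))
    return PeakSet(peaks, label=label)


def random_peakset(rng, n, chrom="chr1", span=1_000_000, width_range=(100, 500), label="rand"):
    starts = np.sort(rng.integers(0, span, size=n))
    widths = rng.integers(*width_range, size=n)
    rows = []
    for i, (s, w) in enumerate(zip(starts, widths)):
        summit = int(s + rng.integers(0, w))
        rows.append((chrom, int(s), int(s + w), summit, f"{label}_{i}"))
    return make_peaks(rows, label=label)


@pytest.fixture
def gene_table():
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["geneA", "geneB", "geneC"],
                "chrom": ["chr1", "chr1", "chr2"],
                "strand": ["+", "-", "+"],
                "tss": [4_000, 20_000, 1_000],
            }
        )
    )
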