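import numpy as np
import pytest

from peakrank.genemodel import GeneModel, GeneRecord
from peakrank.intervals import GenomicInterval, PeakSet
from peakrank.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """Desk-scale scenario for module tests: small genome, few plants."""
    return SimulationConfig(
        n_genes=60,
        chrom_sizes={"chrA": 3_000_000, "chrB": 2_000_000},
        n_planted_targets=8,
        n_planted_decoys=8,
        n_background_peaks=150,
        n_background_histone_sites=40,
        seed=7,
    )


@pytest.fixture
def toy_model():
    """Two genes on one chromosome, one per strand, with CDS.

    geneP (+): tx 10000-20000, exons [10000,12000) and [18000,20000),
    CDS 11000-19000, TSS 10000.
    geneM (-): tx 40000-50000, exons [40000,43000) and [47000,50000),
    CDS 41000-49000, TSS 49999.
    """
    return GeneModel([
        GeneRecord(
            gene_id="geneP", chrom="chr1", strand="+", tss=10_000,
            tx_start=10_000, tx_end=20_000,
            exon_starts=(10_000, 18_000), exon_ends=(12_000, 20_000),
            cds_start=11_000, cds_end=19_000,
        ),
        GeneRecord(
            gene_id="geneM", chrom="chr1", strand="-", tss=49_999,
            tx_start=40_000, tx_end=50_000,
            exon_starts=(40_000, 47_000), exon_ends=(43_000, 50_000),
            cds_start=41_000, cds_end=49_000,
        ),
    ])


def random_intervals(rng, n, chrom_names=("c1", "c2"), chrom_len=10_000, max_width=400):
    out = []
    for _ in range(n):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        start = int(rng.integers(0, chrom_len - 1))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(chrom, start, min(start + width, chrom_len)))
    return out


def random_peak_sets(rng, n_reps, group="TIL", n_peaks=30, **kw):
    return [
        PeakSet(sample_id=f"{group}_{i + 1}", group=group,
                intervals=random_intervals(rng, n_peaks, **kw))
        for i in range(n_reps)
    ]
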