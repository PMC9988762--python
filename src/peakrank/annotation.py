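"""Genomic-feature annotation of binding sites and per-category enrichment
testing of differential sites.

Each site is classified by its midpoint into exactly one category using the
precedence Promoter > FiveUTR > ThreeUTR > Exon > Intron > Downstream >
DistalIntergenic (the hierarchy of the usual ChIP annotators).  The promoter
window defaults to -3000/+3000 bp around the TSS, strand-aware and inclusive
at both edges; Downstream is the 3000 bp window past the transcript end.
UTR calls need a CDS in the gene model; genes without one yield plain Exon.

Per-category enrichment of differential sites against the full consensus
set uses the two-sided Fisher exact test (sum of hypergeometric
probabilities <= the observed table's), Benjamini-Hochberg adjusted across
categories.
"""

from __future__ import annotations

import enum
import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ValidationError
from .genemodel import GeneModel, GeneRecord
from .intervals import GenomicInterval

log = logging.getLogger(__name__)


class AnnotationCategory(enum.Enum):
    Promoter = "Promoter"
    FiveUTR = "FiveUTR"
    ThreeUTR = "ThreeUTR"
    Exon = "Exon"
    Intron = "Intron"
    Downstream = "Downstream"
    DistalIntergenic = "DistalIntergenic"


#: Precedence when a midpoint hits features of several (overlapping) genes.
PRECEDENCE = [
    AnnotationCategory.Promoter,
    AnnotationCategory.FiveUTR,
    AnnotationCategory.ThreeUTR,
    AnnotationCategory.Exon,
    AnnotationCategory.Intron,
    AnnotationCategory.Downstream,
    AnnotationCategory.DistalIntergenic,
]
_RANK = {c: i for i, c in enumerate(PRECEDENCE)}


@dataclass(frozen=True)
class AnnotatedSite:
    site: GenomicInterval
    category: AnnotationCategory
    nearest_gene: str | None
    distance_to_tss: int | None  # signed; negative = upstream of TSS in gene orientation


@dataclass(frozen=True)
class RegionEnrichmentResult:
    category: AnnotationCategory
    a: int  # differential, in category
    b: int  # differential, not in category
    c: int  # non-differential, in category
    d: int  # non-differential, not in category
    odds_ratio: float
    p_value: float
    adjusted_p: float


def _category_for_gene(
    m: int,
    g: GeneRecord,
    promoter_window: tuple[int, int],
    downstream_window: int,
) -> AnnotationCategory | None:
    """Feature class of midpoint ``m`` relative to one gene, or None."""
    up, down = promoter_window
    if g.strand == "+":
        if g.tss - up <= m <= g.tss + down:
            return AnnotationCategory.Promoter
    else:
        if g.tss - down <= m <= g.tss + up:
            return AnnotationCategory.Promoter
    if g.tx_start <= m < g.tx_end:
        in_exon = any(s <= m < e for s, e in zip(g.exon_starts, g.exon_ends))
        if not in_exon:
            return AnnotationCategory.Intron
        if g.cds_start is None:
            return AnnotationCategory.Exon
        if g.strand == "+":
            if m < g.cds_start:
                return AnnotationCategory.FiveUTR
            if m >= g.cds_end:
                return AnnotationCategory.ThreeUTR
        else:
            if m >= g.cds_end:
                return AnnotationCategory.FiveUTR
            if m < g.cds_start:
                return AnnotationCategory.ThreeUTR
        return AnnotationCategory.Exon
    if g.strand == "+":
        if g.tx_end <= m <= g.tx_end + downstream_window:
            return AnnotationCategory.Downstream
    else:
        if g.tx_start - downstream_window <= m < g.tx_start:
            return AnnotationCategory.Downstream
    return None


class _ChromIndex:
    """Sorted per-chromosome gene lookup for midpoint queries."""

    def __init__(self, genes: list[GeneRecord]):
        self.genes = genes  # sorted by (tx_start, gene_id)
        self.tx_starts = [g.tx_start for g in genes]
        ends = np.array([g.tx_end for g in genes], dtype=np.int64)
        self.cummax_end = np.maximum.accumulate(ends) if len(genes) else ends
        # TSS-sorted view for nearest-gene queries
        self.tss_order = sorted(genes, key=lambda g: (g.tss, g.gene_id))
        self.tss_sorted = [g.tss for g in self.tss_order]

    def candidates(self, m: int, reach: int) -> list[GeneRecord]:
        """Genes whose extended footprint [tx_start - reach, tx_end + reach]
        could contain ``m``."""
        hi = bisect_right(self.tx_starts, m + reach)
        lo = int(np.searchsorted(self.cummax_end[:hi], m - reach, side="left"))
        return self.genes[lo:hi]

    def nearest(self, m: int) -> tuple[GeneRecord, int]:
        """Gene with minimal |m - tss|; ties broken by lexicographic id."""
        i = bisect_left(self.tss_sorted, m)
        best: tuple[int, str, GeneRecord] | None = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(self.tss_order):
                g = self.tss_order[j]
                cand = (abs(m - g.tss), g.gene_id, g)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        assert best is not None
        # scan equal-|distance| neighbors for the lexicographic winner
        dist = best[0]
        for j in range(i - 2, -1, -1):
            if abs(m - self.tss_sorted[j]) > dist:
                break
            g = self.tss_order[j]
            if (abs(m - g.tss), g.gene_id) < best[:2]:
                best = (abs(m - g.tss), g.gene_id, g)
        for j in range(i + 2, len(self.tss_order)):
            if abs(m - self.tss_sorted[j]) > dist:
                break
            g = self.tss_order[j]
            if (abs(m - g.tss), g.gene_id) < best[:2]:
                best = (abs(m - g.tss), g.gene_id, g)
        return best[2], best[0]


def annotate_sites(
    sites: Sequence[GenomicInterval],
    model: GeneModel,
    promoter_window: tuple[int, int] = (3000, 3000),
    downstream_window: int = 3000,
) -> list[AnnotatedSite]:
    """Annotate each site by midpoint; see module docstring for the rules.

    With an empty gene model every site is DistalIntergenic with an
    undefined nearest gene (logged once).
    """
    if len(model) == 0:
        log.warning("annotate_sites: empty gene model; all sites DistalIntergenic")
        return [
            AnnotatedSite(s, AnnotationCategory.DistalIntergenic, None, None) for s in sites
        ]
    indexes = {chrom: _ChromIndex(genes) for chrom, genes in model.by_chrom().items()}
    reach = max(promoter_window[0], promoter_window[1], downstream_window)
    out = []
    for s in sites:
        m = s.midpoint
        idx = indexes.get(s.chrom)
        if idx is None:
            out.append(AnnotatedSite(s, AnnotationCategory.DistalIntergenic, None, None))
            continue
        best = AnnotationCategory.DistalIntergenic
        for g in idx.candidates(m, reach):
            cat = _category_for_gene(m, g, promoter_window, downstream_window)
            if cat is not None and _RANK[cat] < _RANK[best]:
                best = cat
        gene, _ = idx.nearest(m)
        signed = m - gene.tss if gene.strand == "+" else gene.tss - m
        out.append(AnnotatedSite(s, best, gene.gene_id, int(signed)))
    return out


def annotate_site(
    site: GenomicInterval,
    model: GeneModel,
    promoter_window: tuple[int, int] = (3000, 3000),
    downstream_window: int = 3000,
) -> AnnotatedSite:
    return annotate_sites([site], model, promoter_window, downstream_window)[0]


def distribution_summary(annotated: Sequence[AnnotatedSite]) -> dict[AnnotationCategory, float]:
    """Fraction of sites per category (all categories present, zeros kept)."""
    if not annotated:
        raise DataError("distribution_summary requires a non-empty annotation list")
    n = len(annotated)
    counts = {c: 0 for c in AnnotationCategory}
    for a in annotated:
        counts[a.category] += 1
    return {c: counts[c] / n for c in AnnotationCategory}


def pooled_distal_fraction(summary: dict[AnnotationCategory, float]) -> float:
    """Rollup of the 'distal' classes (DistalIntergenic + Downstream), for
    reports that pool non-genic categories."""
    return summary[AnnotationCategory.DistalIntergenic] + summary[AnnotationCategory.Downstream]


def annotation_frame(annotated: Sequence[AnnotatedSite]) -> pd.DataFrame:
    rows = [
        {
            "site_id": a.site.name or f"{a.site.chrom}:{a.site.start}-{a.site.end}",
            "chrom": a.site.chrom,
            "start": a.site.start,
            "end": a.site.end,
            "category": a.category.value,
            "nearest_gene": a.nearest_gene,
            "distance_to_tss": a.distance_to_tss,
        }
        for a in annotated
    ]
    return pd.DataFrame(
        rows,
        columns=["site_id", "chrom", "start", "end", "category", "nearest_gene", "distance_to_tss"],
    )


def region_enrichment_test(
    differential_sites: Sequence[GenomicInterval],
    all_consensus_sites: Sequence[GenomicInterval],
    model: GeneModel,
    promoter_window: tuple[int, int] = (3000, 3000),
    downstream_window: int = 3000,
) -> list[RegionEnrichmentResult]:
    """Per-category 2x2 Fisher exact test of differential vs non-differential
    consensus sites.

    ``differential_sites`` must be a subset (by interval identity) of
    ``all_consensus_sites``.  Categories absent from both groups are omitted
    with a log note.  ``adjusted_p`` is BH across the tested categories.
    """
    cons_keys = {iv.key() for iv in all_consensus_sites}
    for iv in differential_sites:
        if iv.key() not in cons_keys:
            raise ValidationError(
                f"differential site {iv.chrom}:{iv.start}-{iv.end} not in the consensus set"
            )
    diff_keys = {iv.key() for iv in differential_sites}
    annotated = annotate_sites(all_consensus_sites, model, promoter_window, downstream_window)

    n_diff_by_cat = {c: 0 for c in AnnotationCategory}
    n_other_by_cat = {c: 0 for c in AnnotationCategory}
    n_diff = len(diff_keys)
    n_other = 0
    seen = set()
    for a in annotated:
        key = a.site.key()
        if key in seen:  # duplicated consensus intervals count once
            continue
        seen.add(key)
        if key in diff_keys:
            n_diff_by_cat[a.category] += 1
        else:
            n_other_by_cat[a.category] += 1
            n_other += 1

    results = []
    pvals = []
    for cat in AnnotationCategory:
        a = n_diff_by_cat[cat]
        c = n_other_by_cat[cat]
        if a + c == 0:
            log.info("region_enrichment_test: category %s absent from both groups; omitted", cat.value)
            continue
        b = n_diff - a
        d = n_other - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        results.append(RegionEnrichmentResult(cat, a, b, c, d, float(odds), float(p), np.nan))
        pvals.append(p)
    if results:
        adj = multipletests(pvals, method="fdr_bh")[1]
        results = [
            RegionEnrichmentResult(r.category, r.a, r.b, r.c, r.d, r.odds_ratio, r.p_value, float(q))
            for r, q in zip(results, adj)
        ]
    return results


def enrichment_frame(results: Sequence[RegionEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category.value,
                "diff_in": r.a,
                "diff_out": r.b,
                "other_in": r.c,
                "other_out": r.d,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
            }
            for r in results
        ],
        columns=[
            "category", "diff_in", "diff_out", "other_in", "other_out",
            "odds_ratio", "p_value", "adjusted_p",
        ],
    )


def plot_distribution(summary: dict[AnnotationCategory, float], path) -> None:
    """Simple bar chart of the category distribution."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    names = [c.value for c in AnnotationCategory]
    fracs = [summary[c] for c in AnnotationCategory]
    ax.bar(names, fracs, color="steelblue")
    ax.set_ylabel("fraction of sites")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
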