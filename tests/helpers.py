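"""Independent brute-force oracles used by the test suite.

Everything here recomputes results by a structurally different route than
the library (per-bp boolean masks, exhaustive enumeration, direct loops)
so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

from peakrank.intervals import GenomicInterval


# ---------------------------------------------------------------------------
# per-bp mask oracles (toy chromosomes only)


def _masks(intervals, chrom_len: int) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for iv in intervals:
        mask = out.setdefault(iv.chrom, np.zeros(chrom_len, dtype=bool))
        mask[iv.start : iv.end] = True
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def mask_merge(intervals, chrom_len: int = 10_000) -> list[GenomicInterval]:
    """Union of intervals as maximal runs of a per-bp boolean mask."""
    out = []
    for chrom in sorted({iv.chrom for iv in intervals}):
        mask = _masks([iv for iv in intervals if iv.chrom == chrom], chrom_len)[chrom]
        out.extend(GenomicInterval(chrom, s, e) for s, e in _runs(mask))
    return out


def mask_consensus(peak_sets, min_overlap: int, chrom_len: int = 10_000) -> list[GenomicInterval]:
    """Merged-pool intervals retained iff >= min_overlap replicates cover
    at least one bp of the interval."""
    pooled = [iv for ps in peak_sets for iv in ps.intervals]
    merged = mask_merge(pooled, chrom_len)
    rep_masks = []
    for ps in peak_sets:
        rep_masks.append(_masks(ps.intervals, chrom_len))
    kept = []
    for iv in merged:
        n = 0
        for masks in rep_masks:
            mask = masks.get(iv.chrom)
            if mask is not None and mask[iv.start : iv.end].any():
                n += 1
        if n >= min_overlap:
            kept.append(iv)
    return kept


def pairwise_overlap_count(query, reference) -> int:
    """O(n*m) scan: number of query intervals overlapping any reference."""
    n = 0
    for q in query:
        if any(
            q.chrom == r.chrom and q.start < r.end and r.start < q.end for r in reference
        ):
            n += 1
    return n


# ---------------------------------------------------------------------------
# Fisher exact (two-sided) by exhaustive fixed-margin enumeration


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Sum of hypergeometric probabilities of all tables with the observed
    margins whose probability is <= the observed table's."""
    n = a + b + c + d
    r1 = a + b
    k1 = a + c
    lo = max(0, r1 - (n - k1))
    hi = min(r1, k1)
    xs = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(xs, n, k1, r1)
    p_obs = hypergeom.pmf(a, n, k1, r1)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


# ---------------------------------------------------------------------------
# regulatory potential by direct loop


def rp_direct(tss: int, peaks, d0: float, window: float) -> float:
    s = 0.0
    for p in peaks:
        center = (p.start + p.end) // 2
        d = abs(center - tss)
        if d <= window:
            s += 2.0 ** (-d / d0)
    return s


# ---------------------------------------------------------------------------
# annotation by per-feature interval lookup


def annotation_oracle(m: int, chrom: str, genes, promoter_window=(3000, 3000), downstream_window=3000) -> str:
    """Build explicit per-feature interval lists and look the midpoint up in
    precedence order.  ``genes`` are GeneRecord-likes."""
    features: dict[str, list[tuple[str, int, int]]] = {
        "Promoter": [], "FiveUTR": [], "ThreeUTR": [], "Exon": [],
        "Intron": [], "Downstream": [],
    }
    up, down = promoter_window
    for g in genes:
        if g.chrom != chrom:
            continue
        if g.strand == "+":
            features["Promoter"].append((g.chrom, g.tss - up, g.tss + down + 1))
            features["Downstream"].append((g.chrom, g.tx_end, g.tx_end + downstream_window + 1))
        else:
            features["Promoter"].append((g.chrom, g.tss - down, g.tss + up + 1))
            features["Downstream"].append((g.chrom, g.tx_start - downstream_window, g.tx_start))
        exons = list(zip(g.exon_starts, g.exon_ends))
        for s, e in exons:
            if g.cds_start is None:
                features["Exon"].append((g.chrom, s, e))
                continue
            # split each exon into 5'UTR / CDS-exon / 3'UTR pieces
            left_utr = "FiveUTR" if g.strand == "+" else "ThreeUTR"
            right_utr = "ThreeUTR" if g.strand == "+" else "FiveUTR"
            if e <= g.cds_start:
                features[left_utr].append((g.chrom, s, e))
            elif s >= g.cds_end:
                features[right_utr].append((g.chrom, s, e))
            else:
                if s < g.cds_start:
                    features[left_utr].append((g.chrom, s, g.cds_start))
                if e > g.cds_end:
                    features[right_utr].append((g.chrom, g.cds_end, e))
                features["Exon"].append((g.chrom, max(s, g.cds_start), min(e, g.cds_end)))
        for (s1, e1), (s2, e2) in zip(exons[:-1], exons[1:]):
            features["Intron"].append((g.chrom, e1, s2))
    for cat in ("Promoter", "FiveUTR", "ThreeUTR", "Exon", "Intron", "Downstream"):
        for c, s, e in features[cat]:
            if c == chrom and s <= m < e:
                return cat
    return "DistalIntergenic"
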