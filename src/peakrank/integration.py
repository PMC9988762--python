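"""Regulatory-potential gene scoring, rank aggregation with differential
expression, and the three-way direction-concordant integration with histone
marks.

The regulatory potential (RP) of a gene g with k nearby peaks is

    s_g = sum_{i=1..k} 2^(-d_i / d0)

where d_i is the distance between the i-th peak's center and the gene's
TSS, and d0 is the half-decay distance (a peak exactly d0 away contributes
one half).  Only peaks whose center lies within ``window`` of the TSS are
summed; the default window of 10 * d0 bounds the neglected tail below
2^-10 per peak.  d0 defaults to 1000 bp, the promoter-type transcription
factor setting.

Gene ranking: R_RP ranks genes by RP score (1 = highest); R_DE ranks genes
by the differential-expression score log2FC * (-log10 adjusted p), signed
within each expression-direction stratum (most up-regulated first among
up genes, most down-regulated first among down genes).  The aggregated rank
is the product R_DE * R_RP, ascending.

Candidate genes must pass three criteria: (1) differential expression at
FDR < 0.05, (2) PGR occupancy change with RP score > 0.1 computed from the
differential-site subset, and (3) at least one differential histone-mark
site assigned to the gene whose direction matches the gene's expression
direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DataError, ValidationError
from .genemodel import GeneModel, GeneRecord
from .intervals import GenomicInterval

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RPScore:
    gene_id: str
    score: float
    k: int
    distances: tuple[int, ...]
    d0: float


def regulatory_potential(
    gene: GeneRecord,
    peaks: Sequence[GenomicInterval],
    d0: float = 1000.0,
    window: float | None = None,
) -> RPScore:
    """RP score of one gene from a peak list (see module docstring)."""
    if d0 <= 0:
        raise ValidationError(f"d0 must be positive, got {d0}")
    if window is None:
        window = 10.0 * d0
    distances = []
    score = 0.0
    for p in peaks:
        if p.chrom != gene.chrom:
            continue
        d = abs(p.midpoint - gene.tss)
        if d <= window:
            distances.append(d)
            score += 2.0 ** (-d / d0)
    return RPScore(gene.gene_id, score, len(distances), tuple(sorted(distances)), d0)


def rp_table(
    model: GeneModel,
    peaks: Sequence[GenomicInterval],
    d0: float = 1000.0,
    window: float | None = None,
) -> pd.DataFrame:
    """RP scores for every gene in the model; columns ``rp_score, k``."""
    if d0 <= 0:
        raise ValidationError(f"d0 must be positive, got {d0}")
    if window is None:
        window = 10.0 * d0
    mids: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[int]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p.midpoint)
    for chrom, ms in by_chrom.items():
        mids[chrom] = np.sort(np.asarray(ms, dtype=np.int64))
    rows = []
    for g in model:
        arr = mids.get(g.chrom)
        if arr is None or not len(arr):
            rows.append((g.gene_id, 0.0, 0))
            continue
        lo = np.searchsorted(arr, g.tss - window, side="left")
        hi = np.searchsorted(arr, g.tss + window, side="right")
        d = np.abs(arr[lo:hi] - g.tss)
        rows.append((g.gene_id, float(np.exp2(-d / d0).sum()), int(hi - lo)))
    return pd.DataFrame(rows, columns=["gene_id", "rp_score", "k"]).set_index("gene_id")


def rank_genes(scores, higher_is_better: bool = True) -> np.ndarray:
    """Ranks with 1 = best and average ranks on ties.  Undefined (NaN)
    scores are ranked last (sharing the average of the trailing ranks) and
    logged."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise DataError("rank_genes requires a non-empty score vector")
    nan = np.isnan(s)
    ranks = np.empty(s.size, dtype=float)
    valid = ~nan
    if valid.any():
        v = s[valid]
        ranks[valid] = rankdata(-v if higher_is_better else v, method="average")
    if nan.any():
        log.warning("rank_genes: %d undefined score(s) ranked last", int(nan.sum()))
        n_valid = int(valid.sum())
        ranks[nan] = (n_valid + 1 + s.size) / 2.0
    return ranks


def de_score_table(de: pd.DataFrame, log_base: float = 10.0) -> pd.DataFrame:
    """Add ``de_score = log2FoldChange * (-log_b padj)`` to a DE table.

    Expects columns ``gene_id, log2FoldChange, pvalue, padj`` (gene_id may
    be the index).  Zero adjusted p-values are clipped to the smallest
    positive float so the score stays finite.
    """
    df = de.copy()
    if "gene_id" in df.columns:
        df = df.set_index("gene_id")
    for col in ("log2FoldChange", "padj"):
        if col not in df.columns:
            raise ValidationError(f"DE table lacks required column {col!r}")
    padj = df["padj"].astype(float).clip(lower=np.finfo(float).tiny)
    df["de_score"] = df["log2FoldChange"] * (-np.log(padj) / math.log(log_base))
    return df


def stratified_de_ranks(de_scored: pd.DataFrame) -> pd.Series:
    """R_DE within each expression-direction stratum: up-regulated genes
    ranked by descending de_score, down-regulated by ascending (most
    negative first).  Genes with de_score exactly 0 join the up stratum."""
    up = de_scored.index[de_scored["de_score"] >= 0]
    down = de_scored.index[de_scored["de_score"] < 0]
    r = pd.Series(np.nan, index=de_scored.index, name="r_de")
    if len(up):
        r.loc[up] = rank_genes(de_scored.loc[up, "de_score"], higher_is_better=True)
    if len(down):
        r.loc[down] = rank_genes(de_scored.loc[down, "de_score"], higher_is_better=False)
    return r


def aggregate_ranks(rde: pd.Series, rrp: pd.Series) -> pd.DataFrame:
    """Rank product R_DE * R_RP over the shared genes, ascending, ties
    broken by gene id.  Genes missing from either ranking are dropped with
    a log note; an empty intersection is an error."""
    common = rde.index.intersection(rrp.index)
    dropped = len(rde.index.union(rrp.index)) - len(common)
    if dropped:
        log.info("aggregate_ranks: dropped %d gene(s) absent from one ranking", dropped)
    if not len(common):
        raise DataError("aggregate_ranks: no genes shared between the two rankings")
    df = pd.DataFrame({"r_de": rde.loc[common], "r_rp": rrp.loc[common]})
    df["rank_product"] = df["r_de"] * df["r_rp"]
    df = df.sort_index().sort_values("rank_product", kind="stable")  # ties by gene id
    df["aggregated_rank"] = np.arange(1, len(df) + 1)
    return df


def assign_sites_to_genes(
    sites: pd.DataFrame,
    model: GeneModel,
    window: int = 3000,
) -> pd.DataFrame:
    """Assign each site to every gene whose transcript span +/- ``window``
    contains the site midpoint (multi-assignment allowed).

    ``sites`` needs columns ``chrom, start, end, log2_fold_change`` and a
    boolean ``significant`` column; the index is the site id.  Returns a
    long table with one row per (gene, site) pair.
    """
    by_chrom = model.by_chrom()
    idx: dict[str, tuple[list, np.ndarray, np.ndarray]] = {}
    for chrom, genes in by_chrom.items():
        starts = np.array([g.tx_start for g in genes], dtype=np.int64)
        ends = np.array([g.tx_end for g in genes], dtype=np.int64)
        idx[chrom] = (genes, starts, np.maximum.accumulate(ends))
    rows = []
    for site_id, row in sites.iterrows():
        chrom = row["chrom"]
        if chrom not in idx:
            continue
        genes, starts, cummax_ends = idx[chrom]
        m = (int(row["start"]) + int(row["end"])) // 2
        hi = np.searchsorted(starts, m + window, side="right")
        lo = np.searchsorted(cummax_ends[:hi], m - window, side="left")
        for g in genes[lo:hi]:
            if g.tx_start - window <= m <= g.tx_end + window:
                rows.append(
                    (g.gene_id, site_id, row["log2_fold_change"], bool(row["significant"]))
                )
    return pd.DataFrame(rows, columns=["gene_id", "site_id", "log2_fold_change", "significant"])


def gene_directions(assignments: pd.DataFrame) -> pd.Series:
    """Per-gene direction (Up/Down) from the sign of the mean log2FC of
    assigned *significant* sites.  Genes whose mean is exactly zero are
    direction-ambiguous and dropped (logged)."""
    sig = assignments[assignments["significant"]]
    if sig.empty:
        return pd.Series(dtype=object, name="direction")
    means = sig.groupby("gene_id")["log2_fold_change"].mean()
    ambiguous = means.index[means == 0]
    if len(ambiguous):
        log.info("gene_directions: %d direction-ambiguous gene(s) excluded", len(ambiguous))
    means = means[means != 0]
    return pd.Series(np.where(means > 0, "Up", "Down"), index=means.index, name="direction")


@dataclass
class PGRIntegration:
    """Genes passing criteria (1) expression FDR and (2) RP > threshold,
    split by whether the contributing differential sites were gained or
    lost, each with aggregated ranks."""

    gained: pd.DataFrame
    lost: pd.DataFrame
    fdr: float
    rp_threshold: float
    d0: float
    # sign of the mean log2FC of significant PGR sites near each gene's TSS;
    # resolves the PGR direction of genes contributed by both subsets
    site_mean_lfc: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def gene_ids(self) -> set[str]:
        return set(self.gained.index) | set(self.lost.index)

    def pgr_direction(self, gene_id: str) -> str | None:
        """Up/Down from subset membership, mean-sign for genes in both;
        exact zero-mean ties are direction-ambiguous (None)."""
        in_gained = gene_id in self.gained.index
        in_lost = gene_id in self.lost.index
        if in_gained and not in_lost:
            return "Up"
        if in_lost and not in_gained:
            return "Down"
        if in_gained and in_lost:
            mean = self.site_mean_lfc.get(gene_id, 0.0)
            if mean == 0:
                return None
            return "Up" if mean > 0 else "Down"
        return None


def _sites_frame(diff_sites: pd.DataFrame, direction: str) -> list[GenomicInterval]:
    sub = diff_sites[diff_sites["direction"] == direction]
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), name=str(i))
        for i, r in sub.iterrows()
    ]


def integrate_de_with_pgr(
    de: pd.DataFrame,
    pgr_diff: pd.DataFrame,
    model: GeneModel,
    fdr: float = 0.05,
    rp_threshold: float = 0.1,
    d0: float = 1000.0,
    rp_window: float | None = None,
    log_base: float = 10.0,
) -> PGRIntegration:
    """Two-way integration of differential expression with differential PGR
    occupancy.

    ``pgr_diff`` is the differential-binding result table (site id index,
    ``chrom, start, end, log2_fold_change, direction`` columns, direction in
    {gained, lost, ns}).  A gene enters the gained (resp. lost) list when
    padj < ``fdr`` and the RP score computed from gained (resp. lost)
    differential sites exceeds ``rp_threshold``.
    """
    de_scored = de_score_table(de, log_base=log_base)
    sig_genes = de_scored.index[de_scored["padj"] < fdr]
    r_de = stratified_de_ranks(de_scored)

    # per-gene mean log2FC of significant PGR sites near the TSS, used to
    # orient genes that end up in both the gained and the lost subset
    window = 10.0 * d0 if rp_window is None else rp_window
    sig_sites = pgr_diff[pgr_diff["direction"].isin(("gained", "lost"))]
    mean_rows: dict[str, list[float]] = {}
    mids = {
        chrom: np.sort(
            ((sub["start"].values + sub["end"].values) // 2).astype(np.int64)
        )
        for chrom, sub in sig_sites.groupby("chrom")
    }
    lfc_by_chrom = {
        chrom: sub["log2_fold_change"].values[
            np.argsort((sub["start"].values + sub["end"].values) // 2, kind="stable")
        ]
        for chrom, sub in sig_sites.groupby("chrom")
    }
    for g in model:
        arr = mids.get(g.chrom)
        if arr is None or not len(arr):
            continue
        lo = np.searchsorted(arr, g.tss - window, side="left")
        hi = np.searchsorted(arr, g.tss + window, side="right")
        if hi > lo:
            mean_rows[g.gene_id] = float(np.mean(lfc_by_chrom[g.chrom][lo:hi]))
    site_mean_lfc = pd.Series(mean_rows, dtype=float)

    out = {}
    for direction in ("gained", "lost"):
        peaks = _sites_frame(pgr_diff, direction)
        rp = rp_table(model, peaks, d0=d0, window=rp_window)
        keep = [g for g in sig_genes if g in rp.index and rp.loc[g, "rp_score"] > rp_threshold]
        if keep:
            sub = de_scored.loc[keep, ["log2FoldChange", "padj", "de_score"]].copy()
            sub["rp_score"] = rp.loc[keep, "rp_score"]
            sub["k"] = rp.loc[keep, "k"]
            r_rp = pd.Series(
                rank_genes(sub["rp_score"], higher_is_better=True), index=sub.index, name="r_rp"
            )
            agg = aggregate_ranks(r_de.loc[sub.index], r_rp)
            out[direction] = sub.join(agg).sort_values("aggregated_rank")
        else:
            out[direction] = pd.DataFrame(
                columns=[
                    "log2FoldChange", "padj", "de_score", "rp_score", "k",
                    "r_de", "r_rp", "rank_product", "aggregated_rank",
                ]
            )
    return PGRIntegration(
        gained=out["gained"], lost=out["lost"], fdr=fdr, rp_threshold=rp_threshold,
        d0=d0, site_mean_lfc=site_mean_lfc,
    )


@dataclass
class ThreeWayResult:
    """Per-mark candidate tables plus the distinct-gene union summary."""

    per_mark: dict[str, pd.DataFrame]
    union: pd.DataFrame
    n_candidates: int


def three_way_integration(
    pgr: PGRIntegration,
    histone_diff: Mapping[str, pd.DataFrame],
    de: pd.DataFrame,
    model: GeneModel,
    assignment_window: int = 3000,
) -> ThreeWayResult:
    """Criterion (3): keep criteria-(1,2) genes that carry >= 1 differential
    histone site whose direction matches the gene's expression direction.

    ``histone_diff`` maps mark name -> differential-site table (columns
    ``chrom, start, end, log2_fold_change, significant``).  Output rows
    carry the (histone, PGR, expression) direction triple per mark.
    """
    if not histone_diff:
        raise DataError(
            "three_way_integration requires differential histone sites for at least one "
            "mark (e.g. H3K27ac, H3K4me3); none were provided"
        )
    de_idx = de.set_index("gene_id") if "gene_id" in de.columns else de
    candidates = sorted(pgr.gene_ids())

    expr_dir = {}
    for g in candidates:
        lfc = float(de_idx.loc[g, "log2FoldChange"])
        if lfc == 0:
            log.info("three_way_integration: gene %s has zero log2FC; excluded", g)
            continue
        expr_dir[g] = "Up" if lfc > 0 else "Down"

    pgr_dir = {g: pgr.pgr_direction(g) for g in candidates}
    ambiguous = [g for g in candidates if pgr_dir[g] is None]
    if ambiguous:
        log.info(
            "three_way_integration: %d gene(s) with direction-ambiguous PGR signal excluded",
            len(ambiguous),
        )

    agg_rank = {}
    for g in candidates:
        ranks = []
        if g in pgr.gained.index:
            ranks.append(pgr.gained.loc[g, "aggregated_rank"])
        if g in pgr.lost.index:
            ranks.append(pgr.lost.loc[g, "aggregated_rank"])
        agg_rank[g] = int(min(ranks))

    per_mark = {}
    union_rows = {}
    for mark, sites in histone_diff.items():
        assignments = assign_sites_to_genes(sites, model, window=assignment_window)
        hist_dir = gene_directions(assignments)
        rows = []
        for g in candidates:
            if g not in expr_dir or g not in hist_dir.index or pgr_dir[g] is None:
                continue
            if hist_dir.loc[g] != expr_dir[g]:  # criterion 3: concordance
                continue
            rows.append({
                "mark": mark,
                "histone_direction": hist_dir.loc[g],
                "pgr_direction": pgr_dir[g],
                "expression_direction": expr_dir[g],
                "gene_id": g,
                "aggregated_rank": agg_rank[g],
            })
            union_rows.setdefault(g, set()).add(mark)
        per_mark[mark] = pd.DataFrame(
            rows,
            columns=[
                "mark", "histone_direction", "pgr_direction",
                "expression_direction", "gene_id", "aggregated_rank",
            ],
        ).sort_values(["gene_id"]).reset_index(drop=True)

    union = pd.DataFrame(
        [
            {
                "gene_id": g,
                "marks": ",".join(sorted(marks)),
                "pgr_direction": pgr_dir[g],
                "expression_direction": expr_dir[g],
                "aggregated_rank": agg_rank[g],
            }
            for g, marks in sorted(union_rows.items())
        ],
        columns=["gene_id", "marks", "pgr_direction", "expression_direction", "aggregated_rank"],
    )
    return ThreeWayResult(per_mark=per_mark, union=union, n_candidates=len(union))
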