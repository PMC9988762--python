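"""Synthetic study generator with planted ground truth.

Emulates the two-condition design of a laboring (TIL) vs non-laboring
(TNIL) myometrium cistrome study: 3 ChIP-seq replicates per condition,
replicate peak sets with boundary jitter and dropout, planted
differentially bound PGR sites placed next to planted differentially
expressed genes, negative-binomial site counts, and direction-labelled
differential histone sites (concordant for planted targets, discordant for
planted decoys).

Every generator draws from an independent substream of one global seed, so
fixture bundles are byte-identical across runs of the same configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .differential import CountMatrix
from .errors import ConfigError, DataError, PlacementError
from .genemodel import GeneModel, GeneRecord
from .intervals import (
    ConsensusSiteSet,
    GenomicInterval,
    PeakSet,
    consensus_sites,
    merge_intervals,
    read_bed,
    site_name,
    write_bed,
)

log = logging.getLogger(__name__)

# substream tags (second word of the rng seed sequence)
_STREAMS = {"model": 1, "truth": 2, "peaks": 3, "counts": 4, "de": 5, "histone": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic scenario.

    Defaults describe the design the pipeline is meant to exercise: a small
    multi-chromosome pseudo-genome, 1000 genes, 3+3 replicates, 30 planted
    fully concordant target genes and 30 discordant decoys, 2-fold-per-unit
    negative-binomial occupancy changes of 4x (log2FC = 2) at planted sites.
    """

    n_genes: int = 1000
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 40_000_000, "chr2": 30_000_000, "chr3": 20_000_000}
    )
    n_replicates_per_group: int = 3
    n_planted_targets: int = 30
    n_planted_decoys: int = 30
    n_background_peaks: int = 2000
    peak_width_mean: float = 400.0
    peak_jitter_sd: float = 25.0
    replicate_dropout_rate: float = 0.1
    nb_dispersion: float = 0.05
    background_mean: float = 100.0
    background_log_sd: float = 1.0
    planted_site_base_mean: float = 200.0
    site_log2fc_planted: float = 2.0
    gene_log2fc_planted: float = 2.0
    null_log2fc_sd: float = 0.25
    planted_de_z_mean: float = 8.0
    n_background_histone_sites: int = 200
    groups: tuple[str, str] = ("TIL", "TNIL")
    marks: tuple[str, ...] = ("H3K27ac", "H3K4me3")
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_replicates_per_group": self.n_replicates_per_group,
            "n_planted_targets": self.n_planted_targets,
            "n_planted_decoys": self.n_planted_decoys,
            "n_background_peaks": self.n_background_peaks,
            "n_background_histone_sites": self.n_background_histone_sites,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        if not (0.0 <= self.replicate_dropout_rate <= 1.0):
            raise ConfigError("replicate_dropout_rate must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if not self.chrom_sizes:
            raise ConfigError("chrom_sizes must be non-empty")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ConfigError(f"chromosome {chrom!r} must have positive length")
        if self.n_planted_targets + self.n_planted_decoys > self.n_genes:
            raise ConfigError("planted targets + decoys exceed n_genes")
        if self.peak_width_mean <= 0 or self.peak_jitter_sd < 0:
            raise ConfigError("peak geometry parameters must be positive / non-negative")


@dataclass
class GroundTruth:
    """Planted signal: which genes/sites/directions were injected."""

    planted_target_genes: frozenset[str]
    planted_decoy_genes: frozenset[str]
    planted_gained_sites: list[GenomicInterval]
    planted_lost_sites: list[GenomicInterval]
    site_gene: dict[str, str]  # "chrom:start-end" -> gene id
    gene_expression_direction: dict[str, str]  # gene -> Up/Down
    planted_histone_directions: dict[str, dict[str, str]]  # gene -> mark -> Up/Down
    planted_histone_sites: dict[str, list[tuple[GenomicInterval, str, str]]]  # mark -> (site, gene, dir)

    def to_json(self, path) -> None:
        def iv(i: GenomicInterval):
            return {"chrom": i.chrom, "start": i.start, "end": i.end, "name": i.name}

        payload = {
            "planted_target_genes": sorted(self.planted_target_genes),
            "planted_decoy_genes": sorted(self.planted_decoy_genes),
            "planted_gained_sites": [iv(i) for i in self.planted_gained_sites],
            "planted_lost_sites": [iv(i) for i in self.planted_lost_sites],
            "site_gene": self.site_gene,
            "gene_expression_direction": self.gene_expression_direction,
            "planted_histone_directions": self.planted_histone_directions,
            "planted_histone_sites": {
                mark: [[iv(i), g, d] for i, g, d in entries]
                for mark, entries in self.planted_histone_sites.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)

        def iv(d):
            return GenomicInterval(d["chrom"], d["start"], d["end"], name=d.get("name"))

        return cls(
            planted_target_genes=frozenset(payload["planted_target_genes"]),
            planted_decoy_genes=frozenset(payload["planted_decoy_genes"]),
            planted_gained_sites=[iv(d) for d in payload["planted_gained_sites"]],
            planted_lost_sites=[iv(d) for d in payload["planted_lost_sites"]],
            site_gene=payload["site_gene"],
            gene_expression_direction=payload["gene_expression_direction"],
            planted_histone_directions=payload["planted_histone_directions"],
            planted_histone_sites={
                mark: [(iv(d), g, dr) for d, g, dr in entries]
                for mark, entries in payload["planted_histone_sites"].items()
            },
        )


# ---------------------------------------------------------------------------
# gene model


_MIN_GENE_LEN, _MAX_GENE_LEN = 2000, 15000
_MIN_GAP = 1000
_MIN_SEGMENT = 100  # smallest exon or intron


def generate_gene_model(config: SimulationConfig) -> GeneModel:
    """Place ``n_genes`` genes with non-overlapping transcript spans.

    Chromosomes receive genes proportionally to their length; within a
    chromosome, gene spans are laid out left to right with random gaps, so
    placement is deterministic given the seed.  Raises
    :class:`PlacementError` when the genome cannot hold the request.
    """
    config.validate()
    rng = _rng(config.seed, "model")
    if config.n_genes == 0:
        return GeneModel([])

    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    quota = sizes / sizes.sum() * config.n_genes
    n_per = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - n_per)):
        if n_per.sum() >= config.n_genes:
            break
        n_per[i] += 1

    genes: list[GeneRecord] = []
    gid = 0
    width = len(str(max(config.n_genes - 1, 1)))
    for chrom, n in zip(chroms, n_per):
        if n == 0:
            continue
        L = config.chrom_sizes[chrom]
        lengths = rng.integers(_MIN_GENE_LEN, _MAX_GENE_LEN + 1, size=n)
        required = int(lengths.sum()) + (n + 1) * _MIN_GAP
        if required > L:
            raise PlacementError(
                f"chromosome {chrom} ({L} bp) too small for {n} genes "
                f"({required} bp required without overlap)"
            )
        slack = L - required
        offsets = np.sort((np.sort(rng.random(n)) * slack).astype(np.int64))
        cursor = _MIN_GAP
        for j in range(n):
            delta = int(offsets[j]) - (int(offsets[j - 1]) if j else 0)
            start = cursor + delta
            length = int(lengths[j])
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            exon_starts, exon_ends = _make_exons(rng, start, length)
            cds_start = exon_starts[0] + (exon_ends[0] - exon_starts[0]) // 2
            cds_end = exon_starts[-1] + (exon_ends[-1] - exon_starts[-1]) // 2
            genes.append(
                GeneRecord(
                    gene_id=f"G{gid:0{width}d}",
                    chrom=chrom,
                    strand=strand,
                    tss=start if strand == "+" else end - 1,
                    tx_start=start,
                    tx_end=end,
                    exon_starts=exon_starts,
                    exon_ends=exon_ends,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
            gid += 1
            cursor = end + _MIN_GAP
    return GeneModel(genes)


def _make_exons(rng: np.random.Generator, start: int, length: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    n_exons = int(rng.integers(2, 9))
    n_segments = 2 * n_exons - 1  # exon, intron, exon, ...
    leftover = length - n_segments * _MIN_SEGMENT
    extra = rng.multinomial(leftover, np.full(n_segments, 1.0 / n_segments))
    seg_lengths = extra + _MIN_SEGMENT
    bounds = start + np.concatenate([[0], np.cumsum(seg_lengths)])
    exon_starts = tuple(int(b) for b in bounds[0:-1:2])
    exon_ends = tuple(int(b) for b in bounds[1::2])
    return exon_starts, exon_ends


# ---------------------------------------------------------------------------
# ground truth


def plant_ground_truth(model: GeneModel, config: SimulationConfig) -> GroundTruth:
    """Pick target/decoy genes and plant PGR and histone sites for them.

    Every planted gene gets one differential PGR site near its TSS (so its
    RP score clears the 0.1 criterion), a random gained/lost PGR direction,
    a random expression direction, and one histone site on a random mark —
    concordant with expression for targets, flipped for decoys.
    """
    config.validate()
    rng = _rng(config.seed, "truth")
    n_t, n_d = config.n_planted_targets, config.n_planted_decoys
    ids = np.array(model.gene_ids())
    chosen = rng.choice(ids, size=n_t + n_d, replace=False) if n_t + n_d else np.array([], dtype=object)
    targets = frozenset(chosen[:n_t].tolist())
    decoys = frozenset(chosen[n_t:].tolist())

    gained, lost = [], []
    site_gene: dict[str, str] = {}
    expr_dir: dict[str, str] = {}
    hist_dirs: dict[str, dict[str, str]] = {}
    hist_sites: dict[str, list[tuple[GenomicInterval, str, str]]] = {m: [] for m in config.marks}

    w = int(config.peak_width_mean)
    for g_id in chosen.tolist():
        g = model.get(g_id)
        chrom_len = config.chrom_sizes[g.chrom]
        center = g.tss + int(rng.integers(-500, 501))
        start = max(0, center - w // 2)
        end = min(chrom_len, start + w)
        iv = GenomicInterval(g.chrom, start, end, name=f"planted:{g_id}")
        if rng.random() < 0.5:
            gained.append(iv)
        else:
            lost.append(iv)
        site_gene[site_name(iv)] = g_id

        direction = "Up" if rng.random() < 0.5 else "Down"
        expr_dir[g_id] = direction
        mark = str(rng.choice(np.array(config.marks)))
        hist_direction = direction if g_id in targets else ("Down" if direction == "Up" else "Up")
        mid = (g.tx_start + g.tx_end) // 2
        h_iv = GenomicInterval(
            g.chrom, max(0, mid - 300), min(chrom_len, mid + 300), name=f"hist:{mark}:{g_id}"
        )
        hist_dirs[g_id] = {mark: hist_direction}
        hist_sites[mark].append((h_iv, g_id, hist_direction))

    return GroundTruth(
        planted_target_genes=targets,
        planted_decoy_genes=decoys,
        planted_gained_sites=gained,
        planted_lost_sites=lost,
        site_gene=site_gene,
        gene_expression_direction=expr_dir,
        planted_histone_directions=hist_dirs,
        planted_histone_sites=hist_sites,
    )


# ---------------------------------------------------------------------------
# peaks


def generate_peak_replicates(
    model: GeneModel, truth: GroundTruth, config: SimulationConfig
) -> list[PeakSet]:
    """One PeakSet per replicate per group.

    Background peaks are shared across every replicate of both groups with
    per-replicate boundary jitter and dropout.  Planted gained sites appear
    in every TIL replicate and no TNIL replicate (conversely for lost
    sites); planted sites are never dropped, so a noise-free configuration
    recovers them exactly in the group consensus.
    """
    config.validate()
    rng = _rng(config.seed, "peaks")
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()

    planted = truth.planted_gained_sites + truth.planted_lost_sites
    # background peaks avoid planted sites so planted counts stay clean
    background: list[GenomicInterval] = []
    w = int(config.peak_width_mean)
    guard = 1000
    attempts = 0
    while len(background) < config.n_background_peaks and attempts < 20 * max(config.n_background_peaks, 1):
        attempts += 1
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        L = config.chrom_sizes[chrom]
        if L <= w + 2:
            continue
        start = int(rng.integers(1, L - w))
        iv = GenomicInterval(chrom, start, start + w)
        if any(
            p.chrom == iv.chrom and p.start - guard < iv.end and iv.start < p.end + guard
            for p in planted
        ):
            continue
        background.append(iv)
    if len(background) < config.n_background_peaks:
        log.warning(
            "generate_peak_replicates: placed %d of %d background peaks",
            len(background), config.n_background_peaks,
        )

    group_of_planted = {site_name(iv): "gained" for iv in truth.planted_gained_sites}
    group_of_planted.update({site_name(iv): "lost" for iv in truth.planted_lost_sites})

    def jitter(iv: GenomicInterval, chrom_len: int) -> GenomicInterval:
        if config.peak_jitter_sd == 0:
            return GenomicInterval(iv.chrom, iv.start, iv.end, name=iv.name)
        ds, de = rng.normal(0, config.peak_jitter_sd, size=2)
        start = max(0, iv.start + int(round(ds)))
        end = min(chrom_len, iv.end + int(round(de)))
        if end <= start:  # jitter collapsed the peak; keep a 1 bp stub
            start = max(0, min(start, chrom_len - 1))
            end = start + 1
        return GenomicInterval(iv.chrom, start, end, name=iv.name)

    peak_sets = []
    for group in config.groups:
        for rep in range(config.n_replicates_per_group):
            intervals = []
            for iv in background:
                if rng.random() < config.replicate_dropout_rate:
                    continue
                intervals.append(jitter(iv, config.chrom_sizes[iv.chrom]))
            wanted = "gained" if group == config.groups[0] else "lost"
            for iv in planted:
                if group_of_planted[site_name(iv)] == wanted:
                    intervals.append(jitter(iv, config.chrom_sizes[iv.chrom]))
            peak_sets.append(
                PeakSet(sample_id=f"{group}_{rep + 1}", group=group, intervals=intervals)
            )
    return peak_sets


# ---------------------------------------------------------------------------
# counts


def simulate_site_counts(
    sites: ConsensusSiteSet | Sequence[GenomicInterval],
    truth: GroundTruth,
    config: SimulationConfig,
) -> CountMatrix:
    """Negative-binomial counts per site and sample.

    Background sites share one lognormal base mean across all samples.
    Sites overlapping a planted gained interval have group mean ratio
    TIL/TNIL = 2^site_log2fc_planted (the reciprocal for lost sites), with
    the planted base mean in the low group.  Counts are gamma-Poisson with
    Var = mu + dispersion * mu^2, so dispersion -> 0 approaches Poisson.
    """
    config.validate()
    if config.nb_dispersion <= 0:
        raise ConfigError("nb_dispersion must be positive")
    site_list = sites.sites if isinstance(sites, ConsensusSiteSet) else list(sites)
    if not site_list:
        raise DataError("simulate_site_counts requires a non-empty site set")
    rng = _rng(config.seed, "counts")

    gained = truth.planted_gained_sites
    lost = truth.planted_lost_sites

    def planted_status(iv: GenomicInterval) -> str:
        for p in gained:
            if iv.overlaps(p):
                return "gained"
        for p in lost:
            if iv.overlaps(p):
                return "lost"
        return "background"

    ratio = 2.0 ** config.site_log2fc_planted
    ga, gb = config.groups  # (TIL, TNIL)
    samples = [
        (f"{g}_{r + 1}", g) for g in config.groups for r in range(config.n_replicates_per_group)
    ]
    n_sites = len(site_list)
    mu = np.empty((n_sites, len(samples)))
    base_bg = config.background_mean * np.exp(rng.normal(0, config.background_log_sd, size=n_sites))
    for i, iv in enumerate(site_list):
        status = planted_status(iv)
        if status == "background":
            mu[i, :] = base_bg[i]
        elif status == "gained":
            for j, (_, g) in enumerate(samples):
                mu[i, j] = config.planted_site_base_mean * (ratio if g == ga else 1.0)
        else:
            for j, (_, g) in enumerate(samples):
                mu[i, j] = config.planted_site_base_mean * (ratio if g == gb else 1.0)

    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam).astype(np.int64)

    names = [iv.name or site_name(iv) for iv in site_list]
    site_table = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in site_list],
            "start": [iv.start for iv in site_list],
            "end": [iv.end for iv in site_list],
        },
        index=pd.Index(names, name="site_id"),
    )
    counts_df = pd.DataFrame(counts, index=site_table.index, columns=[s for s, _ in samples])
    return CountMatrix(counts=counts_df, groups=dict(samples), site_table=site_table)


# ---------------------------------------------------------------------------
# differential expression


def generate_de_table(model: GeneModel, truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """DESeq2-style per-gene table: gene_id, log2FoldChange, pvalue, padj.

    Null genes draw a standard-normal test statistic (uniform p) and a
    small null log2FC; planted targets and decoys draw a strongly shifted
    statistic and |log2FC| = gene_log2fc_planted with the planted sign.
    padj is Benjamini-Hochberg over all genes.
    """
    config.validate()
    rng = _rng(config.seed, "de")
    ids = model.gene_ids()
    planted = truth.planted_target_genes | truth.planted_decoy_genes
    z = rng.normal(0.0, 1.0, size=len(ids))
    lfc = rng.normal(0.0, config.null_log2fc_sd, size=len(ids))
    for i, g in enumerate(ids):
        if g in planted:
            z[i] = rng.normal(config.planted_de_z_mean, 1.0)
            sign = 1.0 if truth.gene_expression_direction[g] == "Up" else -1.0
            lfc[i] = sign * config.gene_log2fc_planted
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    padj = multipletests(pvals, method="fdr_bh")[1] if len(ids) else np.array([])
    return pd.DataFrame(
        {"gene_id": ids, "log2FoldChange": lfc, "pvalue": pvals, "padj": padj}
    )


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (statsmodels fdr_bh), exposed for reuse/tests."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# histone differential sites


def generate_histone_differential(
    model: GeneModel, truth: GroundTruth, config: SimulationConfig
) -> dict[str, pd.DataFrame]:
    """Per-mark differential-site tables (chrom, start, end, log2FC, p,
    padj, significant, direction).

    Planted histone sites are strongly significant with the planted sign;
    background sites are null.  Direction "Up" means higher occupancy in
    the first group (TIL).
    """
    config.validate()
    rng = _rng(config.seed, "histone")
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    out = {}
    for mark in config.marks:
        rows = []
        for iv, gene, direction in truth.planted_histone_sites.get(mark, []):
            sign = 1.0 if direction == "Up" else -1.0
            rows.append(
                {
                    "site_id": site_name(iv),
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "log2_fold_change": sign * abs(rng.normal(1.5, 0.2)),
                    "p_value": 1e-6 * rng.random(),
                }
            )
        for _ in range(config.n_background_histone_sites):
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            L = config.chrom_sizes[chrom]
            start = int(rng.integers(0, max(1, L - 600)))
            rows.append(
                {
                    "site_id": f"{chrom}:{start}-{start + 600}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + 600,
                    "log2_fold_change": rng.normal(0.0, 0.2),
                    "p_value": rng.uniform(0.1, 1.0),
                }
            )
        df = pd.DataFrame(rows).set_index("site_id")
        df["adjusted_p"] = benjamini_hochberg(df["p_value"]) if len(df) else []
        df["significant"] = df["adjusted_p"] < 0.05
        df["direction"] = np.where(
            ~df["significant"], "ns", np.where(df["log2_fold_change"] > 0, "gained", "lost")
        )
        out[mark] = df
    return out


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimulatedStudy:
    """Everything one synthetic run produces, ready for the pipeline."""

    config: SimulationConfig
    model: GeneModel
    truth: GroundTruth
    peak_sets: list[PeakSet]
    consensus: dict[str, ConsensusSiteSet]
    union_sites: list[GenomicInterval]
    counts: CountMatrix
    de_table: pd.DataFrame
    histone: dict[str, pd.DataFrame]


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run every generator and derive the consensus/union site universe."""
    config.validate()
    model = generate_gene_model(config)
    truth = plant_ground_truth(model, config)
    peak_sets = generate_peak_replicates(model, truth, config)
    consensus = {}
    for group in config.groups:
        members = [ps for ps in peak_sets if ps.group == group]
        consensus[group] = consensus_sites(members)
    union = merge_intervals(
        [iv for c in consensus.values() for iv in c.sites]
    )
    union = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=site_name(iv)) for iv in union
    ]
    counts = simulate_site_counts(union, truth, config)
    de_table = generate_de_table(model, truth, config)
    histone = generate_histone_differential(model, truth, config)
    return SimulatedStudy(
        config=config,
        model=model,
        truth=truth,
        peak_sets=peak_sets,
        consensus=consensus,
        union_sites=union,
        counts=counts,
        de_table=de_table,
        histone=histone,
    )


def write_fixture_bundle(dir_path, study: SimulatedStudy) -> dict[str, str]:
    """Write the study to ``dir_path`` as plain-text files and return the
    manifest (file name -> role), also saved as ``manifest.json``.

    BED files round-trip through :func:`peakrank.intervals.read_bed`.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    for ps in study.peak_sets:
        fname = f"peaks_{ps.sample_id}.bed"
        write_bed(ps, out / fname)
        manifest[fname] = f"peaks:{ps.group}:{ps.sample_id}"
    study.model.to_tsv(out / "gene_model.tsv")
    manifest["gene_model.tsv"] = "gene_model"
    study.de_table.to_csv(out / "de_table.tsv", sep="\t", index=False)
    manifest["de_table.tsv"] = "de_table"
    study.counts.to_tsv(out / "site_counts.tsv")
    manifest["site_counts.tsv"] = "count_matrix"
    for mark, df in study.histone.items():
        fname = f"histone_{mark}.tsv"
        df.to_csv(out / fname, sep="\t")
        manifest[fname] = f"histone_differential:{mark}"
    study.truth.to_json(out / "ground_truth.json")
    manifest["ground_truth.json"] = "ground_truth"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest.json"] = "manifest"
    return manifest
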