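"""End-to-end orchestration: configuration, stage sequencing, outputs.

A run is driven by one YAML config holding either a ``synthetic`` block
(a :class:`~peakrank.simulate.SimulationConfig`) or an ``inputs`` block of
file paths, plus a ``thresholds`` block in which every tunable used
anywhere downstream lives exactly once.  Stages run in a fixed order —
consensus sites per group, genomic annotation with enrichment testing,
differential binding with the PC2 filter audit, RP/rank tables, candidate
tables — and the run writes TSV outputs, a run-metadata JSON (parameters,
seed, per-file checksums) and a markdown report.  Outputs contain no
timestamps: identical config and inputs give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    annotate_sites,
    annotation_frame,
    distribution_summary,
    enrichment_frame,
    plot_distribution,
    region_enrichment_test,
)
from .differential import (
    CountMatrix,
    apply_pc2_filter,
    classify_sites,
    normalize_counts,
    test_differential_sites,
)
from .errors import ConfigError, DataError
from .genemodel import GeneModel
from .integration import (
    PGRIntegration,
    ThreeWayResult,
    integrate_de_with_pgr,
    three_way_integration,
)
from .intervals import (
    GenomicInterval,
    consensus_sites,
    merge_intervals,
    overlap_fraction,
    read_bed,
    site_name,
    write_bed,
)
from .simulate import GroundTruth, SimulatedStudy, SimulationConfig, simulate_study

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Every tunable parameter of the analysis, with its default."""

    fdr: float = 0.05                  # DE significance (criterion 1)
    rp: float = 0.1                    # RP score cut (criterion 2)
    pc2: float | None = 0.005          # |PC2 loading| noise cut; None disables
    diffbind_alpha: float = 0.05       # per-site binding test level
    diffbind_mode: str = "raw"         # "raw" (P < alpha) or "adjusted" (BH)
    diffbind_variance: str = "pooled"  # "pooled" (calibrated at n=3) or "welch"
    promoter_upstream: int = 3000
    promoter_downstream: int = 3000
    downstream_window: int = 3000
    d0: float = 1000.0                 # RP half-decay distance (bp)
    rp_window: float | None = None     # peak inclusion window; None -> 10 * d0
    assignment_window: int = 3000      # histone site-to-gene window (criterion 3)
    de_log_base: float = 10.0
    min_overlap: int | None = None     # consensus support; None -> all replicates

    def validate(self) -> list[str]:
        errors = []
        for key in ("fdr", "diffbind_alpha"):
            v = getattr(self, key)
            if not (0.0 < v < 1.0):
                errors.append(f"thresholds.{key}: out of (0,1): {v}")
        for key in ("rp", "d0", "de_log_base"):
            if getattr(self, key) <= 0:
                errors.append(f"thresholds.{key}: must be positive")
        for key in ("promoter_upstream", "promoter_downstream", "downstream_window", "assignment_window"):
            if getattr(self, key) < 0:
                errors.append(f"thresholds.{key}: must be >= 0")
        if self.pc2 is not None and self.pc2 < 0:
            errors.append("thresholds.pc2: must be >= 0 or null")
        if self.diffbind_mode not in ("raw", "adjusted"):
            errors.append("thresholds.diffbind_mode: must be 'raw' or 'adjusted'")
        if self.diffbind_variance not in ("pooled", "welch"):
            errors.append("thresholds.diffbind_variance: must be 'pooled' or 'welch'")
        if self.rp_window is not None and self.rp_window <= 0:
            errors.append("thresholds.rp_window: must be positive or null")
        if self.min_overlap is not None and self.min_overlap < 1:
            errors.append("thresholds.min_overlap: must be >= 1 or null")
        return errors


@dataclass(frozen=True)
class InputPaths:
    """Real-data input block: paths to peak BEDs and tables."""

    peaks: tuple[Mapping[str, str], ...]  # each: {path, sample_id, group}
    gene_model: str
    de_table: str
    count_matrix: str
    histone_tables: Mapping[str, str] = field(default_factory=dict)  # mark -> path
    groups: tuple[str, str] = ("TIL", "TNIL")


@dataclass(frozen=True)
class PipelineConfig:
    synthetic: SimulationConfig | None = None
    inputs: InputPaths | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    outdir: str = "peakrank_out"
    seed: int | None = None
    log_level: str = "INFO"
    make_plot: bool = False

    def validate(self) -> list[str]:
        errors = []
        if (self.synthetic is None) == (self.inputs is None):
            errors.append("exactly one of 'synthetic' and 'inputs' must be present")
        errors.extend(self.thresholds.validate())
        return errors


def _build_dataclass(cls, data: Mapping[str, Any], path: str, errors: list[str]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    for key in sorted(unknown):
        errors.append(f"{path}.{key}: unknown key")
    kwargs = {k: v for k, v in data.items() if k in known}
    try:
        return cls(**kwargs)
    except (TypeError, ConfigError) as exc:
        errors.append(f"{path}: {exc}")
        return None


def load_config(data: Mapping[str, Any]) -> PipelineConfig:
    """Build and validate a PipelineConfig from a parsed mapping, filling in
    every default.  All violations are collected and raised together."""
    errors: list[str] = []
    if not isinstance(data, Mapping):
        raise ConfigError("config root must be a mapping")
    known_top = {"synthetic", "inputs", "thresholds", "outdir", "seed", "log_level", "make_plot"}
    for key in sorted(set(data) - known_top):
        errors.append(f"{key}: unknown key")

    synthetic = None
    if "synthetic" in data and data["synthetic"] is not None:
        block = dict(data["synthetic"])
        if "chrom_sizes" in block:
            block["chrom_sizes"] = dict(block["chrom_sizes"])
        for tup_key in ("groups", "marks"):
            if tup_key in block:
                block[tup_key] = tuple(block[tup_key])
        synthetic = _build_dataclass(SimulationConfig, block, "synthetic", errors)
        if synthetic is not None:
            try:
                synthetic.validate()
            except ConfigError as exc:
                errors.append(f"synthetic: {exc}")

    inputs = None
    if "inputs" in data and data["inputs"] is not None:
        block = dict(data["inputs"])
        if "peaks" in block:
            block["peaks"] = tuple(dict(p) for p in block["peaks"])
        if "histone_tables" in block:
            block["histone_tables"] = dict(block["histone_tables"])
        if "groups" in block:
            block["groups"] = tuple(block["groups"])
        inputs = _build_dataclass(InputPaths, block, "inputs", errors)

    thresholds = _build_dataclass(
        Thresholds, dict(data.get("thresholds") or {}), "thresholds", errors
    ) or Thresholds()

    cfg = PipelineConfig(
        synthetic=synthetic,
        inputs=inputs,
        thresholds=thresholds,
        outdir=str(data.get("outdir", "peakrank_out")),
        seed=data.get("seed"),
        log_level=str(data.get("log_level", "INFO")),
        make_plot=bool(data.get("make_plot", False)),
    )
    errors.extend(cfg.validate())
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def validate_config(path) -> PipelineConfig:
    """Parse a YAML config file; raise ConfigError listing all violations."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return load_config(data)


def config_echo(cfg: PipelineConfig) -> dict[str, Any]:
    """The normalized config with every default filled in, as plain data."""
    out: dict[str, Any] = {
        "version": __version__,
        "outdir": cfg.outdir,
        "seed": cfg.seed,
        "log_level": cfg.log_level,
        "make_plot": cfg.make_plot,
        "thresholds": dataclasses.asdict(cfg.thresholds),
    }
    if cfg.synthetic is not None:
        block = dataclasses.asdict(cfg.synthetic)
        block["chrom_sizes"] = dict(block["chrom_sizes"])
        out["synthetic"] = block
    if cfg.inputs is not None:
        out["inputs"] = dataclasses.asdict(cfg.inputs)
    return out


# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    config: PipelineConfig
    model: GeneModel
    truth: GroundTruth | None
    consensus: dict[str, Any]
    union_sites: list[GenomicInterval]
    annotation: pd.DataFrame
    summary: dict
    enrichment: pd.DataFrame
    differential: pd.DataFrame
    gained: pd.DataFrame
    lost: pd.DataFrame
    pgr_integration: PGRIntegration
    three_way: ThreeWayResult | None
    funnel: dict[str, int]
    outputs: dict[str, str]


def _load_real_inputs(inputs: InputPaths):
    peak_sets = [
        read_bed(p["path"], sample_id=p.get("sample_id"), group=p["group"])
        for p in inputs.peaks
    ]
    model = GeneModel.from_tsv(inputs.gene_model)
    de = pd.read_csv(inputs.de_table, sep="\t")
    counts = CountMatrix.from_tsv(inputs.count_matrix)
    histone = {
        mark: pd.read_csv(path, sep="\t", index_col="site_id")
        for mark, path in inputs.histone_tables.items()
    }
    return peak_sets, model, de, counts, histone


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and write the report bundle to ``config.outdir``."""
    errors = config.validate()
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    th = config.thresholds
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    funnel: dict[str, int] = {}

    # -- stage 0: data -----------------------------------------------------
    truth = None
    if config.synthetic is not None:
        sim_cfg = config.synthetic
        if config.seed is not None:
            sim_cfg = replace(sim_cfg, seed=config.seed)
        log.info("stage 0: simulating synthetic study (seed=%d)", sim_cfg.seed)
        study = simulate_study(sim_cfg)
        peak_sets = study.peak_sets
        model, de, counts, histone = study.model, study.de_table, study.counts, study.histone
        truth = study.truth
        groups = sim_cfg.groups
        consensus = study.consensus
        union = study.union_sites
    else:
        log.info("stage 0: loading inputs")
        peak_sets, model, de, counts, histone = _load_real_inputs(config.inputs)
        groups = config.inputs.groups
        consensus = {}
        for group in groups:
            members = [ps for ps in peak_sets if ps.group == group]
            if not members:
                raise DataError(f"no peak files labelled with group {group!r}")
            consensus[group] = consensus_sites(members, min_overlap=th.min_overlap)
        union = [
            GenomicInterval(iv.chrom, iv.start, iv.end, name=site_name(iv))
            for iv in merge_intervals([iv for c in consensus.values() for iv in c.sites])
        ]
        union_names = {iv.name for iv in union}
        missing = union_names - set(counts.site_table.index)
        if missing:
            log.warning(
                "count matrix lacks %d of %d consensus union sites; proceeding on the intersection",
                len(missing), len(union),
            )
            union = [iv for iv in union if iv.name in set(counts.site_table.index)]

    for group in groups:
        funnel[f"peaks_in_{group}"] = sum(len(ps) for ps in peak_sets if ps.group == group)
        funnel[f"consensus_sites_{group}"] = len(consensus[group])
    funnel["union_sites"] = len(union)
    log.info("stage 1: consensus — %s", {g: len(consensus[g]) for g in groups})

    # -- stage 2: annotation ----------------------------------------------
    promoter_window = (th.promoter_upstream, th.promoter_downstream)
    annotated = annotate_sites(union, model, promoter_window, th.downstream_window)
    summary = distribution_summary(annotated) if annotated else {}
    ann_df = annotation_frame(annotated)
    log.info("stage 2: annotated %d union sites", len(annotated))

    # -- stage 3: differential binding ------------------------------------
    norm = normalize_counts(counts)
    keep = [n for n in counts.site_table.index if n in {iv.name for iv in union}]
    results = test_differential_sites(
        norm, groups=tuple(groups), alpha=th.diffbind_alpha, mode=th.diffbind_mode,
        variance=th.diffbind_variance,
    )
    results = results.loc[keep]
    n_sig = int(
        (results["p_value" if th.diffbind_mode == "raw" else "adjusted_p"] < th.diffbind_alpha).sum()
    )
    funnel["differential_sites_prefilter"] = n_sig
    results, pc2 = apply_pc2_filter(
        results, norm, threshold=th.pc2, alpha=th.diffbind_alpha, mode=th.diffbind_mode
    )
    funnel["pc2_removed"] = len(pc2.removed) if pc2 is not None else 0
    gained, lost = classify_sites(results, alpha=th.diffbind_alpha, mode=th.diffbind_mode)
    funnel["gained_sites"] = len(gained)
    funnel["lost_sites"] = len(lost)
    log.info(
        "stage 3: %d significant sites, %d removed by PC2 filter, %d gained / %d lost",
        n_sig, funnel["pc2_removed"], len(gained), len(lost),
    )

    # -- stage 4: per-category enrichment ----------------------------------
    sig_sites = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), name=str(i))
        for i, r in pd.concat([gained, lost]).iterrows()
    ]
    enr = region_enrichment_test(sig_sites, union, model, promoter_window, th.downstream_window)
    enr_df = enrichment_frame(enr)

    # -- stage 5: integration ----------------------------------------------
    pgr_diff = results[results["filtered"] != "Y"].copy()
    pgr_diff["direction"] = "ns"
    pgr_diff.loc[gained.index, "direction"] = "gained"
    pgr_diff.loc[lost.index, "direction"] = "lost"
    pgr = integrate_de_with_pgr(
        de, pgr_diff, model,
        fdr=th.fdr, rp_threshold=th.rp, d0=th.d0, rp_window=th.rp_window,
        log_base=th.de_log_base,
    )
    funnel["genes_integrated_gained"] = len(pgr.gained)
    funnel["genes_integrated_lost"] = len(pgr.lost)
    log.info(
        "stage 5: integration — %d genes (gained PGR), %d genes (lost PGR)",
        len(pgr.gained), len(pgr.lost),
    )

    three_way = None
    if histone:
        hist_inputs = {}
        for mark, df in histone.items():
            sub = df.copy()
            if "significant" not in sub.columns:
                sub["significant"] = sub["adjusted_p"] < th.fdr
            hist_inputs[mark] = sub
        three_way = three_way_integration(
            pgr, hist_inputs, de, model, assignment_window=th.assignment_window
        )
        funnel["candidate_genes"] = three_way.n_candidates
        log.info("stage 6: three-way integration — %d candidate genes", three_way.n_candidates)

    # -- outputs ------------------------------------------------------------
    outputs: dict[str, str] = {}

    def save(df: pd.DataFrame, fname: str, index: bool = True) -> None:
        path = outdir / fname
        df.to_csv(path, sep="\t", index=index)
        outputs[fname] = _sha256(path)

    for group in groups:
        path = outdir / f"consensus_{group}.bed"
        write_bed(consensus[group].sites, path)
        outputs[path.name] = _sha256(path)
    save(ann_df, "sites_annotation.tsv", index=False)
    save(enr_df, "region_enrichment.tsv", index=False)
    res_out = results.copy()
    res_out.index.name = "site_id"
    save(res_out, "differential_sites.tsv")
    save(pgr.gained, "integrated_gained.tsv")
    save(pgr.lost, "integrated_lost.tsv")
    if three_way is not None:
        for mark, df in three_way.per_mark.items():
            save(df, f"candidates_{mark}.tsv", index=False)
        save(three_way.union, "candidates_union.tsv", index=False)
    if config.make_plot and summary:
        plot_distribution(summary, outdir / "annotation_distribution.png")

    metadata = {
        "config": config_echo(config),
        "funnel": funnel,
        "checksums": dict(sorted(outputs.items())),
    }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
    _write_report(outdir / "report.md", config, funnel, summary, enr_df, three_way)
    outputs["run_metadata.json"] = _sha256(outdir / "run_metadata.json")
    outputs["report.md"] = _sha256(outdir / "report.md")

    return PipelineResult(
        config=config, model=model, truth=truth, consensus=consensus,
        union_sites=union, annotation=ann_df, summary=summary, enrichment=enr_df,
        differential=results, gained=gained, lost=lost, pgr_integration=pgr,
        three_way=three_way, funnel=funnel, outputs=outputs,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_report(path, config, funnel, summary, enr_df, three_way) -> None:
    lines = ["# peakrank run report", ""]
    lines.append("## Funnel")
    for key, val in funnel.items():
        lines.append(f"- {key}: {val}")
    if summary:
        lines.append("")
        lines.append("## Annotation distribution (union consensus sites)")
        for cat, frac in summary.items():
            lines.append(f"- {cat.value}: {frac:.2f}")
    if len(enr_df):
        lines.append("")
        lines.append("## Region enrichment (differential vs consensus)")
        lines.append(enr_df.to_string(index=False))
    if three_way is not None:
        lines.append("")
        lines.append(f"## Candidate genes: {three_way.n_candidates}")
        if len(three_way.union):
            lines.append(three_way.union.to_string(index=False))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# planted-truth evaluation (synthetic runs)


def evaluate_against_truth(result: PipelineResult) -> dict[str, float]:
    """Sensitivity/precision of the candidate table against the planted
    targets, and the number of planted discordant decoys that leaked in."""
    if result.truth is None or result.three_way is None:
        raise DataError("evaluation requires a synthetic run with histone data")
    targets = set(result.truth.planted_target_genes)
    decoys = set(result.truth.planted_decoy_genes)
    called = set(result.three_way.union["gene_id"])
    tp = len(called & targets)
    sensitivity = tp / len(targets) if targets else float("nan")
    precision = tp / len(called) if called else float("nan")
    return {
        "n_called": len(called),
        "n_targets": len(targets),
        "true_positives": tp,
        "sensitivity": sensitivity,
        "precision": precision,
        "decoys_included": len(called & decoys),
    }
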