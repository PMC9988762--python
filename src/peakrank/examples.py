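"""Bundled worked example: direction-annotated candidate genes from a
laboring (TIL) vs non-laboring (TNIL) myometrium PGR study.

Each entry gives, for one gene and one histone mark, the direction triple
(differential histone occupancy, differential PGR occupancy, differential
expression) with "Up" meaning higher in labor.  ``build_example_inputs``
turns the triples into a toy gene model, a DE table, differential PGR
sites and differential histone sites, so the full three-way integration
can be exercised end to end; ``run_example`` does exactly that.
"""

from __future__ import annotations

import pandas as pd

from .genemodel import GeneModel, GeneRecord
from .integration import PGRIntegration, ThreeWayResult, integrate_de_with_pgr, three_way_integration

# (histone direction, PGR direction, expression direction) -> genes, per mark
H3K27AC_TRIPLES: list[tuple[str, str, str, tuple[str, ...]]] = [
    ("Up", "Up", "Up", ("COLEC12", "ATP11A", "NID2", "CHST15", "KIF5C")),
    ("Up", "Down", "Up", ("TMED10",)),
    ("Down", "Up", "Down", ("MPRIP", "NCS1", "TNS1", "ALDH4A1")),
    ("Down", "Down", "Down", ("SVIL", "RERG", "MAP4", "EVA1C", "GRIN2A")),
]

H3K4ME3_TRIPLES: list[tuple[str, str, str, tuple[str, ...]]] = [
    ("Up", "Up", "Up", ("KIF5C",)),
    ("Down", "Up", "Down", ("TNS1", "CBX7", "AHDC1")),
]

TRIPLES: dict[str, list[tuple[str, str, str, tuple[str, ...]]]] = {
    "H3K27ac": H3K27AC_TRIPLES,
    "H3K4me3": H3K4ME3_TRIPLES,
}

_SPACING = 100_000
_SPAN = 10_000


def _gene_table() -> dict[str, tuple[str, str, str]]:
    """gene -> (histone dir per first mark seen, pgr dir, expr dir)."""
    out: dict[str, tuple[str, str, str]] = {}
    for triples in TRIPLES.values():
        for hist, pgr, expr, genes in triples:
            for g in genes:
                out.setdefault(g, (hist, pgr, expr))
    return out


def build_example_inputs() -> tuple[GeneModel, pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Encode the direction triples as pipeline inputs.

    Returns (gene model, DE table, differential PGR site table,
    per-mark differential histone site tables).  Every gene gets one PGR
    site centred on its TSS (RP score 1.0) and one histone site per listed
    mark in its gene body.
    """
    genes = sorted(_gene_table())
    info = _gene_table()

    records = []
    for i, g in enumerate(genes):
        start = _SPACING * (i + 1)
        end = start + _SPAN
        records.append(
            GeneRecord(
                gene_id=g, chrom="chrEx", strand="+", tss=start,
                tx_start=start, tx_end=end,
                exon_starts=(start,), exon_ends=(end,),
            )
        )
    model = GeneModel(records)

    de_rows = []
    pgr_rows = []
    for g in genes:
        _, pgr_dir, expr_dir = info[g]
        rec = model.get(g)
        de_rows.append(
            {
                "gene_id": g,
                "log2FoldChange": 2.0 if expr_dir == "Up" else -2.0,
                "pvalue": 1e-8,
                "padj": 1e-6,
            }
        )
        pgr_rows.append(
            {
                "site_id": f"pgr:{g}",
                "chrom": rec.chrom,
                "start": rec.tss - 200,
                "end": rec.tss + 200,
                "log2_fold_change": 1.5 if pgr_dir == "Up" else -1.5,
                "p_value": 1e-4,
                "adjusted_p": 1e-3,
                "direction": "gained" if pgr_dir == "Up" else "lost",
            }
        )
    de = pd.DataFrame(de_rows)
    pgr_sites = pd.DataFrame(pgr_rows).set_index("site_id")

    histone: dict[str, pd.DataFrame] = {}
    for mark, triples in TRIPLES.items():
        rows = []
        for hist_dir, _, _, mark_genes in triples:
            for g in mark_genes:
                rec = model.get(g)
                mid = (rec.tx_start + rec.tx_end) // 2
                rows.append(
                    {
                        "site_id": f"{mark}:{g}",
                        "chrom": rec.chrom,
                        "start": mid - 300,
                        "end": mid + 300,
                        "log2_fold_change": 1.5 if hist_dir == "Up" else -1.5,
                        "significant": True,
                    }
                )
        histone[mark] = pd.DataFrame(rows).set_index("site_id")
    return model, de, pgr_sites, histone


def run_example() -> tuple[PGRIntegration, ThreeWayResult]:
    """Integrate the example inputs and return the candidate tables."""
    model, de, pgr_sites, histone = build_example_inputs()
    pgr = integrate_de_with_pgr(de, pgr_sites, model)
    result = three_way_integration(pgr, histone, de, model)
    return pgr, result
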