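"""Gene model: per-gene chromosome, strand, TSS, transcript span and exon
structure — the coordinate frame for annotation and regulatory-potential
scoring.

On disk the model is a TSV with columns ``gene_id, chrom, strand, tss,
txStart, txEnd, exonStarts, exonEnds`` (exon columns comma-joined, trailing
comma tolerated) plus optional ``cdsStart, cdsEnd``.  Coordinates are
0-based half-open; the TSS of a ``+`` gene is ``txStart`` and of a ``-``
gene ``txEnd - 1`` (the last transcribed base).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ValidationError

COLUMNS = [
    "gene_id", "chrom", "strand", "tss", "tx_start", "tx_end",
    "exon_starts", "exon_ends", "cds_start", "cds_end",
]

_TSV_NAMES = {
    "tx_start": "txStart", "tx_end": "txEnd",
    "exon_starts": "exonStarts", "exon_ends": "exonEnds",
    "cds_start": "cdsStart", "cds_end": "cdsEnd",
}


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]
    cds_start: int | None = None
    cds_end: int | None = None


class GeneModel:
    """A validated, immutable-by-convention collection of gene records."""

    def __init__(self, genes: list[GeneRecord]):
        self.genes = list(genes)
        self._validate()
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValidationError("duplicate gene ids in gene model")

    def _validate(self) -> None:
        for g in self.genes:
            if g.strand not in ("+", "-"):
                raise ValidationError(f"{g.gene_id}: gene strand must be + or -")
            if not (0 <= g.tx_start < g.tx_end):
                raise ValidationError(f"{g.gene_id}: invalid transcript span")
            if not (g.tx_start <= g.tss < g.tx_end):
                raise ValidationError(f"{g.gene_id}: TSS outside transcript span")
            if len(g.exon_starts) != len(g.exon_ends) or not g.exon_starts:
                raise ValidationError(f"{g.gene_id}: inconsistent exon structure")
            if g.exon_starts[0] != g.tx_start or g.exon_ends[-1] != g.tx_end:
                raise ValidationError(f"{g.gene_id}: exons do not span the transcript")
            for s, e in zip(g.exon_starts, g.exon_ends):
                if not (g.tx_start <= s < e <= g.tx_end):
                    raise ValidationError(f"{g.gene_id}: exon outside transcript span")
            if (g.cds_start is None) != (g.cds_end is None):
                raise ValidationError(f"{g.gene_id}: CDS must have both bounds or neither")
            if g.cds_start is not None and not (g.tx_start <= g.cds_start < g.cds_end <= g.tx_end):
                raise ValidationError(f"{g.gene_id}: CDS outside transcript span")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    def get(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def by_chrom(self) -> dict[str, list[GeneRecord]]:
        """Genes grouped by chromosome, sorted by (tx_start, gene_id)."""
        out: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for chrom in out:
            out[chrom].sort(key=lambda g: (g.tx_start, g.gene_id))
        return out

    # -- I/O ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            rows.append({
                "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
                "tss": g.tss, "tx_start": g.tx_start, "tx_end": g.tx_end,
                "exon_starts": ",".join(map(str, g.exon_starts)),
                "exon_ends": ",".join(map(str, g.exon_ends)),
                "cds_start": g.cds_start, "cds_end": g.cds_end,
            })
        return pd.DataFrame(rows, columns=COLUMNS)

    def to_tsv(self, path) -> None:
        df = self.to_frame().rename(columns=_TSV_NAMES)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneModel":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
        df = df.rename(columns={v: k for k, v in _TSV_NAMES.items()})
        genes = []
        has_cds = "cds_start" in df.columns
        for row in df.itertuples(index=False):
            cds_start = cds_end = None
            if has_cds and not pd.isna(row.cds_start):
                cds_start, cds_end = int(row.cds_start), int(row.cds_end)
            genes.append(GeneRecord(
                gene_id=row.gene_id, chrom=row.chrom, strand=row.strand,
                tss=int(row.tss), tx_start=int(row.tx_start), tx_end=int(row.tx_end),
                exon_starts=_parse_ints(row.exon_starts),
                exon_ends=_parse_ints(row.exon_ends),
                cds_start=cds_start, cds_end=cds_end,
            ))
        return cls(genes)


def _parse_ints(text) -> tuple[int, ...]:
    return tuple(int(x) for x in str(text).strip(",").split(",") if x)
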