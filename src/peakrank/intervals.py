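"""Strand-aware genomic interval algebra: BED I/O, merging, replicate
consensus, and cistrome-overlap statistics.

All coordinates are BED-native — 0-based, half-open ``[start, end)`` — in
every internal structure; nothing is converted at the edges because BED is
also the on-disk format.  Chromosome names are compared by exact string
match (no ``chr`` prefix normalization).

ChIP-seq peaks carry no meaningful strand, so peak intervals default to
strand ``"."``; strand only matters in the gene model used downstream.

Consensus construction follows the DiffBind convention: the peaks of all
replicates of a group are pooled and merged, and a merged interval is kept
as a consensus site only if peaks from at least ``min_overlap`` distinct
replicates overlap it by >= 1 bp (default: every replicate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import BedParseError, ConfigError, DataError, ValidationError

log = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    Invariants: ``0 <= start < end`` and a non-empty chromosome name.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval requires 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        """Integer midpoint (floor), used for annotation and RP distances."""
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two half-open intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def _sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


def normalize_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sorted copy of ``intervals`` (by chrom, start, end). Validation happens
    at construction time, so sorting is all normalization does."""
    return sorted(intervals, key=_sort_key)


@dataclass
class PeakSet:
    """Peak calls of one ChIP-seq sample (one replicate of one condition)."""

    sample_id: str
    group: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = normalize_intervals(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class ConsensusSiteSet:
    """Merged intervals supported by >= ``min_overlap`` replicates of a group.

    ``support`` is a sites x replicates table of overlapping-peak counts;
    ``provenance`` lists the sample ids that contributed.
    """

    group: str
    sites: list[GenomicInterval]
    support: pd.DataFrame
    provenance: list[str]

    def __len__(self) -> int:
        return len(self.sites)

    def site_names(self) -> list[str]:
        return [iv.name for iv in self.sites]


class OverlapResult(NamedTuple):
    fraction: float
    n_overlapping: int
    n_query: int


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path, sample_id: str | None = None, group: str = "") -> PeakSet:
    """Read a BED3+ file into a :class:`PeakSet`.

    ``track``/``browser``/``#`` comment lines and blank lines are skipped.
    A name of ``"."`` is kept literally; a score of ``"."`` becomes ``None``.
    Malformed lines raise :class:`BedParseError` with their line number.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(path, lineno, f"expected >= 3 tab-separated fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise BedParseError(path, lineno, f"non-integer coordinates: {exc}") from None
            name = fields[3] if len(fields) > 3 else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise BedParseError(path, lineno, f"non-numeric score {fields[4]!r}") from None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
                )
            except ValidationError as exc:
                raise BedParseError(path, lineno, str(exc)) from None
    return PeakSet(sample_id=sample_id, group=group, intervals=intervals)


def write_bed(peaks: PeakSet | Sequence[GenomicInterval], path) -> None:
    """Write intervals as BED6. Missing names become ``"."``, missing scores
    ``0``; scores outside [0, 1000] are clamped with a logged warning."""
    intervals = peaks.intervals if isinstance(peaks, PeakSet) else list(peaks)
    intervals = normalize_intervals(intervals)
    clamped = 0
    with open(path, "w") as fh:
        for iv in intervals:
            score = 0.0 if iv.score is None else float(iv.score)
            if score < 0 or score > 1000:
                score = min(max(score, 0.0), 1000.0)
                clamped += 1
            score_str = f"{score:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score_str}\t{iv.strand}\n"
            )
    if clamped:
        log.warning("write_bed(%s): clamped %d score(s) to [0, 1000]", path, clamped)


# ---------------------------------------------------------------------------
# Interval algebra


def merge_intervals(
    intervals: Iterable[GenomicInterval], min_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap on the same chromosome is <= ``min_gap``.

    With the default ``min_gap=0`` touching intervals (``a.end == b.start``,
    gap exactly 0) are joined; intervals separated by at least one base are
    not.  The output is disjoint, sorted, unstranded and nameless, and its
    base-pair union equals the union of the input.
    """
    out: list[GenomicInterval] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    for iv in normalize_intervals(intervals):
        if iv.chrom == cur_chrom and iv.start - cur_end <= min_gap:
            cur_end = max(cur_end, iv.end)
        else:
            if cur_chrom is not None:
                out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur_chrom is not None:
        out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return out


def _chrom_arrays(intervals: Sequence[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, sorted_ends) arrays, starts sorted ascending."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = {}
    for chrom, ivs in by_chrom.items():
        starts = np.array(sorted(iv.start for iv in ivs), dtype=np.int64)
        ends = np.array(sorted(iv.end for iv in ivs), dtype=np.int64)
        out[chrom] = (starts, ends)
    return out


def count_overlaps(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> np.ndarray:
    """For each query interval, the number of subject intervals overlapping it
    by >= 1 bp.  Exact for arbitrary (possibly self-overlapping) subjects:
    #(s.start < q.end) - #(s.end <= q.start)."""
    arrays = _chrom_arrays(subjects)
    counts = np.zeros(len(queries), dtype=np.int64)
    for i, q in enumerate(queries):
        if q.chrom not in arrays:
            continue
        starts, ends = arrays[q.chrom]
        n_started = np.searchsorted(starts, q.end, side="left")
        n_finished = np.searchsorted(ends, q.start, side="right")
        counts[i] = n_started - n_finished
    return counts


def site_name(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def consensus_sites(
    peak_sets: Sequence[PeakSet], min_overlap: int | None = None
) -> ConsensusSiteSet:
    """Consensus sites of one group of replicates.

    Pools and merges all replicate peaks, then keeps each merged interval only
    if peaks from at least ``min_overlap`` distinct replicates overlap it
    (default: all replicates).  Per-replicate overlapping-peak counts are
    returned as the ``support`` table.
    """
    if not peak_sets:
        raise DataError("consensus_sites requires at least one PeakSet")
    groups = {ps.group for ps in peak_sets}
    if len(groups) != 1:
        raise DataError(f"all PeakSets must share one group label, got {sorted(groups)}")
    group = peak_sets[0].group
    n_rep = len(peak_sets)
    if min_overlap is None:
        min_overlap = n_rep
    if not (1 <= min_overlap <= n_rep):
        raise ConfigError(
            f"min_overlap={min_overlap} out of range for {n_rep} replicate(s)"
        )

    pooled = [iv for ps in peak_sets for iv in ps.intervals]
    merged = merge_intervals(pooled)
    support = np.column_stack(
        [count_overlaps(merged, ps.intervals) for ps in peak_sets]
    ) if merged else np.zeros((0, n_rep), dtype=np.int64)
    keep = (support > 0).sum(axis=1) >= min_overlap

    sites = []
    for iv, ok in zip(merged, keep):
        if ok:
            sites.append(GenomicInterval(iv.chrom, iv.start, iv.end, name=site_name(iv)))
    support_df = pd.DataFrame(
        support[keep],
        index=[s.name for s in sites],
        columns=[ps.sample_id for ps in peak_sets],
    )
    return ConsensusSiteSet(
        group=group,
        sites=sites,
        support=support_df,
        provenance=[ps.sample_id for ps in peak_sets],
    )


def overlap_fraction(
    query: ConsensusSiteSet | Sequence[GenomicInterval],
    reference: ConsensusSiteSet | Sequence[GenomicInterval],
) -> OverlapResult:
    """Fraction of query sites overlapping (>= 1 bp) any reference site.

    An empty query raises :class:`DataError` — the fraction is undefined,
    not silently zero.
    """
    q = query.sites if isinstance(query, ConsensusSiteSet) else list(query)
    r = reference.sites if isinstance(reference, ConsensusSiteSet) else list(reference)
    if not q:
        raise DataError("overlap_fraction is undefined for an empty query set")
    counts = count_overlaps(q, r)
    n_overlap = int((counts > 0).sum())
    return OverlapResult(fraction=n_overlap / len(q), n_overlapping=n_overlap, n_query=len(q))
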