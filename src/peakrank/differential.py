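"""Differential binding over consensus sites: CPM normalization, a per-site
two-group Welch test, the PC2-loading noise filter, and gained/lost
classification.

The per-site test is a two-sample t-test on log2 counts-per-million — a
deliberate, documented stand-in for a DiffBind-style negative-binomial
consensus of DESeq2 and edgeR, which is out of scope here.  The default
uses the pooled-variance (Student) statistic: with 3 replicates per group
the Welch-Satterthwaite approximation is measurably conservative (true
size ~0.035 at nominal 0.05 even for ideal normal data), while the pooled
test is calibrated and matches the shared-variance philosophy of the NB
tools it stands in for; ``variance="welch"`` is available for designs with
genuinely heteroskedastic groups.  Significance can be judged on the raw
p-value (``mode="raw"``, mirroring the common "P < 0.05" DiffBind usage)
or on the BH-adjusted p-value (``mode="adjusted"``).

The noise filter computes a PCA of the samples x differential-sites matrix
(samples are observations, sites are variables, columns mean-centered,
unscaled, via SVD).  A site's "loading" is its entry in the unit-norm
second right singular vector; sites with |loading| above the threshold are
treated as noisy and removed.  Because singular vectors are sign
indeterminate, only the magnitude is used.  Note the scale of unit-norm
loadings shrinks like m^-1/2 with the number of sites m, so a fixed
absolute threshold is meaningful only relative to the size of the site set
it was chosen for (see docs/methods.md).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError, ValidationError

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "chrom", "start", "end", "log2_fold_change", "p_value", "adjusted_p",
    "direction", "pc2_loading", "filtered", "variance_fallback",
]


@dataclass
class CountMatrix:
    """Raw read counts per consensus site (rows) and sample (columns).

    ``site_table`` carries the interval coordinates per site id; ``groups``
    maps sample id -> condition label.
    """

    counts: pd.DataFrame
    groups: Mapping[str, str]
    site_table: pd.DataFrame  # index: site_id; columns: chrom, start, end

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(self.site_table.index):
            raise ValidationError("counts and site_table must share the same site index")
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValidationError(f"samples missing a group label: {missing}")
        if (self.counts.values < 0).any():
            raise ValidationError("counts must be non-negative")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    def to_tsv(self, path) -> None:
        out = self.site_table.join(self.counts)
        out.index.name = "site_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, groups: Mapping[str, str] | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="site_id")
        site_table = df[["chrom", "start", "end"]]
        counts = df.drop(columns=["chrom", "start", "end"])
        if groups is None:
            # sample columns follow the "<GROUP>_<replicate>" convention
            groups = {s: s.rsplit("_", 1)[0] for s in counts.columns}
        return cls(counts=counts, groups=dict(groups), site_table=site_table)


@dataclass
class NormalizedMatrix:
    """log2(CPM + pseudocount) values, same shape as the raw counts."""

    logcpm: pd.DataFrame
    groups: Mapping[str, str]
    site_table: pd.DataFrame
    pseudocount: float

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.logcpm.columns if self.groups[s] == group]


@dataclass
class PC2FilterResult:
    retained: list[str]
    removed: list[str]
    loadings: pd.Series  # unit-norm PC2 loadings per site id (NaN when skipped)
    skipped: bool = False


def normalize_counts(cm: CountMatrix, pseudocount: float = 0.5) -> NormalizedMatrix:
    """Counts-per-million per sample, then log2(cpm + pseudocount).

    Raw CPM columns sum to 1e6 exactly; an all-zero sample is an error
    because its library size is undefined.
    """
    libsize = cm.counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise DataError(f"all-zero sample(s): {list(zero.index)}")
    cpm = cm.counts / libsize * 1e6
    logcpm = np.log2(cpm + pseudocount)
    return NormalizedMatrix(
        logcpm=logcpm, groups=dict(cm.groups), site_table=cm.site_table, pseudocount=pseudocount
    )


def test_differential_sites(
    norm: NormalizedMatrix,
    groups: tuple[str, str] = ("TIL", "TNIL"),
    alpha: float = 0.05,
    mode: str = "raw",
    variance: str = "pooled",
) -> pd.DataFrame:
    """Per-site two-sample t-test on log2 CPM, group A over group B.

    Positive log2 fold change means higher occupancy in ``groups[0]``
    (gained).  ``variance`` selects the pooled (default) or Welch
    statistic; under Welch, sites with zero within-group variance in both
    groups fall back to the pooled test and are flagged in
    ``variance_fallback``.  Returns a DataFrame indexed by site id with
    :data:`RESULT_COLUMNS`.
    """
    if mode not in ("raw", "adjusted"):
        raise ConfigError(f"mode must be 'raw' or 'adjusted', got {mode!r}")
    if variance not in ("pooled", "welch"):
        raise ConfigError(f"variance must be 'pooled' or 'welch', got {variance!r}")
    ga, gb = groups
    cols_a = norm.samples_in(ga)
    cols_b = norm.samples_in(gb)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise DataError(
            f"need >= 2 samples per group for testing, got {len(cols_a)} ({ga}) / {len(cols_b)} ({gb})"
        )
    a = norm.logcpm[cols_a].values
    b = norm.logcpm[cols_b].values
    lfc = a.mean(axis=1) - b.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # scipy warns about precision loss on near-constant sites; those are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_res = stats.ttest_ind(a, b, axis=1, equal_var=(variance == "pooled"))
    pvals = np.asarray(t_res.pvalue, dtype=float)

    # Degenerate sites: zero variance in both groups -> undefined statistic.
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    fallback = degenerate.copy()
    if degenerate.any():
        if variance == "welch":
            with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                pooled = stats.ttest_ind(a[degenerate], b[degenerate], axis=1, equal_var=True)
            pvals[degenerate] = np.asarray(pooled.pvalue, dtype=float)
        # both variances zero: identical values -> p = 1; different -> p -> 0
        pvals[degenerate] = np.where(
            np.isnan(pvals[degenerate]), np.where(lfc[degenerate] == 0, 1.0, 0.0), pvals[degenerate]
        )
        log.warning(
            "test_differential_sites: %d site(s) with zero within-group variance handled by fallback",
            int(degenerate.sum()),
        )
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    padj = multipletests(pvals, method="fdr_bh")[1]

    sig = pvals < alpha if mode == "raw" else padj < alpha
    direction = np.where(~sig, "ns", np.where(lfc > 0, "gained", np.where(lfc < 0, "lost", "ns")))

    out = norm.site_table.copy()
    out["log2_fold_change"] = lfc
    out["p_value"] = pvals
    out["adjusted_p"] = padj
    out["direction"] = direction
    out["pc2_loading"] = np.nan
    out["filtered"] = "N"
    out["variance_fallback"] = fallback
    return out[RESULT_COLUMNS]


def pc2_noise_filter(
    norm: NormalizedMatrix | pd.DataFrame,
    site_ids: Sequence[str],
    threshold: float = 0.005,
) -> PC2FilterResult:
    """Remove differential sites with |PC2 loading| above ``threshold``.

    PCA is computed on the samples x sites submatrix (sites as variables,
    columns mean-centered, unscaled) by singular value decomposition;
    loadings are the entries of the unit-norm second right singular vector.
    With fewer than 3 sites, fewer than 3 samples, or fewer than two nonzero
    singular values the filter is skipped with a warning and everything is
    retained.
    """
    logcpm = norm.logcpm if isinstance(norm, NormalizedMatrix) else norm
    site_ids = list(site_ids)
    missing = [s for s in site_ids if s not in logcpm.index]
    if missing:
        raise DataError(f"site ids absent from the normalized matrix: {missing[:5]}")
    nan_loadings = pd.Series(np.nan, index=site_ids, name="pc2_loading")
    if len(site_ids) < 3 or logcpm.shape[1] < 3:
        log.warning(
            "pc2_noise_filter skipped: need >= 3 sites and >= 3 samples, got %d x %d",
            len(site_ids), logcpm.shape[1],
        )
        return PC2FilterResult(retained=site_ids, removed=[], loadings=nan_loadings, skipped=True)

    X = logcpm.loc[site_ids].T.values  # samples x sites
    X = X - X.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    if (s > tol).sum() < 2:
        log.warning("pc2_noise_filter skipped: fewer than 2 nonzero singular values")
        return PC2FilterResult(retained=site_ids, removed=[], loadings=nan_loadings, skipped=True)

    loadings = pd.Series(vt[1], index=site_ids, name="pc2_loading")
    noisy = loadings.abs() > threshold
    removed = list(loadings.index[noisy])
    retained = list(loadings.index[~noisy])
    log.info(
        "pc2_noise_filter: removed %d of %d differential site(s) at |loading| > %g",
        len(removed), len(site_ids), threshold,
    )
    return PC2FilterResult(retained=retained, removed=removed, loadings=loadings)


def apply_pc2_filter(
    results: pd.DataFrame,
    norm: NormalizedMatrix,
    threshold: float | None = 0.005,
    alpha: float = 0.05,
    mode: str = "raw",
) -> tuple[pd.DataFrame, PC2FilterResult | None]:
    """Annotate the differential-test table with PC2 loadings and mark noisy
    significant sites ``filtered="Y"``.  ``threshold=None`` disables the
    filter (the audit columns stay empty)."""
    out = results.copy()
    if threshold is None:
        return out, None
    pcol = "p_value" if mode == "raw" else "adjusted_p"
    diff_ids = list(out.index[out[pcol] < alpha])
    fr = pc2_noise_filter(norm, diff_ids, threshold=threshold)
    out.loc[fr.loadings.index, "pc2_loading"] = fr.loadings
    out.loc[fr.removed, "filtered"] = "Y"
    out.loc[fr.removed, "direction"] = "ns"
    return out, fr


def classify_sites(results: pd.DataFrame, alpha: float = 0.05, mode: str = "raw") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition tested (and possibly PC2-filtered) sites into gained and
    lost tables by significance and fold-change sign."""
    if mode not in ("raw", "adjusted"):
        raise ConfigError(f"mode must be 'raw' or 'adjusted', got {mode!r}")
    if results.empty:
        empty = results.iloc[0:0]
        return empty.copy(), empty.copy()
    pcol = "p_value" if mode == "raw" else "adjusted_p"
    usable = results[results["filtered"] != "Y"]
    sig = usable[usable[pcol] < alpha]
    gained = sig[sig["log2_fold_change"] > 0].copy()
    lost = sig[sig["log2_fold_change"] < 0].copy()
    return gained, lost
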