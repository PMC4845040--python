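"""Paired RNA-seq transporter fold-change analysis with subset FDR.

Counts from seven donors, each contributing a rifampin-treated and a
vehicle-treated library, are CPM-normalized, filtered for expression,
converted to per-donor log2 fold changes (with zero counts replaced by the
minimum nonzero normalized value so the log is defined), tested for a
treatment effect, and BH-corrected over the transporter catalogue only.

Fold changes are displayed with the signed-reciprocal convention of the
field's tables: a doubling prints as 2.0, a halving as -2.0, and 1.0 means
no change (never -1.0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import TransporterCatalogue

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "cpm_normalize",
    "expressed_filter",
    "per_donor_log2fc",
    "paired_test",
    "subset_bh_fdr",
    "signed_fold_display",
    "TransporterDE",
    "TransporterDEResults",
]


@dataclass
class CountMatrix:
    """Gene x sample read counts with a paired donor/treatment design."""

    counts: pd.DataFrame
    samples: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("sample metadata index must match count columns")
        for col in ("donor", "treatment"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata is missing the {col!r} column")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def donors(self) -> list:
        return sorted(self.samples["donor"].unique())

    def arm_columns(self, treatment: str) -> list[str]:
        return list(self.samples.index[self.samples["treatment"] == treatment])

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        """Read counts and sample sheet; a ``library_size`` column in the
        sample sheet overrides the column-sum default."""
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        samples.index = samples.index.astype(str)
        counts.columns = counts.columns.astype(str)
        samples = samples.loc[counts.columns]
        libs = (
            samples["library_size"].astype(float)
            if "library_size" in samples.columns
            else None
        )
        return cls(counts=counts, samples=samples, library_sizes=libs)


def cpm_normalize(c: CountMatrix) -> pd.DataFrame:
    """Counts per million: count * 1e6 / library size, per column."""
    return c.counts * 1e6 / c.library_sizes


def expressed_filter(
    c: CountMatrix,
    min_reads: float = 10.0,
    quantifier: str = "all",
    min_count: int | None = None,
) -> CountMatrix:
    """Keep genes whose CPM reaches ``min_reads`` consistently in one arm.

    ``quantifier`` controls how many samples of an arm must pass: ``"all"``
    (default), ``"any"``, or an integer threshold via ``min_count``.
    """
    cpm = cpm_normalize(c)
    keep = pd.Series(False, index=c.counts.index)
    for treatment in sorted(c.samples["treatment"].unique()):
        cols = c.arm_columns(treatment)
        passing = (cpm[cols] >= min_reads).sum(axis=1)
        if quantifier == "all":
            keep |= passing == len(cols)
        elif quantifier == "any":
            keep |= passing >= 1
        elif quantifier == "count":
            if min_count is None:
                raise ValueError("quantifier='count' requires min_count")
            keep |= passing >= min_count
        else:
            raise ValueError(f"unknown quantifier {quantifier!r}")
    logger.info("expressed filter kept %d of %d genes", int(keep.sum()), len(keep))
    return CountMatrix(
        counts=c.counts[keep],
        samples=c.samples,
        library_sizes=c.library_sizes,
    )


def per_donor_log2fc(
    c: CountMatrix,
    treatment: str = "rifampin",
    control: str = "vehicle",
    zero_substitution: str = "global",
) -> pd.DataFrame:
    """Per-donor log2(treated / control) on CPM values.

    Zeroes cannot enter the log, so a zero normalized value is replaced by
    the minimum nonzero normalized value — of the whole matrix by default
    (``zero_substitution='global'``) or of the gene's own row
    (``'per_gene'``).
    """
    cpm = cpm_normalize(c)
    arr = cpm.to_numpy(dtype=float)
    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        raise ValueError("count matrix has no nonzero values")
    global_min = nonzero.min()
    if zero_substitution == "global":
        filled = cpm.where(cpm > 0, global_min)
    elif zero_substitution == "per_gene":
        row_min = cpm.where(cpm > 0).min(axis=1).fillna(global_min)
        filled = cpm.where(cpm > 0, row_min, axis=0)
    else:
        raise ValueError("zero_substitution must be 'global' or 'per_gene'")
    out = {}
    for d in c.donors:
        sub = c.samples[c.samples["donor"] == d]
        col_t = sub.index[sub["treatment"] == treatment]
        col_c = sub.index[sub["treatment"] == control]
        if len(col_t) != 1 or len(col_c) != 1:
            raise ValueError(f"donor {d!r} is not paired across both treatments")
        out[d] = np.log2(filled[col_t[0]] / filled[col_c[0]])
    return pd.DataFrame(out, index=cpm.index)


def signed_fold_display(linear_fold: float) -> float:
    """Signed-reciprocal display: x for x >= 1, -1/x for x < 1.

    A fold of exactly 1 (no change) displays as 1.0, never -1.0.
    """
    if linear_fold <= 0:
        raise ValueError("linear fold change must be positive")
    return linear_fold if linear_fold >= 1 else -1.0 / linear_fold


def paired_test(
    log2fc: pd.DataFrame,
    mode: str = "paired",
    counts: CountMatrix | None = None,
    treatment: str = "rifampin",
    control: str = "vehicle",
) -> pd.Series:
    """Per-gene p-values for a rifampin effect.

    ``mode='paired'`` (default): one-sample t-test of the per-donor log2
    fold changes against zero, honouring the donor pairing.  ``mode='pooled'``:
    an exact binomial test on the summed counts per arm against the
    library-size ratio — the reading that can produce the extreme p-values
    deep-coverage data supports.  Zero-variance genes in paired mode get a
    degenerate-case p (1 if the effect is 0, else the smallest
    representable) with a warning.
    """
    if mode == "paired":
        arr = log2fc.to_numpy(dtype=float)
        n = arr.shape[1]
        if n < 2:
            raise ValueError("paired test requires at least 2 donors")
        means = arr.mean(axis=1)
        sds = arr.std(axis=1, ddof=1)
        pvals = np.ones(len(arr))
        degenerate = sds == 0
        ok = ~degenerate
        t = np.zeros(len(arr))
        t[ok] = means[ok] / (sds[ok] / np.sqrt(n))
        pvals[ok] = 2 * stats.t.sf(np.abs(t[ok]), df=n - 1)
        if degenerate.any():
            nz = degenerate & (means != 0)
            if nz.any():
                warnings.warn(
                    f"{int(nz.sum())} gene(s) with zero variance and nonzero "
                    "effect; p reported as smallest representable",
                    stacklevel=2,
                )
            pvals[nz] = np.finfo(float).tiny
            pvals[degenerate & (means == 0)] = 1.0
        return pd.Series(pvals, index=log2fc.index, name="p")
    if mode == "pooled":
        if counts is None:
            raise ValueError("pooled mode requires the count matrix")
        cols_t = counts.arm_columns(treatment)
        cols_c = counts.arm_columns(control)
        lib_t = float(counts.library_sizes[cols_t].sum())
        lib_c = float(counts.library_sizes[cols_c].sum())
        prob = lib_t / (lib_t + lib_c)
        pvals = []
        for _, row in counts.counts.iterrows():
            k = int(row[cols_t].sum())
            m = int(row[cols_c].sum())
            if k + m == 0:
                pvals.append(1.0)
                continue
            pvals.append(stats.binomtest(k, k + m, prob).pvalue)
        return pd.Series(pvals, index=counts.counts.index, name="p")
    raise ValueError("mode must be 'paired' or 'pooled'")


def subset_bh_fdr(pvals: pd.Series, catalogue: TransporterCatalogue) -> pd.Series:
    """BH step-up q-values computed over the catalogue genes only.

    The correction universe is the set of catalogue genes present in
    ``pvals``; genes outside the catalogue receive no q-value and cannot
    influence the ones inside.
    """
    in_cat = [g for g in pvals.index if g in catalogue]
    out = pd.Series(np.nan, index=pvals.index, name="q")
    if in_cat:
        out[in_cat] = multipletests(pvals[in_cat].to_numpy(), method="fdr_bh")[1]
    return out


@dataclass
class TransporterDEResults:
    """Differential-expression results over the transporter catalogue.

    ``frame`` is indexed by gene with per-gene mean log2FC, the
    signed-reciprocal display fold, p and q; ``log2fc`` keeps the per-donor
    vectors feeding the correlation stage.
    """

    frame: pd.DataFrame
    log2fc: pd.DataFrame
    test_mode: str
    q_threshold: float = 0.05

    def de_table(self, catalogue_only: bool = True) -> pd.DataFrame:
        """Result rows sorted by q then |fold|, with a significance flag."""
        tab = self.frame.copy()
        if catalogue_only:
            tab = tab[tab["q"].notna()]
        tab = tab.assign(significant=tab["q"] < self.q_threshold)
        tab = tab.reindex(
            tab.assign(_absf=tab["fold_change"].abs())
            .sort_values(["q", "_absf"], ascending=[True, False], kind="mergesort")
            .index
        )
        return tab.reset_index()

    def effect_vectors(self, genes=None) -> pd.DataFrame:
        vecs = self.log2fc
        return vecs if genes is None else vecs.loc[[g for g in genes if g in vecs.index]]

    def summary(self) -> str:
        tab = self.de_table()
        lines = [
            "Paired transporter differential expression",
            f"  test mode: {self.test_mode}; genes tested (catalogue): {len(tab)}",
            f"  significant at q < {self.q_threshold}: {int(tab['significant'].sum())}",
            "",
            tab.head(10).to_string(index=False),
        ]
        return "\n".join(lines)


class TransporterDE:
    """Paired fold-change model for transporter genes in a count matrix."""

    def __init__(
        self,
        counts: CountMatrix,
        catalogue: TransporterCatalogue,
        treatment: str = "rifampin",
        control: str = "vehicle",
        min_reads: float = 10.0,
        expressed_quantifier: str = "all",
        zero_substitution: str = "global",
    ):
        self.counts = counts
        self.catalogue = catalogue
        self.treatment = treatment
        self.control = control
        self.min_reads = min_reads
        self.expressed_quantifier = expressed_quantifier
        self.zero_substitution = zero_substitution

    def fit(self, test_mode: str = "paired") -> TransporterDEResults:
        filtered = expressed_filter(
            self.counts, min_reads=self.min_reads, quantifier=self.expressed_quantifier
        )
        log2fc = per_donor_log2fc(
            filtered,
            treatment=self.treatment,
            control=self.control,
            zero_substitution=self.zero_substitution,
        )
        pvals = paired_test(
            log2fc,
            mode=test_mode,
            counts=filtered,
            treatment=self.treatment,
            control=self.control,
        )
        qvals = subset_bh_fdr(pvals, self.catalogue)
        mean_l2 = log2fc.mean(axis=1)
        display = mean_l2.map(lambda v: signed_fold_display(float(2.0**v)))
        frame = pd.DataFrame(
            {
                "mean_log2fc": mean_l2,
                "fold_change": display,
                "p": pvals,
                "q": qvals,
            },
            index=log2fc.index.rename("gene"),
        )
        return TransporterDEResults(frame=frame, log2fc=log2fc, test_mode=test_mode)
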