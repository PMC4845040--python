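"""Relative quantification of qPCR Ct data by the delta-delta-Ct method.

The conventions follow the kidney-cell replication arm exactly: each
sample's target Ct is subtracted FROM the reference (GAPDH) Ct
(dCt = Ct_reference - Ct_target), the control-condition dCt is subtracted
from the rifampin-condition dCt, and fold change = 2**ddCt.  With this
pairing of signs a one-cycle drop in the target's Ct under treatment (i.e.
doubling of template) gives ddCt = +1 and fold 2, so the formula is
internally consistent even though the textbook form is usually written
2**(-ddCt) with the opposite dCt direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DdctRecord",
    "delta_ct",
    "ddct_fold_change",
    "replicate_stats",
    "analyze_qpcr_table",
]


def delta_ct(ct_target: float, ct_reference: float):
    """Reference-minus-target Ct (cycles)."""
    return ct_reference - ct_target


def ddct_fold_change(dct_treated: float, dct_control: float) -> float:
    """Fold change 2**(dCt_treated - dCt_control) for reference-minus-target dCts."""
    return float(2.0 ** (dct_treated - dct_control))


@dataclass(frozen=True)
class DdctRecord:
    """Relative-expression result for one gene across biologic replicates."""

    gene: str
    n_replicates: int
    mean_ddct: float
    fold_change: float
    sem_ddct: float
    fold_low: float      # 2**(mean - SEM)
    fold_high: float     # 2**(mean + SEM)
    sem_fold: float      # SEM of the per-replicate linear folds
    p_value: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")


def replicate_stats(
    gene: str,
    dct_treated: np.ndarray | list,
    dct_control: np.ndarray | list,
) -> DdctRecord:
    """Mean fold, SEM and a two-sample t-test from per-replicate dCts.

    The per-replicate ddCts are each treated replicate's dCt minus the mean
    control dCt; the SEM is computed on those ddCts and carried to the fold
    scale as the asymmetric band 2**(mean +/- SEM).  The SEM of the
    per-replicate linear folds is reported alongside, since averaging folds
    directly is biased.  Significance is a two-sided t-test between the two
    conditions' dCts.
    """
    a = np.asarray(dct_treated, dtype=float)
    b = np.asarray(dct_control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per condition")
    ddct = a - b.mean()
    mean_ddct = float(ddct.mean())
    sem_ddct = float(ddct.std(ddof=1) / np.sqrt(len(ddct)))
    folds = 2.0**ddct
    sem_fold = float(folds.std(ddof=1) / np.sqrt(len(folds)))
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            p = 1.0
        else:
            warnings.warn(
                f"{gene}: zero variance in both conditions with different means; "
                "p reported as smallest representable",
                stacklevel=2,
            )
            p = float(np.finfo(float).tiny)
    else:
        p = float(stats.ttest_ind(a, b).pvalue)
    return DdctRecord(
        gene=gene,
        n_replicates=len(a),
        mean_ddct=mean_ddct,
        fold_change=float(2.0**mean_ddct),
        sem_ddct=sem_ddct,
        fold_low=float(2.0 ** (mean_ddct - sem_ddct)),
        fold_high=float(2.0 ** (mean_ddct + sem_ddct)),
        sem_fold=sem_fold,
        p_value=p,
    )


def analyze_qpcr_table(
    table: pd.DataFrame,
    reference_gene: str = "GAPDH",
    treatment: str = "rifampin",
    control: str = "vehicle",
) -> pd.DataFrame:
    """ddCt analysis of a long-format Ct table.

    ``table`` needs columns ``gene, condition, replicate, ct``.  Each
    target gene's Ct is normalized against the reference gene's Ct of the
    same (condition, replicate) well.
    """
    required = {"gene", "condition", "replicate", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"qPCR table is missing column(s): {sorted(missing)}")
    ref = table[table["gene"] == reference_gene].set_index(["condition", "replicate"])["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} not found in table")
    records = []
    for gene, sub in table[table["gene"] != reference_gene].groupby("gene", sort=True):
        sub = sub.set_index(["condition", "replicate"])
        dct = delta_ct(sub["ct"], ref.loc[sub.index])
        try:
            treated = dct.xs(treatment, level="condition").to_numpy()
            ctrl = dct.xs(control, level="condition").to_numpy()
        except KeyError as exc:
            raise ValueError(f"gene {gene!r} lacks condition {exc}") from None
        records.append(replicate_stats(str(gene), treated, ctrl))
    return pd.DataFrame([r.__dict__ for r in records])
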