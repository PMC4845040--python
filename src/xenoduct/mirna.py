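"""miRNA Ct-array preprocessing and donor-paired differential expression.

The pipeline reproduces the OpenArray processing order: technical-duplicate
merging with ceiling censoring, control small-RNA removal, a detection
filter requiring consistent expression in at least one treatment arm,
quantile normalization across samples, and a donor-blocked differential
test of the rifampin effect.  Ct is inversely related to log2 abundance, so
a negative treatment-minus-vehicle Ct difference means induction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CtMatrix",
    "merge_technical_duplicates",
    "remove_controls",
    "detection_filter",
    "quantile_normalize",
    "pca_qc",
    "MirnaDifferential",
    "MirnaDifferentialResults",
    "preprocess",
]

CT_CEILING = 40.0
DETECTION_CUTOFF = 35.0
CONTROL_PATTERNS = ("U6", "RNU")


@dataclass
class CtMatrix:
    """Cycle-threshold values, features x samples, with sample metadata.

    ``values`` holds Ct in cycles with NaN marking undetected wells.
    ``samples`` is indexed by the column names of ``values`` and carries
    ``donor``, ``treatment`` and (before merging) ``replicate`` columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    ceiling: float = CT_CEILING

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata index must match value columns")
        for col in ("donor", "treatment"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata is missing the {col!r} column")
        finite = self.values.to_numpy()[np.isfinite(self.values.to_numpy())]
        if finite.size and (finite <= 0).any():
            raise ValueError("Ct values must be positive cycles")

    @property
    def treatments(self) -> list[str]:
        return sorted(self.samples["treatment"].unique())

    @property
    def donors(self) -> list:
        return sorted(self.samples["donor"].unique())

    def arm_columns(self, treatment: str) -> list[str]:
        return list(self.samples.index[self.samples["treatment"] == treatment])

    @classmethod
    def from_csv(cls, values_path, samples_path, **kw) -> "CtMatrix":
        values = pd.read_csv(values_path, index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        samples.index = samples.index.astype(str)
        values.columns = values.columns.astype(str)
        return cls(values=values, samples=samples.loc[values.columns], **kw)


def merge_technical_duplicates(raw: CtMatrix) -> CtMatrix:
    """Collapse exactly two technical replicates per biological sample.

    Both detected: the mean.  Both undetected: the ceiling Ct (default 40).
    Exactly one detected: the detectable value.
    """
    if "replicate" not in raw.samples.columns:
        raise ValueError("merging requires a 'replicate' column in sample metadata")
    groups = raw.samples.groupby(["donor", "treatment"], sort=True)
    bad = [key for key, g in groups if len(g) != 2]
    if bad:
        raise ValueError(
            f"expected exactly 2 technical replicates per (donor, treatment); offending: {bad}"
        )
    cols, meta = [], []
    merged = {}
    for (donor, treatment), g in groups:
        a, b = raw.values[g.index[0]], raw.values[g.index[1]]
        mean = (a + b) / 2  # NaN if either is NaN
        one = a.fillna(b).where(a.isna() | b.isna())  # the detected value if exactly one
        out = mean.fillna(one).fillna(raw.ceiling)
        name = f"{donor}_{treatment}"
        merged[name] = out
        cols.append(name)
        meta.append({"donor": donor, "treatment": treatment})
    values = pd.DataFrame(merged, index=raw.values.index)[cols]
    samples = pd.DataFrame(meta, index=pd.Index(cols, name="sample"))
    return CtMatrix(values=values, samples=samples, ceiling=raw.ceiling)


def remove_controls(
    m: CtMatrix, control_patterns: tuple[str, ...] = CONTROL_PATTERNS
) -> CtMatrix:
    """Drop control small RNAs (names starting U6/RNU, case-insensitive)."""
    pats = tuple(p.upper() for p in control_patterns)
    keep = [f for f in m.values.index if not str(f).upper().startswith(pats)]
    n_removed = len(m.values) - len(keep)
    logger.info("removed %d control features", n_removed)
    return CtMatrix(values=m.values.loc[keep], samples=m.samples, ceiling=m.ceiling)


def detection_filter(
    m: CtMatrix,
    min_samples: int = 4,
    ct_cutoff: float = DETECTION_CUTOFF,
) -> CtMatrix:
    """Keep features detected (Ct < cutoff) in >= ``min_samples`` samples of
    at least one treatment arm, on the merged per-sample values."""
    detected = m.values < ct_cutoff
    keep_mask = pd.Series(False, index=m.values.index)
    for treatment in m.treatments:
        cols = m.arm_columns(treatment)
        keep_mask |= detected[cols].sum(axis=1) >= min_samples
    logger.info(
        "detection filter kept %d of %d features", int(keep_mask.sum()), len(keep_mask)
    )
    return CtMatrix(values=m.values[keep_mask], samples=m.samples, ceiling=m.ceiling)


def quantile_normalize(m: CtMatrix) -> CtMatrix:
    """Force every sample column onto the common rank-wise mean distribution.

    Ties within a column receive the mean of the reference values their
    positions would have occupied.
    """
    v = m.values
    if v.isna().any().any():
        raise ValueError("quantile normalization requires a complete matrix")
    reference = pd.DataFrame(np.sort(v.to_numpy(), axis=0)).mean(axis=1).to_numpy()
    out = {}
    for col in v.columns:
        s = v[col]
        pos = s.rank(method="first").astype(int).to_numpy() - 1
        assigned = pd.Series(reference[pos], index=s.index)
        out[col] = assigned.groupby(s).transform("mean")
    values = pd.DataFrame(out, index=v.index)[v.columns]
    return CtMatrix(values=values, samples=m.samples, ceiling=m.ceiling)


def pca_qc(m: CtMatrix, n_components: int = 2) -> dict:
    """Sample-level PCA for systematic-variation QC; no automatic exclusion.

    Returns sample scores on the leading components, the fraction of
    variance each explains, and the sample metadata for labelling.
    """
    X = m.values.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(s))
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=m.values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return {
        "scores": scores,
        "variance_explained": explained[:k],
        "samples": m.samples.copy(),
    }


def preprocess(
    raw: CtMatrix,
    control_patterns: tuple[str, ...] = CONTROL_PATTERNS,
    min_samples: int = 4,
    ct_cutoff: float = DETECTION_CUTOFF,
) -> CtMatrix:
    """The full fixed-order preprocessing: merge, remove controls, detection
    filter, quantile normalize."""
    m = merge_technical_duplicates(raw)
    m = remove_controls(m, control_patterns)
    m = detection_filter(m, min_samples=min_samples, ct_cutoff=ct_cutoff)
    return quantile_normalize(m)


@dataclass
class MirnaDifferentialResults:
    """Per-feature rifampin effects from the donor-paired Ct analysis.

    ``frame`` has one row per feature with the mean treatment-minus-vehicle
    Ct difference (``delta_delta_ct``, cycles), its abundance-oriented
    counterpart ``log2fc = -delta_delta_ct``, the paired-test p-value and
    the BH-adjusted q.  ``effects`` holds the per-donor vectors used by the
    correlation stage.
    """

    frame: pd.DataFrame
    effects: pd.DataFrame
    orientation: str
    method: str
    alpha: float = 0.05

    def effect_vectors(self) -> pd.DataFrame:
        """Per-donor miRNA effect vectors in the configured orientation."""
        if self.orientation == "abundance":
            return -self.effects
        return self.effects.copy()

    def summary(self) -> str:
        n_sig = int((self.frame["q"] < self.alpha).sum())
        lines = [
            "Donor-paired miRNA differential analysis",
            f"  method: {self.method}; features: {len(self.frame)}; "
            f"donors: {self.effects.shape[1]}",
            f"  significant at q < {self.alpha}: {n_sig}",
            "",
            self.frame.sort_values("q").head(10).to_string(),
        ]
        return "\n".join(lines)


class MirnaDifferential:
    """Donor-blocked differential model for a paired, normalized T matrix.

    The general mixed/blocked two-way layout (treatment fixed, donor as
    block) reduces, with two paired conditions, to a one-sample test of the
    per-donor treatment-minus-vehicle differences against zero, and that is
    the default; ``method='anova'`` fits the blocked OLS explicitly and
    gives the identical F/t inference.
    """

    def __init__(
        self,
        data: CtMatrix,
        treatment: str = "rifampin",
        control: str = "vehicle",
        orientation: str = "abundance",
    ):
        if treatment not in data.treatments or control not in data.treatments:
            raise ValueError(
                f"treatments {data.treatments} do not include "
                f"{treatment!r} and {control!r}"
            )
        donors = data.donors
        if len(donors) < 2:
            raise ValueError("need at least 2 donors for a paired analysis")
        for d in donors:
            sub = data.samples[data.samples["donor"] == d]
            if set(sub["treatment"]) != {treatment, control}:
                raise ValueError(f"donor {d!r} is not paired across both treatments")
        if orientation not in ("abundance", "ct"):
            raise ValueError("orientation must be 'abundance' or 'ct'")
        self.data = data
        self.treatment = treatment
        self.control = control
        self.orientation = orientation

    def _donor_differences(self) -> pd.DataFrame:
        cols_t, cols_c = {}, {}
        for d in self.data.donors:
            sub = self.data.samples[self.data.samples["donor"] == d]
            cols_t[d] = sub.index[sub["treatment"] == self.treatment][0]
            cols_c[d] = sub.index[sub["treatment"] == self.control][0]
        diffs = {
            d: self.data.values[cols_t[d]] - self.data.values[cols_c[d]]
            for d in self.data.donors
        }
        return pd.DataFrame(diffs, index=self.data.values.index)

    def fit(self, method: str = "paired") -> MirnaDifferentialResults:
        if method not in ("paired", "anova"):
            raise ValueError("method must be 'paired' or 'anova'")
        diffs = self._donor_differences()
        effects = diffs.to_numpy()
        means = effects.mean(axis=1)
        pvals = np.ones(len(diffs))
        n = effects.shape[1]
        for i, row in enumerate(effects):
            sd = row.std(ddof=1)
            if sd == 0:
                if means[i] == 0:
                    pvals[i] = 1.0
                else:
                    warnings.warn(
                        f"feature {diffs.index[i]!r}: zero variance with nonzero "
                        "effect; p-value reported as smallest representable",
                        stacklevel=2,
                    )
                    pvals[i] = np.finfo(float).tiny
            else:
                t = means[i] / (sd / np.sqrt(n))
                pvals[i] = 2 * stats.t.sf(abs(t), df=n - 1)
        qvals = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
        frame = pd.DataFrame(
            {
                "delta_delta_ct": means,
                "log2fc": -means,
                "p": pvals,
                "q": qvals,
            },
            index=diffs.index.rename("mirna"),
        )
        return MirnaDifferentialResults(
            frame=frame,
            effects=diffs,
            orientation=self.orientation,
            method=method,
        )
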