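"""Exact small-sample Spearman rank correlation.

With seven paired donors there are only 7! = 5040 equally likely rank
orderings under the null of no association, so the permutation distribution
of Spearman's rho can be enumerated completely instead of relying on the
usual large-sample t approximation (whose assumptions a 7-point effect
vector cannot support).  The two-sided exact p-value is the fraction of all
n! permutations of one vector's ranks whose |rho| is at least the observed
|rho|.  Ties are handled with average ranks, and the enumeration permutes
the observed multiset of tied ranks.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationRecord",
    "spearman_rho",
    "exact_p",
    "correlate_pair",
    "correlation_matrix",
    "select_significant",
    "null_distribution_sum_d2",
]

#: largest n for which the full n! enumeration is attempted (8! = 40320)
MAX_ENUM = 8

_EPS = 1e-9


class ConstantVectorError(ValueError):
    """Raised when Spearman correlation is undefined (a constant vector)."""


def _checked_ranks(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 paired observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError(
            "Spearman correlation is undefined for a constant vector"
        )
    return stats.rankdata(x), stats.rankdata(y)


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman_rho(x, y) -> float:
    """Spearman's rho on average-ranked values.

    Without ties this equals ``1 - 6 * sum(d^2) / (n * (n^2 - 1))`` where
    ``d`` are the rank differences.
    """
    rx, ry = _checked_ranks(x, y)
    return _rho_of_ranks(rx, ry)


def exact_p(
    x,
    y,
    max_enum: int = MAX_ENUM,
    fallback: bool = False,
) -> float:
    """Two-sided exact permutation p-value for Spearman's rho.

    Enumerates all ``n!`` permutations of y's ranks (including duplicated
    arrangements of tied ranks, so each of the n! orderings keeps equal null
    weight) and counts those with ``|rho| >= |rho_observed|``.  For
    ``n > max_enum`` the t-distribution approximation is used instead when
    ``fallback=True``; otherwise that is an error.
    """
    rx, ry = _checked_ranks(x, y)
    n = len(rx)
    if n > max_enum:
        if not fallback:
            raise ValueError(
                f"n={n} exceeds the enumeration cap ({max_enum}); "
                "pass fallback=True to use the large-sample approximation"
            )
        warnings.warn(
            f"n={n} > {max_enum}: using the large-sample t approximation "
            "instead of full enumeration",
            stacklevel=2,
        )
        return float(stats.spearmanr(x, y).pvalue)

    # rho is affine in the dot product rx . perm(ry): precompute the threshold
    # on the dot product once and count permutations by dot product alone.
    rxc = rx - rx.mean()
    sy = ry - ry.mean()
    denom = math.sqrt((rxc @ rxc) * (sy @ sy))
    obs = abs(float(rxc @ sy)) / denom
    # rxc sums to zero, so |rho| of a permutation is |rxc . perm(ry)| / denom;
    # the n! dot products collapse to one matrix product against the cached
    # permutation matrix of y's rank multiset.
    perms = _perm_matrix(tuple(sorted(ry)))
    count = int((np.abs(perms @ rxc) >= (obs - _EPS) * denom).sum())
    return count / math.factorial(n)


@lru_cache(maxsize=8)
def _perm_matrix(rank_multiset: tuple) -> np.ndarray:
    """All n! orderings of a rank multiset as an (n!, n) array."""
    return np.array(list(itertools.permutations(rank_multiset)), dtype=float)


@dataclass(frozen=True)
class CorrelationRecord:
    """Result of one exact Spearman test between two effect vectors."""

    id_a: str
    id_b: str
    rho: float
    p_exact: float
    n: int
    ties: bool


def correlate_pair(
    id_a: str,
    x,
    id_b: str,
    y,
    max_enum: int = MAX_ENUM,
    fallback: bool = False,
) -> CorrelationRecord:
    rx, ry = _checked_ranks(x, y)
    ties = len(np.unique(rx)) < len(rx) or len(np.unique(ry)) < len(ry)
    return CorrelationRecord(
        id_a=id_a,
        id_b=id_b,
        rho=_rho_of_ranks(rx, ry),
        p_exact=exact_p(x, y, max_enum=max_enum, fallback=fallback),
        n=len(rx),
        ties=ties,
    )


def correlation_matrix(
    a: pd.DataFrame,
    b: pd.DataFrame | None = None,
    max_enum: int = MAX_ENUM,
    fallback: bool = False,
) -> pd.DataFrame:
    """Exact Spearman tests for all pairs of effect vectors.

    ``a`` and ``b`` are frames of per-donor effect vectors (features in rows,
    donors in columns, shared column order).  With ``b=None`` the upper
    triangle of ``a`` against itself is computed (self-pairs excluded).
    Constant vectors are skipped with a warning.
    """
    records = []
    if b is None:
        pairs = itertools.combinations(a.index, 2)
        get = lambda i, j: (a.loc[i], a.loc[j])  # noqa: E731
    else:
        if list(a.columns) != list(b.columns):
            raise ValueError("effect-vector frames must share the donor column order")
        pairs = itertools.product(a.index, b.index)
        get = lambda i, j: (a.loc[i], b.loc[j])  # noqa: E731
    for i, j in pairs:
        x, y = get(i, j)
        try:
            rec = correlate_pair(str(i), x, str(j), y, max_enum=max_enum, fallback=fallback)
        except ConstantVectorError:
            warnings.warn(f"skipping constant effect vector in pair ({i}, {j})", stacklevel=2)
            continue
        records.append(rec)
    return pd.DataFrame(
        {
            "id_a": [r.id_a for r in records],
            "id_b": [r.id_b for r in records],
            "rho": [r.rho for r in records],
            "p_exact": [r.p_exact for r in records],
            "n": [r.n for r in records],
            "ties": [r.ties for r in records],
        }
    )


def select_significant(
    records: pd.DataFrame,
    alpha: float = 0.05,
    feature_q: dict[str, float] | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Significant correlations, split into positive/negative panels.

    ``feature_q`` optionally maps feature ids to their own differential-test
    q-values; records whose features appear there with q >= ``q_threshold``
    are dropped (the rule used for reporting only transporters that were
    themselves regulated).
    """
    out = records[records["p_exact"] < alpha].copy()
    if feature_q is not None:
        def _ok(fid: str) -> bool:
            q = feature_q.get(fid)
            return q is None or q < q_threshold

        out = out[[_ok(i) and _ok(j) for i, j in zip(out["id_a"], out["id_b"])]]
    out["panel"] = np.where(out["rho"] > 0, "positive", "negative")
    return out.sort_values(["panel", "p_exact"], kind="mergesort").reset_index(drop=True)


def null_distribution_sum_d2(n: int) -> dict[int, int]:
    """Exact null distribution of ``sum(d^2)`` over all n! tie-free rankings."""
    base = np.arange(1, n + 1)
    counts: dict[int, int] = {}
    for perm in itertools.permutations(base):
        s = int(((base - np.asarray(perm)) ** 2).sum())
        counts[s] = counts.get(s, 0) + 1
    return counts
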