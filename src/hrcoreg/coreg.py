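"""Anchored gene-set co-regulation statistic with a subset-permutation null.

The question: is an anchor gene (BRCA1 or BRCA2) more strongly co-expressed
with a designated target set (the other upregulated HR genes) than with
random same-size subsets of a candidate pool (all upregulated genes)?

Statistic. For each target gene, Spearman's rho between the anchor and the
target across samples; the per-target coefficients are pooled through
Fisher's Z-transformation — ``z' = atanh(rho)``, arithmetic mean of z',
back-transformed with tanh. The same pooling is used for the observed
statistic, for each null draw, and for the null mean.

Null. ``m`` independent draws of ``k`` genes without replacement from the
pool (anchor excluded from the pool; the designated targets stay *in* the
pool). The empirical p-value is add-one smoothed:

    P = (n + 1) / (m + 1)

where ``n`` counts draws whose pooled statistic is as high as or higher
than the observed one. P is never 0 and never exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ATANH_CLAMP = 1.0 - 1e-12


class CoregError(ValueError):
    pass


def fisher_pool(rhos: Sequence[float]) -> float:
    """tanh(mean(atanh(rho))); |rho| = 1 is clamped to avoid infinities."""
    r = np.asarray(rhos, dtype=float)
    if r.size == 0:
        raise CoregError("cannot pool an empty set of correlations")
    if (np.abs(r) >= 1.0).any():
        import warnings
        warnings.warn("|rho| = 1 clamped before Fisher pooling", stacklevel=2)
        r = np.clip(r, -ATANH_CLAMP, ATANH_CLAMP)
    return float(np.tanh(np.arctanh(r).mean()))


@dataclass
class CoregStat:
    """Observed (and optionally null-calibrated) co-regulation statistic."""

    anchor: str
    targets: tuple[str, ...]
    rho_per_target: pd.Series = field(repr=False)
    pooled: float = 0.0
    null_mean: Optional[float] = None
    p_empirical: Optional[float] = None
    m: Optional[int] = None
    n_ge: Optional[int] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "anchor": self.anchor,
            "targets": list(self.targets),
            "observed": self.pooled,
            "null_mean": self.null_mean,
            "p_empirical": self.p_empirical,
            "m": self.m,
            "n_ge": self.n_ge,
            "seed": self.seed,
            "per_gene_rho": {
                g: float(r) for g, r in self.rho_per_target.items()
            },
        }


def _spearman_vs_anchor(
    matrix: pd.DataFrame, anchor: str, genes: Sequence[str]
) -> pd.Series:
    """Spearman rho of the anchor against each listed gene, vectorized as a
    Pearson correlation of rank-transformed rows."""
    if anchor not in matrix.index:
        raise CoregError(f"anchor {anchor!r} not in matrix")
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise CoregError(f"genes not in matrix: {missing[:5]}")
    if matrix.shape[1] < 3:
        raise CoregError("need >= 3 samples")
    sub = matrix.loc[[anchor, *genes]].to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, sub)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    if (norms == 0).any():
        bad = [g for g, nn in zip([anchor, *genes], norms) if nn == 0]
        raise CoregError(f"constant expression vector(s): {bad}")
    r = (ranks[1:] @ ranks[0]) / (norms[1:] * norms[0])
    return pd.Series(np.clip(r, -1.0, 1.0), index=list(genes))


def pooled_rho(
    matrix: pd.DataFrame, anchor: str, targets: Sequence[str]
) -> CoregStat:
    """Observed anchored statistic: Fisher-pooled Spearman rho of the anchor
    against each target gene."""
    targets = tuple(targets)
    if not targets:
        raise CoregError("target set is empty")
    if anchor in targets:
        raise CoregError("anchor must not be in the target set")
    rho = _spearman_vs_anchor(matrix, anchor, targets)
    return CoregStat(
        anchor=anchor, targets=targets, rho_per_target=rho,
        pooled=fisher_pool(rho.to_numpy()),
    )


@dataclass
class NullDistribution:
    """Pooled statistic for m random size-k subsets of the candidate pool."""

    draws: np.ndarray = field(repr=False)
    pool: tuple[str, ...]
    k: int
    seed: Optional[int]

    @property
    def m(self) -> int:
        return int(self.draws.size)

    @property
    def null_mean(self) -> float:
        """Fisher-pooled mean of the per-draw pooled statistics (the same
        pooling used for the observed statistic)."""
        return fisher_pool(self.draws)


def permutation_null(
    matrix: pd.DataFrame,
    anchor: str,
    pool: Sequence[str],
    k: int,
    m: int = 10_000,
    seed: Optional[int] = None,
    with_replacement: bool = False,
) -> NullDistribution:
    """m random size-k gene subsets of the pool, each Fisher-pooled.

    The anchor is excluded from the pool (error if present). Because the
    per-gene rho does not depend on the subset, the anchor-vs-gene
    correlations are computed once and each draw pools a random subset of
    the precomputed z' values — exactly equivalent to recomputing the
    statistic per draw.
    """
    pool = tuple(pool)
    if anchor in pool:
        raise CoregError("anchor must be excluded from the pool")
    if len(pool) < k:
        raise CoregError(f"pool size {len(pool)} smaller than k = {k}")
    if m < 1:
        raise CoregError("need at least one draw")
    rho = _spearman_vs_anchor(matrix, anchor, pool).to_numpy()
    z = np.arctanh(np.clip(rho, -ATANH_CLAMP, ATANH_CLAMP))
    rng = np.random.default_rng(seed)
    draws = np.empty(m)
    for i in range(m):
        idx = rng.choice(len(pool), size=k, replace=with_replacement)
        draws[i] = np.tanh(z[idx].mean())
    return NullDistribution(draws=draws, pool=pool, k=k, seed=seed)


def empirical_p(observed: float, null: NullDistribution) -> tuple[float, int]:
    """Add-one empirical p: ``P = (n+1)/(m+1)`` with ``n`` counting null
    draws >= observed (exact float comparison)."""
    n = int(np.sum(null.draws >= observed))
    return (n + 1) / (null.m + 1), n


@dataclass
class MedianSplit:
    """Samples split at the anchor's median expression (ties to low)."""

    low: tuple[str, ...]
    high: tuple[str, ...]
    median: float


def median_split(
    values: pd.Series, ties: str = "low"
) -> MedianSplit:
    """Split samples at the median of the anchor's expression.

    ``ties="low"`` puts samples at exactly the median into the low group
    (low = x <= median); ``ties="high"`` puts them into the high group.
    """
    if len(values) < 2:
        raise CoregError("need >= 2 samples to split")
    med = float(np.median(values.to_numpy(dtype=float)))
    if ties == "low":
        low = values.index[values <= med]
        high = values.index[values > med]
    elif ties == "high":
        low = values.index[values < med]
        high = values.index[values >= med]
    else:
        raise CoregError(f"ties must be 'low' or 'high', got {ties!r}")
    return MedianSplit(low=tuple(low), high=tuple(high), median=med)


def coregulation_test(
    matrix: pd.DataFrame,
    anchor: str,
    targets: Sequence[str],
    pool: Sequence[str],
    k: Optional[int] = None,
    m: int = 10_000,
    seed: Optional[int] = None,
) -> CoregStat:
    """Full anchored co-regulation test.

    Composes the observed pooled statistic, the subset-permutation null
    (k defaults to the target-set size) and the add-one empirical p-value.
    ``matrix`` is any genes × samples expression table on a scale whose
    ranks are meaningful (normalized counts or log2CPM).
    """
    stat = pooled_rho(matrix, anchor, targets)
    k = k if k is not None else len(stat.targets)
    null = permutation_null(matrix, anchor, pool, k=k, m=m, seed=seed)
    p, n_ge = empirical_p(stat.pooled, null)
    stat.null_mean = null.null_mean
    stat.p_empirical = p
    stat.m = null.m
    stat.n_ge = n_ge
    stat.seed = seed
    return stat
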