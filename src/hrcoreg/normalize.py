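"""nCounter-style normalization chain for panel count matrices.

Pipeline order (each step optional but conventionally composed in this
order): background adjustment from the internal negative controls, a
within-sample scaling from the internal positive controls, an across-sample
input correction from the housekeeping genes, gene exclusion, and replicate
averaging. Counts are kept as real numbers after normalization — no
re-rounding — since the downstream differential-expression test is
rank-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import (
    ENDOGENOUS, HOUSEKEEPING, NEGATIVE, POSITIVE, CountMatrix,
)
from .synthetic import TAGSET_EXCLUDED_GENES  # canonical exclusion list


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizationFactors:
    """Per-sample factors computed along the chain, for audit and QC.

    ``flags`` maps sample -> list of QC flag strings (currently only
    out-of-range positive-control scale factors).
    """

    background: Optional[pd.Series] = None
    positive_scale: Optional[pd.Series] = None
    housekeeping_scale: Optional[pd.Series] = None
    flags: dict[str, list[str]] = field(default_factory=dict)

    def add_flag(self, sample: str, flag: str) -> None:
        self.flags.setdefault(sample, []).append(flag)

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        if self.background is not None:
            cols["background"] = self.background
        if self.positive_scale is not None:
            cols["positive_scale"] = self.positive_scale
        if self.housekeeping_scale is not None:
            cols["housekeeping_scale"] = self.housekeeping_scale
        df = pd.DataFrame(cols)
        df["flags"] = [";".join(self.flags.get(s, [])) for s in df.index]
        return df


def background_adjust(
    matrix: CountMatrix, statistic: str = "mean", k: float = 2.0
) -> tuple[CountMatrix, pd.Series]:
    """Subtract the per-sample negative-control background, clamped at 0.

    The background statistic is the mean of the negative controls
    (``statistic="mean"``), or mean + k·SD (``statistic="mean_sd"``).
    Control rows (positive and negative) are retained unmodified for audit.
    """
    negatives = matrix.class_values(NEGATIVE)
    if negatives.empty:
        raise NormalizationError(
            "no negative-control probes present; cannot adjust background"
        )
    background = negatives.mean(axis=0)
    if statistic == "mean_sd":
        background = background + k * negatives.std(axis=0, ddof=1).fillna(0.0)
    elif statistic != "mean":
        raise NormalizationError(f"unknown background statistic {statistic!r}")
    out = matrix.values.astype(float).copy()
    adjust = matrix.probe_class.isin([ENDOGENOUS, HOUSEKEEPING])
    out.loc[adjust] = (out.loc[adjust] - background).clip(lower=0.0)
    return matrix.with_values(out), background.rename("background")


def positive_control_normalize(
    matrix: CountMatrix, flag_range: tuple[float, float] = (0.3, 3.0)
) -> tuple[CountMatrix, NormalizationFactors]:
    """Within-sample scaling from the positive-control titration probes.

    Per-sample factor = (arithmetic mean over samples of the per-sample
    geometric means of the positive controls) / (that sample's geometric
    mean). Endogenous, housekeeping and positive-control counts are
    multiplied by the factor (so re-computed factors on the output are 1);
    factors outside ``flag_range`` set a QC flag but do not drop the sample.
    """
    pos = matrix.class_values(POSITIVE)
    if pos.shape[0] < 2:
        raise NormalizationError("need >= 2 positive-control probes")
    if (pos.to_numpy() <= 0).any():
        bad = pos.columns[(pos <= 0).any(axis=0)]
        raise NormalizationError(
            f"zero positive-control count (geometric mean undefined) in "
            f"sample(s): {list(bad)}"
        )
    geo = np.exp(np.log(pos).mean(axis=0))
    factors = geo.mean() / geo
    out = matrix.values.astype(float).copy()
    scale = matrix.probe_class.isin([ENDOGENOUS, HOUSEKEEPING, POSITIVE])
    out.loc[scale] = out.loc[scale] * factors
    nf = NormalizationFactors(positive_scale=factors.rename("positive_scale"))
    lo, hi = flag_range
    for s, f in factors.items():
        if not lo <= f <= hi:
            nf.add_flag(s, "positive_scale_out_of_range")
    return matrix.with_values(out), nf


def housekeeping_normalize(
    matrix: CountMatrix,
) -> tuple[CountMatrix, pd.Series]:
    """Across-sample input correction from the housekeeping gene means.

    Per-sample factor = (grand mean over samples of per-sample housekeeping
    means) / (that sample's housekeeping mean); endogenous and housekeeping
    counts are multiplied by the factor, making housekeeping means exactly
    equal across samples.
    """
    hk = matrix.class_values(HOUSEKEEPING)
    if hk.empty:
        raise NormalizationError("no housekeeping genes present")
    means = hk.mean(axis=0)
    zero = means.index[means <= 0]
    if len(zero):
        raise NormalizationError(
            f"housekeeping mean is zero for sample(s): {list(zero)}"
        )
    factors = means.mean() / means
    out = matrix.values.astype(float).copy()
    scale = matrix.probe_class.isin([ENDOGENOUS, HOUSEKEEPING])
    out.loc[scale] = out.loc[scale] * factors
    return matrix.with_values(out), factors.rename("housekeeping_scale")


def apply_exclusions(
    matrix: CountMatrix, exclusions: Iterable[str]
) -> CountMatrix:
    """Drop listed genes (e.g. a defective TagSet lot) before analysis.

    Genes absent from the matrix produce a warning, not an error — panel
    dialects differ.
    """
    exclusions = list(exclusions)
    missing = [g for g in exclusions if g not in matrix.values.index]
    if missing:
        warnings.warn(
            f"exclusion list genes not in matrix: {missing}", stacklevel=2
        )
    return matrix.drop_genes(exclusions)


def average_replicates(
    matrix: CountMatrix, samples: pd.DataFrame
) -> tuple[CountMatrix, pd.DataFrame]:
    """Collapse replicate re-runs to their per-gene arithmetic mean.

    ``samples`` must be indexed by sample with a ``replicate_of`` column
    (empty for base samples). Groups of any size are averaged into the base
    sample; non-replicated samples pass through. Returns the collapsed
    matrix and the collapsed sample sheet.
    """
    rep = samples["replicate_of"].fillna("")
    unknown = [
        s for s, base in rep.items()
        if base and base not in matrix.values.columns
    ]
    if unknown:
        raise NormalizationError(
            f"replicate_of references missing sample(s): "
            f"{[rep[s] for s in unknown]}"
        )
    groups: dict[str, list[str]] = {}
    for s in matrix.values.columns:
        base = rep.get(s, "") or s
        groups.setdefault(base, []).append(s)
    out = pd.DataFrame(
        {base: matrix.values[members].mean(axis=1)
         for base, members in groups.items()},
    )
    out = out[[b for b in groups]]  # preserve base-sample order
    collapsed = samples.loc[list(groups)].copy()
    collapsed["replicate_of"] = ""
    return matrix.with_values(out), collapsed


@dataclass
class NormalizedResult:
    matrix: CountMatrix
    samples: pd.DataFrame
    factors: NormalizationFactors


def normalize_pipeline(
    matrix: CountMatrix,
    samples: pd.DataFrame,
    exclusions: Iterable[str] = TAGSET_EXCLUDED_GENES,
    background_statistic: str = "mean",
) -> NormalizedResult:
    """Full chain: background → positive → housekeeping → exclusion →
    replicate averaging."""
    m, background = background_adjust(matrix, statistic=background_statistic)
    m, nf = positive_control_normalize(m)
    m, hk = housekeeping_normalize(m)
    m = apply_exclusions(m, exclusions) if exclusions else m
    m, collapsed = average_replicates(m, samples)
    factors = NormalizationFactors(
        background=background,
        positive_scale=nf.positive_scale,
        housekeeping_scale=hk,
        flags=nf.flags,
    )
    return NormalizedResult(matrix=m, samples=collapsed, factors=factors)
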