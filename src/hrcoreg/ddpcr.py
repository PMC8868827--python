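"""Absolute mRNA quantitation from droplet digital PCR well summaries.

A ddPCR well partitions the RT-PCR mix into thousands of droplets; target
molecules distribute across droplets approximately Poisson, so the mean
occupancy (copies per droplet, CPD) follows from the fraction of *negative*
droplets:

    lambda = -ln(n_negative / n_total),    c = lambda / V_d   [copies/µL]

with V_d the droplet volume in µL. Confidence intervals use the delta
method on the positive fraction. A duplex well carries a target on the FAM
channel and a reference gene (e.g. GUSB) on the HEX channel; reporting
normalizes the target concentration to the reference. The input-equalization
loading scheme runs a first assay at a fixed RNA mass, measures the
reference CPD, and scales the second assay's input so the reference sits at
a standard occupancy (default 0.05 CPD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: droplet volume conventions, µL per droplet
V_D_INSTRUMENT = 0.00085  # QX200 nominal
V_D_CONVENTION = 0.001    # 1 nL convention under which 0.05 CPD = 50 copies/µL

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class DdpcrError(ValueError):
    pass


@dataclass
class DropletWell:
    """One well of a duplex droplet assay: totals and positives per channel."""

    well: str
    target_fam: str
    target_hex: str
    n_droplets: int
    n_pos_fam: int
    n_pos_hex: int
    no_rt: bool = False

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise DdpcrError(f"well {self.well}: no droplets read")
        for n in (self.n_pos_fam, self.n_pos_hex):
            if not 0 <= n <= self.n_droplets:
                raise DdpcrError(
                    f"well {self.well}: positives outside [0, total]"
                )

    def positives(self, channel: str) -> int:
        if channel == "fam":
            return self.n_pos_fam
        if channel == "hex":
            return self.n_pos_hex
        raise DdpcrError(f"unknown channel {channel!r}")

    def target(self, channel: str) -> str:
        return self.target_fam if channel == "fam" else self.target_hex


@dataclass
class ConcentrationEstimate:
    """Poisson occupancy and concentration for one channel of one well."""

    well: str
    target: str
    channel: str
    lambda_cpd: float          # copies per droplet
    copies_per_ul: float
    ci_low: float
    ci_high: float
    droplet_volume: float      # µL, recorded with every estimate
    n_droplets: int
    flags: tuple[str, ...] = ()


def estimate_concentration(
    well: DropletWell,
    channel: str = "fam",
    droplet_volume: float = V_D_CONVENTION,
) -> ConcentrationEstimate:
    """Poisson occupancy fit for one channel of a droplet well.

    ``lambda = -ln((total - positives)/total)`` and ``c = lambda / V_d``.
    The 95% CI comes from the delta method: ``SE(lambda) =
    sqrt(p_hat / ((1 - p_hat) * total))``, clamped at 0.

    Degenerate wells are handled explicitly rather than erroring out of the
    batch: a saturated well (all droplets positive) reports a finite lower
    bound using half a pseudo-negative and is flagged ``saturated``; a well
    with zero positives reports c = 0 with a one-sided rule-of-three upper
    bound and is flagged ``zero_positives``.
    """
    if droplet_volume <= 0:
        raise DdpcrError("droplet volume must be positive")
    n = well.n_droplets
    k = well.positives(channel)
    flags: list[str] = []
    if k == n:
        # saturation: occupancy unbounded above; report a lower bound
        lam = float(np.log(n / 0.5))
        c = lam / droplet_volume
        return ConcentrationEstimate(
            well=well.well, target=well.target(channel), channel=channel,
            lambda_cpd=lam, copies_per_ul=c, ci_low=c, ci_high=float("inf"),
            droplet_volume=droplet_volume, n_droplets=n,
            flags=("saturated",),
        )
    if k == 0:
        lam_up = 3.0 / n  # rule of three
        return ConcentrationEstimate(
            well=well.well, target=well.target(channel), channel=channel,
            lambda_cpd=0.0, copies_per_ul=0.0, ci_low=0.0,
            ci_high=lam_up / droplet_volume,
            droplet_volume=droplet_volume, n_droplets=n,
            flags=("zero_positives",),
        )
    p_hat = k / n
    lam = float(-np.log1p(-p_hat))
    se = float(np.sqrt(p_hat / ((1.0 - p_hat) * n)))
    c = lam / droplet_volume
    lo = max(0.0, (lam - Z_95 * se)) / droplet_volume
    hi = (lam + Z_95 * se) / droplet_volume
    return ConcentrationEstimate(
        well=well.well, target=well.target(channel), channel=channel,
        lambda_cpd=lam, copies_per_ul=c, ci_low=lo, ci_high=hi,
        droplet_volume=droplet_volume, n_droplets=n, flags=tuple(flags),
    )


@dataclass
class NormalizedRatio:
    """Target concentration normalized to the duplex reference gene."""

    target: str
    reference: str
    ratio: float
    ci_low: float
    ci_high: float


def normalized_ratio(
    target: ConcentrationEstimate, reference: ConcentrationEstimate
) -> NormalizedRatio:
    """Ratio of target to reference concentration with a delta-method CI.

    The CI is computed on the log-ratio treating the two channel estimates
    as independent (they share droplets; the approximation is conservative
    at low occupancy): ``SE(log ratio)^2 = (SE_t/c_t)^2 + (SE_r/c_r)^2``.
    """
    if reference.copies_per_ul <= 0:
        raise DdpcrError("reference concentration must be positive")
    if target.copies_per_ul <= 0:
        # ratio 0; upper bound from target CI alone
        return NormalizedRatio(
            target=target.target, reference=reference.target, ratio=0.0,
            ci_low=0.0, ci_high=target.ci_high / reference.copies_per_ul,
        )
    r = target.copies_per_ul / reference.copies_per_ul
    # recover SE(c) from the symmetric CI halfwidth
    se_t = (target.ci_high - target.copies_per_ul) / Z_95
    se_r = (reference.ci_high - reference.copies_per_ul) / Z_95
    se_log = np.sqrt(
        (se_t / target.copies_per_ul) ** 2
        + (se_r / reference.copies_per_ul) ** 2
    )
    return NormalizedRatio(
        target=target.target, reference=reference.target, ratio=r,
        ci_low=float(r * np.exp(-Z_95 * se_log)),
        ci_high=float(r * np.exp(Z_95 * se_log)),
    )


@dataclass
class LoadingScheme:
    """Two-assay input equalization to a standard reference occupancy."""

    first_mass_ng: float = 30.0
    measured_cpd: float | None = None
    target_cpd: float = 0.05
    max_load_ng: float = 100.0

    def __post_init__(self) -> None:
        if self.first_mass_ng <= 0 or self.target_cpd <= 0:
            raise DdpcrError("masses and CPDs must be positive")


def loading_mass(scheme: LoadingScheme) -> tuple[float, bool]:
    """Second-assay RNA input (ng) placing the reference at target CPD.

    Linearity of input: ``mass2 = mass1 * target_cpd / measured_cpd``.
    Returns ``(mass2, over_capacity)`` where the flag marks loads above
    ``max_load_ng``.
    """
    if scheme.measured_cpd is None or scheme.measured_cpd <= 0:
        raise DdpcrError("measured reference CPD must be positive")
    mass2 = scheme.first_mass_ng * scheme.target_cpd / scheme.measured_cpd
    return mass2, mass2 > scheme.max_load_ng


def no_rt_check(
    well: DropletWell,
    channel: str = "fam",
    droplet_volume: float = V_D_CONVENTION,
    threshold: float = 0.2,
) -> bool:
    """Pass/fail for a no-reverse-transcriptase contamination control.

    Passes iff the estimated concentration is at or below ``threshold``
    copies/µL (default 0.2, above the 0.16 copies/µL maximum seen in
    accepted runs).
    """
    if not well.no_rt:
        raise DdpcrError(f"well {well.well} is not flagged as a no-RT control")
    est = estimate_concentration(well, channel, droplet_volume)
    return est.copies_per_ul <= threshold


@dataclass
class ConcordanceResult:
    spearman_rho: float
    pearson_r: float
    discordant: tuple[str, ...]
    rank_differences: pd.Series = field(repr=False, default=None)


def concordance(
    platform_a: Sequence[float],
    platform_b: Sequence[float],
    sample_ids: Sequence[str],
    flag_fraction: float = 0.5,
) -> ConcordanceResult:
    """Cross-platform agreement of paired per-sample expression values.

    Computes Spearman and Pearson correlations over paired samples, and
    flags samples whose between-platform rank difference exceeds
    ``flag_fraction * n`` (default 0.5), the pattern of a single clearly
    discordant sample in an otherwise monotone relation.
    """
    a = np.asarray(platform_a, dtype=float)
    b = np.asarray(platform_b, dtype=float)
    ids = list(sample_ids)
    if not (len(a) == len(b) == len(ids)):
        raise DdpcrError("platform vectors and sample ids must be paired")
    if len(a) < 3:
        raise DdpcrError("need at least 3 paired samples")
    rho = float(stats.spearmanr(a, b).statistic)
    r = float(stats.pearsonr(a, b).statistic)
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    diff = pd.Series(np.abs(ra - rb), index=ids)
    cut = flag_fraction * len(a)
    flagged = tuple(diff.index[diff > cut])
    return ConcordanceResult(
        spearman_rho=rho, pearson_r=r, discordant=flagged,
        rank_differences=diff,
    )


# -- batch table interface -------------------------------------------------

def read_wells(path) -> list[DropletWell]:
    """Read droplet wells from CSV (columns well, target_fam, target_hex,
    n_droplets, n_pos_fam, n_pos_hex[, no_rt])."""
    df = pd.read_csv(path)
    wells = []
    for _, row in df.iterrows():
        wells.append(DropletWell(
            well=str(row["well"]),
            target_fam=str(row["target_fam"]),
            target_hex=str(row["target_hex"]),
            n_droplets=int(row["n_droplets"]),
            n_pos_fam=int(row["n_pos_fam"]),
            n_pos_hex=int(row["n_pos_hex"]),
            no_rt=bool(row.get("no_rt", False)),
        ))
    return wells


def quantify_wells(
    wells: Sequence[DropletWell], droplet_volume: float = V_D_CONVENTION
) -> pd.DataFrame:
    """Per-channel concentration table for a batch of wells."""
    rows = []
    for w in wells:
        for ch in ("fam", "hex"):
            e = estimate_concentration(w, ch, droplet_volume)
            rows.append({
                "well": e.well, "target": e.target, "channel": ch,
                "lambda_cpd": e.lambda_cpd,
                "copies_per_ul": e.copies_per_ul,
                "ci_low": e.ci_low, "ci_high": e.ci_high,
                "droplet_volume": e.droplet_volume,
                "flags": ";".join(e.flags),
            })
    return pd.DataFrame(rows)


def ratio_wells(
    wells: Sequence[DropletWell], droplet_volume: float = V_D_CONVENTION
) -> pd.DataFrame:
    """FAM/HEX normalized ratios for a batch of duplex wells."""
    rows = []
    for w in wells:
        t = estimate_concentration(w, "fam", droplet_volume)
        ref = estimate_concentration(w, "hex", droplet_volume)
        nr = normalized_ratio(t, ref)
        rows.append({
            "well": w.well, "target": nr.target, "reference": nr.reference,
            "ratio": nr.ratio, "ci_low": nr.ci_low, "ci_high": nr.ci_high,
        })
    return pd.DataFrame(rows)
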