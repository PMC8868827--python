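"""Synthetic study generators for the whole pipeline.

Three generators emulate the data structures the analysis stages consume:

* :func:`simulate_nanostring_study` — a hybridization-counting panel study
  of 11 normal fallopian-tube and 38 tumor samples over 180 endogenous
  probes (plus 12 housekeeping, 6 positive- and 8 negative-control probes),
  with per-lane size and efficiency factors, a shared latent factor that
  co-regulates a designated HR gene module, multiplicative tumor effects on
  designated up-/down-regulated genes, and two replicate re-runs.
* :func:`simulate_droplet_well` — droplet digital PCR wells in which each
  droplet is independently positive with probability ``1 - exp(-c * V_d)``.
* :func:`simulate_transcript_fixtures` — transcript/variant pairs that
  straddle every NMD rule boundary, including frameshifts whose PTC must be
  found by scanning the shifted reading frame.

Counts are Poisson with log-normal means: for endogenous gene g in sample s

    K_gs ~ Poisson(L_s * E_s * mu_g * effect_gs * latent_gs * noise_gs) + B_gs

where L_s is the lane size factor (RNA input), E_s the lane hybridization
efficiency (captured by the positive controls), mu_g the baseline mean,
``effect_gs`` the tumor up/down shift, ``latent_gs = exp(sd_f * f_s)`` the
shared module factor, noise per-cell log-normal, and B_gs ~ Poisson(bg) an
additive background also seen by the control probes. Each generator draws
from one explicitly seeded RNG stream; fixed seed implies byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ddpcr import DropletWell
from .matrix import (
    ENDOGENOUS, FALLOPIAN_TUBE, HOUSEKEEPING, NEGATIVE, POSITIVE, TUMOR,
    CountMatrix,
)
from .nmd import (
    FRAMESHIFT_DEL, FRAMESHIFT_INS, INFRAME_EXON_SKIP, MISSENSE, NONSENSE,
    STOP_CODONS, TranscriptModel, Variant,
)


class ConfigError(ValueError):
    pass


# the 12 upregulated HR genes beyond BRCA1/2 (merged HR + Fanconi anemia
# pathway) used as the default co-regulated module together with BRCA1/2
HR_TARGET_GENES = (
    "BRIP1", "BLM", "FANCD2", "FANCG", "FANCI", "GEN1",
    "RAD51", "RAD54L", "UBE2T", "USP1", "XRCC2", "XRCC3",
)

# genes excluded from analysis for a defective TagSet lot
TAGSET_EXCLUDED_GENES = (
    "ERCC1", "ERCC2", "ERCC3", "ERCC4", "ERCC5", "ERCC6", "ERCC8",
    "EXO1", "FAN1", "FANCA", "FANCB", "FANCC",
)

HR_PATHWAY = "Homologous Recombination and Fanconi Anemia"

_FILLER_PATHWAYS = (
    "Cell Cycle and Signaling",
    "Base excision repair",
    "Nucleotide Excision Repair",
    "Mismatch Repair",
    "Translesion Synthesis",
    "Non-homologous End Joining",
    "Apoptosis",
    "Checkpoint Activation",
    "Independent Repair Enzymes/Polymerases",
)


def _default_gene_names(n_endogenous: int) -> list[str]:
    named = ["BRCA1", "BRCA2", *HR_TARGET_GENES, *TAGSET_EXCLUDED_GENES]
    if n_endogenous <= len(named):
        return named[:n_endogenous]
    filler = [f"DDR{i:03d}" for i in range(1, n_endogenous - len(named) + 1)]
    return named + filler


@dataclass
class StudyConfig:
    """Study shape and statistical structure of a simulated panel run.

    The defaults are the study conditions: 11 normal + 38 tumor samples,
    180 endogenous + 12 housekeeping probes, 6 positive / 8 negative
    controls, a 14-gene co-regulated HR module (BRCA1, BRCA2 plus the 12 HR
    targets) whose shared latent factor gives a model log-scale pairwise
    correlation of ``latent_sd^2 / (latent_sd^2 + noise_sd^2)`` (~0.6 at
    the defaults), 47 upregulated and 25 downregulated genes in tumors.
    """

    n_normal: int = 11
    n_tumor: int = 38
    n_endogenous: int = 180
    n_housekeeping: int = 12
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    hr_module_genes: Optional[tuple[str, ...]] = None
    upregulated_genes: Optional[tuple[str, ...]] = None
    downregulated_genes: Optional[tuple[str, ...]] = None
    latent_sd: float = 0.49     # sqrt(1.5) * noise_sd -> module rho ~ 0.6
    noise_sd: float = 0.40      # per-gene log-scale biological noise
    tumor_upshift: float = 2.0
    tumor_downshift: float = 0.5
    lane_sd: float = 0.25       # log-normal sd of lane size factors
    efficiency_sd: float = 0.15  # log-normal sd of lane efficiencies
    background_mean: float = 5.0  # negative-control Poisson mean
    baseline_median: float = 200.0  # median endogenous expression level
    baseline_log_sd: float = 1.0
    housekeeping_median: float = 800.0
    housekeeping_log_sd: float = 0.3
    pos_control_top: float = 16384.0  # 4-fold geometric titration series
    pos_control_ratio: float = 4.0
    n_replicate_pairs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_normal", "n_tumor", "n_endogenous", "n_housekeeping",
                     "n_pos_controls", "n_neg_controls"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.latent_sd < 0 or self.noise_sd < 0:
            raise ConfigError("latent_sd and noise_sd must be >= 0")
        genes = _default_gene_names(self.n_endogenous)
        if self.hr_module_genes is None:
            module = [g for g in ("BRCA1", "BRCA2", *HR_TARGET_GENES)
                      if g in genes]
            self.hr_module_genes = tuple(module)
        else:
            self.hr_module_genes = tuple(self.hr_module_genes)
            missing = set(self.hr_module_genes) - set(genes)
            if missing:
                raise ConfigError(
                    f"hr_module_genes not in the panel: {sorted(missing)}"
                )
        if self.upregulated_genes is None:
            extra = [g for g in genes
                     if g.startswith("DDR")][: max(0, 47 - len(self.hr_module_genes))]
            self.upregulated_genes = tuple(
                list(self.hr_module_genes) + extra
            )
        else:
            self.upregulated_genes = tuple(self.upregulated_genes)
        if self.downregulated_genes is None:
            up = set(self.upregulated_genes)
            pool = [g for g in genes if g.startswith("DDR") and g not in up]
            self.downregulated_genes = tuple(pool[:25])
        else:
            self.downregulated_genes = tuple(self.downregulated_genes)

    @property
    def gene_names(self) -> list[str]:
        return _default_gene_names(self.n_endogenous)


@dataclass
class SimulatedStudy:
    """Bundle returned by :func:`simulate_nanostring_study`.

    ``truth`` holds the quantities the generator knows exactly (per-cell
    lane-free means, lane and efficiency factors, latent factor values),
    for closing the loop in normalization tests.
    """

    counts: CountMatrix
    annotation: pd.DataFrame
    samples: pd.DataFrame
    truth: dict = field(repr=False, default_factory=dict)


def simulate_nanostring_study(
    config: StudyConfig | None = None, seed: int | None = None
) -> SimulatedStudy:
    """Simulate a full panel study (counts, annotation, sample sheet).

    ``seed`` overrides ``config.seed`` when given. The sample sheet has one
    row per matrix column with columns ``group`` (tumor / fallopian_tube)
    and ``replicate_of`` (empty, or the base sample a re-run duplicates).
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    genes = config.gene_names
    hk_genes = [f"HK{i:02d}" for i in range(1, config.n_housekeeping + 1)]
    pos_genes = [f"POS_{chr(65 + i)}" for i in range(config.n_pos_controls)]
    neg_genes = [f"NEG_{chr(65 + i)}" for i in range(config.n_neg_controls)]

    normals = [f"FT{i:02d}" for i in range(1, config.n_normal + 1)]
    tumors = [f"T{i:02d}" for i in range(1, config.n_tumor + 1)]
    base_samples = normals + tumors
    groups = [FALLOPIAN_TUBE] * len(normals) + [TUMOR] * len(tumors)

    n_s = len(base_samples)
    n_g = len(genes)

    # per-gene baselines (fixed per study, drawn once)
    mu = config.baseline_median * np.exp(
        rng.normal(0.0, config.baseline_log_sd, size=n_g)
    )
    mu_hk = config.housekeeping_median * np.exp(
        rng.normal(0.0, config.housekeeping_log_sd, size=len(hk_genes))
    )
    titration = config.pos_control_top / (
        config.pos_control_ratio ** np.arange(config.n_pos_controls)
    )

    # per-sample lane factors and the shared latent factor
    lane = np.exp(rng.normal(0.0, config.lane_sd, size=n_s))
    efficiency = np.exp(rng.normal(0.0, config.efficiency_sd, size=n_s))
    latent_raw = rng.normal(0.0, 1.0, size=n_s)

    is_tumor = np.array([g == TUMOR for g in groups])
    effect = np.ones((n_g, n_s))
    up = set(config.upregulated_genes)
    down = set(config.downregulated_genes)
    module = set(config.hr_module_genes)
    for i, g in enumerate(genes):
        if g in up:
            effect[i, is_tumor] = config.tumor_upshift
        elif g in down:
            effect[i, is_tumor] = config.tumor_downshift

    # latent module factor: mean-one log-normal so the baseline is preserved
    latent = np.ones((n_g, n_s))
    if config.latent_sd > 0:
        lf = np.exp(config.latent_sd * latent_raw - config.latent_sd**2 / 2)
        for i, g in enumerate(genes):
            if g in module:
                latent[i, :] = lf

    noise = np.exp(
        rng.normal(0.0, config.noise_sd, size=(n_g, n_s))
        - config.noise_sd**2 / 2
    )

    true_mean = mu[:, None] * effect * latent * noise  # lane-free expectation
    lane_scale = lane * efficiency
    endo_mean = true_mean * lane_scale[None, :]
    hk_mean = mu_hk[:, None] * lane_scale[None, :]
    pos_mean = titration[:, None] * efficiency[None, :]

    def _counts(mean: np.ndarray) -> np.ndarray:
        return rng.poisson(mean) + rng.poisson(
            config.background_mean, size=mean.shape
        )

    endo = _counts(endo_mean)
    hk = _counts(hk_mean)
    pos = _counts(pos_mean)
    neg = rng.poisson(config.background_mean,
                      size=(len(neg_genes), n_s))

    values = pd.DataFrame(
        np.vstack([endo, hk, pos, neg]),
        index=pd.Index(genes + hk_genes + pos_genes + neg_genes, name="gene"),
        columns=base_samples,
    )

    # replicate re-runs: fresh Poisson redraw of the same lane mean
    replicate_of: dict[str, str] = {}
    rep_idx = list(range(min(config.n_replicate_pairs, n_s)))
    # one normal and one tumor first, then further alternating
    order = []
    if normals:
        order.append(0)
    if tumors:
        order.append(len(normals))
    for j in range(n_s):
        if j not in order:
            order.append(j)
    for j in order[: config.n_replicate_pairs]:
        base = base_samples[j]
        rep = f"{base}_rep2"
        col = np.concatenate([
            _counts(endo_mean[:, [j]]).ravel(),
            _counts(hk_mean[:, [j]]).ravel(),
            _counts(pos_mean[:, [j]]).ravel(),
            rng.poisson(config.background_mean, size=len(neg_genes)),
        ])
        values[rep] = col
        replicate_of[rep] = base

    pathway = []
    for g in genes:
        if g in ("BRCA1", "BRCA2") or g in HR_TARGET_GENES:
            pathway.append(HR_PATHWAY)
        elif g in TAGSET_EXCLUDED_GENES:
            pathway.append("Nucleotide Excision Repair"
                           if g.startswith("ERCC")
                           else HR_PATHWAY)
        else:
            pathway.append(
                _FILLER_PATHWAYS[sum(map(ord, g)) % len(_FILLER_PATHWAYS)]
            )
    annotation = pd.DataFrame(
        {
            "probe_class": ([ENDOGENOUS] * n_g
                            + [HOUSEKEEPING] * len(hk_genes)
                            + [POSITIVE] * len(pos_genes)
                            + [NEGATIVE] * len(neg_genes)),
            "pathway": (pathway + ["Housekeeping"] * len(hk_genes)
                        + [""] * (len(pos_genes) + len(neg_genes))),
        },
        index=values.index,
    )

    sample_rows = []
    for s, grp in zip(base_samples, groups):
        sample_rows.append({"sample": s, "group": grp, "replicate_of": ""})
    for rep, base in replicate_of.items():
        grp = groups[base_samples.index(base)]
        sample_rows.append(
            {"sample": rep, "group": grp, "replicate_of": base}
        )
    samples = pd.DataFrame(sample_rows).set_index("sample")
    samples = samples.loc[values.columns]

    truth = {
        "true_mean": pd.DataFrame(true_mean, index=genes,
                                  columns=base_samples),
        "lane_factor": pd.Series(lane, index=base_samples),
        "efficiency_factor": pd.Series(efficiency, index=base_samples),
        "latent_factor": pd.Series(latent_raw, index=base_samples),
        "config": config,
    }
    return SimulatedStudy(
        counts=CountMatrix(values=values, annotation=annotation),
        annotation=annotation.reset_index(),
        samples=samples,
        truth=truth,
    )


@dataclass
class DdpcrSimConfig:
    """One simulated duplex droplet well.

    ``n_droplets=None`` draws a count uniformly from the observed plausible
    range 5,549–19,264 read droplets.
    """

    true_concentration: float = 25.0   # FAM target, copies/µL
    ref_concentration: float = 50.0    # HEX reference, copies/µL (0.05 CPD)
    droplet_volume: float = 0.001      # µL per droplet
    n_droplets: Optional[int] = None
    target_fam: str = "BRCA1"
    target_hex: str = "GUSB"
    well: str = "A01"
    no_rt: bool = False
    seed: int = 0

    DROPLET_RANGE = (5549, 19264)

    def __post_init__(self) -> None:
        if self.true_concentration < 0 or self.ref_concentration < 0:
            raise ConfigError("concentrations must be >= 0")
        if self.droplet_volume <= 0:
            raise ConfigError("droplet volume must be positive")
        if self.n_droplets is not None and self.n_droplets <= 0:
            raise ConfigError("n_droplets must be positive")


def simulate_droplet_well(
    config: DdpcrSimConfig | None = None, seed: int | None = None
) -> DropletWell:
    """Draw one duplex droplet well.

    Each droplet is independently positive with probability
    ``1 - exp(-c * V_d)`` per channel.
    """
    config = config or DdpcrSimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if config.n_droplets is None:
        lo, hi = DdpcrSimConfig.DROPLET_RANGE
        n = int(rng.integers(lo, hi + 1))
    else:
        n = config.n_droplets
    p_fam = -np.expm1(-config.true_concentration * config.droplet_volume)
    p_hex = -np.expm1(-config.ref_concentration * config.droplet_volume)
    return DropletWell(
        well=config.well,
        target_fam=config.target_fam,
        target_hex=config.target_hex,
        n_droplets=n,
        n_pos_fam=int(rng.binomial(n, p_fam)),
        n_pos_hex=int(rng.binomial(n, p_hex)),
        no_rt=config.no_rt,
    )


def wells_table(wells: Sequence[DropletWell]) -> pd.DataFrame:
    """Droplet wells as the CSV schema the quantitation stage reads."""
    return pd.DataFrame([
        {
            "well": w.well, "target_fam": w.target_fam,
            "target_hex": w.target_hex, "n_droplets": w.n_droplets,
            "n_pos_fam": w.n_pos_fam, "n_pos_hex": w.n_pos_hex,
            "no_rt": w.no_rt,
        }
        for w in wells
    ])


# -- transcript / variant fixtures ----------------------------------------

_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


def _stop_free_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def _build_transcript(
    rng: np.random.Generator,
    transcript_id: str,
    exon_lengths: tuple[int, ...],
    cds_start: int,
) -> TranscriptModel:
    """Random transcript whose reference reading frame is stop-free from the
    CDS start up to a natural stop placed at the very end."""
    total = sum(exon_lengths)
    utr5 = "".join(rng.choice(list("ACGT"), size=cds_start - 1))
    n_codons = (total - (cds_start - 1)) // 3
    cds = _stop_free_cds(rng, max(n_codons - 1, 1)) + "TAA"
    seq = (utr5 + cds)[:total]
    if len(seq) < total:
        seq = seq + "".join(rng.choice(list("ACGT"), size=total - len(seq)))
    return TranscriptModel(
        transcript_id=transcript_id,
        exon_lengths=exon_lengths,
        cds_start=cds_start,
        sequence=seq,
    )


@dataclass
class TranscriptFixture:
    label: str
    transcript: TranscriptModel
    variant: Variant


def simulate_transcript_fixtures(seed: int = 0) -> list[TranscriptFixture]:
    """Transcript/variant fixtures straddling every NMD rule boundary.

    Covered cases: a mid-CDS nonsense PTC passing all rules; a PTC in the
    last exon; a two-exon transcript; a start-proximal PTC (<200 nt); a
    junction-proximal PTC (<=50 nt); frameshift insertion and deletion whose
    PTC must be found in the shifted frame; a missense and an in-frame exon
    skip (no PTC). Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    fixtures: list[TranscriptFixture] = []
    five_exons = (300, 300, 300, 300, 300)  # last junction at 1200

    def add(label, exons, cds_start, vtype, position, length=0):
        t = _build_transcript(rng, f"TX_{label}", exons, cds_start)
        fixtures.append(TranscriptFixture(
            label=label,
            transcript=t,
            variant=Variant(
                transcript_id=t.transcript_id, type=vtype,
                position=position, length=length,
            ),
        ))

    # nonsense positions chosen codon-aligned with cds_start = 50
    add("nonsense_all_rules_pass", five_exons, 50, NONSENSE, 50 + 201 * 3)
    add("nonsense_last_exon", five_exons, 50, NONSENSE, 50 + 400 * 3)  # 1250
    add("nonsense_two_exon", (600, 600), 50, NONSENSE, 50 + 150 * 3)
    add("nonsense_start_proximal", five_exons, 50, NONSENSE, 50 + 50 * 3)
    add("nonsense_junction_proximal", five_exons, 50, NONSENSE, 50 + 376 * 3)
    add("frameshift_ins_mid_cds", five_exons, 50, FRAMESHIFT_INS, 500, 1)
    add("frameshift_del_mid_cds", five_exons, 50, FRAMESHIFT_DEL, 500, 2)
    add("missense", five_exons, 50, MISSENSE, 500)
    add("inframe_exon_skip", five_exons, 50, INFRAME_EXON_SKIP, 156)
    return fixtures
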