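"""Nonsense-mediated decay (NMD) prediction for PTC-generating variants.

A premature termination codon (PTC) is predicted to elicit NMD when all
three classical positional rules hold on the (mutant) spliced transcript:

1. the PTC lies more than a threshold distance (default 50 nt, configurable
   up to 55) upstream of the last exon–exon junction;
2. the transcript has more than two exons;
3. the PTC lies more than 200 nt downstream of the start codon.

Coordinates are 1-based and fully closed on the spliced transcript. All
distances are measured from the *first nucleotide of the stop codon*: the
junction distance is ``(last nt of the penultimate exon) - ptc + 1`` and the
start distance is ``ptc - cds_start``. Frameshift variants are first applied
to the transcript (adjusting exon lengths and the spliced sequence), and the
shifted reading frame is scanned for the first stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

STOP_CODONS = {"TAA", "TAG", "TGA"}

NMD_PREDICTED = "NMD_predicted"
NMD_ESCAPE = "NMD_escape"
NOT_APPLICABLE = "not_applicable"

FRAMESHIFT_INS = "frameshift_ins"
FRAMESHIFT_DEL = "frameshift_del"
NONSENSE = "nonsense"
INFRAME_EXON_SKIP = "inframe_exon_skip"
MISSENSE = "missense"
VARIANT_TYPES = (
    FRAMESHIFT_INS, FRAMESHIFT_DEL, NONSENSE, INFRAME_EXON_SKIP, MISSENSE,
)


class NmdError(ValueError):
    pass


@dataclass
class TranscriptModel:
    """Spliced transcript: ordered exon lengths plus CDS start.

    ``sequence`` (DNA or RNA alphabet; U is normalized to T) is optional and
    only required to locate the PTC created by a frameshift.
    """

    transcript_id: str
    exon_lengths: tuple[int, ...]
    cds_start: int  # 1-based position of the A of the start codon
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        self.exon_lengths = tuple(int(x) for x in self.exon_lengths)
        if any(x <= 0 for x in self.exon_lengths):
            raise NmdError("exon lengths must be positive")
        if not 1 <= self.cds_start <= self.length:
            raise NmdError("CDS start outside transcript")
        if self.sequence is not None:
            self.sequence = self.sequence.upper().replace("U", "T")
            if len(self.sequence) != self.length:
                raise NmdError(
                    "sequence length does not match summed exon lengths"
                )

    @property
    def length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def exon_count(self) -> int:
        return len(self.exon_lengths)

    @property
    def last_junction(self) -> Optional[int]:
        """Transcript position of the last nt before the final junction
        (i.e. the last nt of the penultimate exon); None for single-exon."""
        if self.exon_count < 2:
            return None
        return sum(self.exon_lengths[:-1])

    # exon-local <-> transcript coordinate round trip
    def to_exon_local(self, pos: int) -> tuple[int, int]:
        """Transcript position -> (exon index 1-based, offset 1-based)."""
        if not 1 <= pos <= self.length:
            raise NmdError(f"position {pos} outside transcript")
        cum = 0
        for i, L in enumerate(self.exon_lengths, start=1):
            if pos <= cum + L:
                return i, pos - cum
            cum += L
        raise AssertionError("unreachable")

    def to_transcript(self, exon_index: int, offset: int) -> int:
        if not 1 <= exon_index <= self.exon_count:
            raise NmdError("exon index out of range")
        if not 1 <= offset <= self.exon_lengths[exon_index - 1]:
            raise NmdError("offset outside exon")
        return sum(self.exon_lengths[: exon_index - 1]) + offset


@dataclass
class Variant:
    """Transcript-level variant description.

    ``position`` is 1-based on the reference spliced transcript. For an
    insertion, ``length`` nucleotides (``inserted_sequence`` if given) are
    inserted *after* ``position``; for a deletion, positions
    ``position .. position+length-1`` are removed. For a nonsense variant,
    ``position`` is the first nucleotide of the new stop codon.
    """

    transcript_id: str
    type: str
    position: int
    length: int = 0
    inserted_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.type not in VARIANT_TYPES:
            raise NmdError(f"unknown variant type {self.type!r}")
        if self.type in (FRAMESHIFT_INS, FRAMESHIFT_DEL):
            if self.length % 3 == 0:
                raise NmdError(
                    "frameshift variant length must not be a multiple of 3"
                )
        if self.inserted_sequence is not None:
            self.inserted_sequence = (
                self.inserted_sequence.upper().replace("U", "T")
            )
            if len(self.inserted_sequence) != self.length:
                raise NmdError("inserted_sequence length mismatch")


@dataclass
class NmdRuleConfig:
    """Thresholds of the three positional rules."""

    junction_threshold: int = 50   # nt; classical rule range 50-55
    start_threshold: int = 200     # nt downstream of the start codon
    min_exon_count: int = 3        # "more than two exons"

    def __post_init__(self) -> None:
        if self.junction_threshold <= 0 or self.start_threshold <= 0:
            raise NmdError("thresholds must be positive")


@dataclass
class NMDPrediction:
    transcript_id: str
    ptc_position: Optional[int]          # mutant transcript coordinates
    distance_to_last_junction: Optional[int]
    distance_from_start: Optional[int]
    exon_count: int
    rule_junction: Optional[bool]
    rule_exon_count: Optional[bool]
    rule_start_distance: Optional[bool]
    call: str
    nonstop: bool = False


def apply_variant(
    transcript: TranscriptModel, variant: Variant
) -> TranscriptModel:
    """Mutant transcript model after an insertion or deletion.

    Exon lengths are adjusted in place of the affected exon(s); the spliced
    sequence, if present, is edited accordingly. Non-indel variants return
    the transcript unchanged (a nonsense SNV preserves coordinates).
    """
    if variant.type == FRAMESHIFT_INS:
        exon_i, _ = transcript.to_exon_local(variant.position)
        lengths = list(transcript.exon_lengths)
        lengths[exon_i - 1] += variant.length
        seq = None
        if transcript.sequence is not None:
            ins = variant.inserted_sequence or "A" * variant.length
            p = variant.position
            seq = transcript.sequence[:p] + ins + transcript.sequence[p:]
        return TranscriptModel(
            transcript_id=transcript.transcript_id,
            exon_lengths=tuple(lengths),
            cds_start=transcript.cds_start,
            sequence=seq,
        )
    if variant.type == FRAMESHIFT_DEL:
        start = variant.position
        end = variant.position + variant.length - 1
        if end > transcript.length:
            raise NmdError("deletion runs past transcript end")
        lengths = list(transcript.exon_lengths)
        for pos in range(start, end + 1):
            exon_i, _ = transcript.to_exon_local(pos)
            lengths[exon_i - 1] -= 1
        lengths = [L for L in lengths if L > 0]
        seq = None
        if transcript.sequence is not None:
            seq = transcript.sequence[: start - 1] + transcript.sequence[end:]
        cds = transcript.cds_start
        if cds >= start:  # deletion upstream of the start codon shifts it
            cds = max(1, cds - min(variant.length, cds - start + 1))
        return TranscriptModel(
            transcript_id=transcript.transcript_id,
            exon_lengths=tuple(lengths),
            cds_start=cds,
            sequence=seq,
        )
    return transcript


def locate_ptc(
    transcript: TranscriptModel, variant: Variant
) -> tuple[Optional[int], TranscriptModel, bool]:
    """PTC position created by a variant, in mutant transcript coordinates.

    Returns ``(ptc_position, mutant_transcript, nonstop)``:

    - nonsense: the variant position itself (first nt of the stop codon);
    - frameshift: the mutant sequence is read codon by codon from the CDS
      start and the first stop codon's first-nucleotide position returned —
      ``nonstop=True`` (with position None) if no stop occurs before the
      transcript end;
    - missense / in-frame exon skip: None (no PTC).
    """
    if variant.type == NONSENSE:
        if variant.position < transcript.cds_start:
            raise NmdError("nonsense variant upstream of the start codon")
        return variant.position, transcript, False
    if variant.type in (MISSENSE, INFRAME_EXON_SKIP):
        return None, transcript, False
    # frameshift
    if transcript.sequence is None:
        raise NmdError(
            "spliced sequence required to locate a frameshift PTC"
        )
    if variant.position < transcript.cds_start:
        raise NmdError("frameshift upstream of the start codon")
    mutant = apply_variant(transcript, variant)
    seq = mutant.sequence
    for i in range(mutant.cds_start - 1, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i + 1, mutant, False
    return None, mutant, True


def predict_nmd(
    transcript: TranscriptModel,
    ptc_position: Optional[int],
    config: NmdRuleConfig | None = None,
    nonstop: bool = False,
) -> NMDPrediction:
    """Apply the three positional rules to a located PTC.

    A PTC in the last exon fails the junction rule (not an error). A
    variant with no PTC yields ``not_applicable``.
    """
    config = config or NmdRuleConfig()
    if ptc_position is None:
        return NMDPrediction(
            transcript_id=transcript.transcript_id, ptc_position=None,
            distance_to_last_junction=None, distance_from_start=None,
            exon_count=transcript.exon_count,
            rule_junction=None, rule_exon_count=None,
            rule_start_distance=None, call=NOT_APPLICABLE, nonstop=nonstop,
        )
    if not 1 <= ptc_position <= transcript.length:
        raise NmdError("PTC position outside transcript")
    junction = transcript.last_junction
    if junction is None:
        d_junction = None
        rule1 = False
    else:
        d_junction = junction - ptc_position + 1
        rule1 = d_junction > config.junction_threshold
    d_start = ptc_position - transcript.cds_start
    rule2 = transcript.exon_count >= config.min_exon_count
    rule3 = d_start > config.start_threshold
    call = NMD_PREDICTED if (rule1 and rule2 and rule3) else NMD_ESCAPE
    return NMDPrediction(
        transcript_id=transcript.transcript_id, ptc_position=ptc_position,
        distance_to_last_junction=d_junction, distance_from_start=d_start,
        exon_count=transcript.exon_count,
        rule_junction=rule1, rule_exon_count=rule2,
        rule_start_distance=rule3, call=call,
    )


def classify_variant(
    transcript: TranscriptModel,
    variant: Variant,
    config: NmdRuleConfig | None = None,
) -> NMDPrediction:
    """Locate the PTC (if any) and apply the rules on the mutant model."""
    ptc, mutant, nonstop = locate_ptc(transcript, variant)
    return predict_nmd(mutant, ptc, config, nonstop=nonstop)


def predictions_table(
    pairs: list[tuple[TranscriptModel, Variant]],
    config: NmdRuleConfig | None = None,
) -> pd.DataFrame:
    """Batch classification as a flat table (one row per variant)."""
    rows = []
    for transcript, variant in pairs:
        p = classify_variant(transcript, variant, config)
        rows.append({
            "transcript": transcript.transcript_id,
            "variant_type": variant.type,
            "variant_position": variant.position,
            "ptc_position": p.ptc_position,
            "distance_to_last_junction": p.distance_to_last_junction,
            "distance_from_start": p.distance_from_start,
            "exon_count": p.exon_count,
            "rule_junction": p.rule_junction,
            "rule_exon_count": p.rule_exon_count,
            "rule_start_distance": p.rule_start_distance,
            "call": p.call,
        })
    return pd.DataFrame(rows)


def read_transcripts(path) -> dict[str, TranscriptModel]:
    """Read transcripts from CSV (transcript, exon_index, length[, cds_start])
    with one row per exon; optional per-transcript sequence column."""
    df = pd.read_csv(path)
    models = {}
    for tid, grp in df.groupby("transcript", sort=False):
        grp = grp.sort_values("exon_index")
        seq = None
        if "sequence" in grp.columns:
            joined = "".join(
                s for s in grp["sequence"].astype(str) if s and s != "nan"
            )
            seq = joined or None
        cds = int(grp["cds_start"].iloc[0]) if "cds_start" in grp.columns else 1
        models[tid] = TranscriptModel(
            transcript_id=str(tid),
            exon_lengths=tuple(int(x) for x in grp["length"]),
            cds_start=cds,
            sequence=seq,
        )
    return models


def read_variants(path) -> list[Variant]:
    """Read variants from CSV (transcript, type, position, length)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(Variant(
            transcript_id=str(row["transcript"]),
            type=str(row["type"]),
            position=int(row["position"]),
            length=int(row.get("length", 0) or 0),
        ))
    return out
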